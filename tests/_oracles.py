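"""Independent oracles shared between test modules."""

import numpy as np


def absorption_oracle(delta: float, b: float, K: int) -> np.ndarray:
    """Threshold-hitting probabilities of the single-group chain by direct
    linear-system solution of the full one-step transition matrix.

    Independent of the closed-form product under test.
    """
    interior = np.arange(1, K)
    t = b * (interior / K) * (1.0 - interior / K)
    Q = np.zeros((K - 1, K - 1))
    to_K = np.zeros(K - 1)
    for i, n in enumerate(interior):
        Q[i, i] = delta * (1.0 - t[i])
        if n + 1 < K:
            Q[i, i + 1] = delta * t[i]
        else:
            to_K[i] = delta * t[i]
    h = np.linalg.solve(np.eye(K - 1) - Q, to_K)
    return np.concatenate([[0.0], h, [1.0]])
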