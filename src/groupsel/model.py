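"""Discrete-time stochastic simulator of group-structured populations.

A population is a collection of groups, each holding n_A cooperators
(social individuals) and n_B cheaters (asocial individuals) on K sites.
Every timestep, three processes run in order:

1. reproduction — every group independently gains at most one individual,
   with probabilities proportional to type fraction and free resources;
2. group death — at most one group is removed, with composition-dependent
   probability in the "relative" and "absolute" fitness modes;
3. group splitting — if the population is below the carrying capacity K_g
   and at least one group has filled its K sites, one full group splits
   into two daughters by uniform allocation of its members.

The per-step operations are exposed as plain numpy functions operating on
a PopulationState (used by the tests and for small-scale exploration);
`simulate` runs the fused loop in a numba kernel sharing the same
np.random.Generator, so a fixed seed gives bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .analytics import DegenerateWeightsError

__all__ = [
    "GroupState",
    "ModelParams",
    "PopulationState",
    "RunResult",
    "reproduction_probs",
    "step_reproduction",
    "death_probs",
    "step_death",
    "allocate_daughters",
    "step_split",
    "init_homogeneous",
    "init_heterogeneous",
    "simulate",
]

MODES = ("neutral", "relative", "absolute")
_MODE_CODE = {m: i for i, m in enumerate(MODES)}


@dataclass(frozen=True)
class GroupState:
    """Composition of one group: n_A cooperators, n_B cheaters."""

    n_A: int
    n_B: int

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError("group counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_A + self.n_B


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    K    : splitting threshold (sites per group), integer >= 2.
    K_g  : environmental carrying capacity in groups, integer >= 1.
    mu   : per-step probability that any group death occurs, in [0, 1].
    a    : social trait strength, in [0, 1].
    b    : asocial reproduction scale factor, in [1, 4] (the sum of the
           two reproduction probabilities stays <= 1 iff b <= 4).
    mode : "neutral", "relative" or "absolute" group fitness.
    """

    K: int
    K_g: int
    mu: float
    a: float = 0.0
    b: float = 1.0
    mode: str = "neutral"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be an integer >= 2, got {self.K}")
        if self.K_g < 1:
            raise ValueError(f"K_g must be an integer >= 1, got {self.K_g}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must be in [0, 1], got {self.mu}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"a must be in [0, 1], got {self.a}")
        if not 1.0 <= self.b <= 4.0:
            raise ValueError(f"b must be in [1, 4], got {self.b}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass
class PopulationState:
    """Group compositions as parallel integer arrays plus the current time."""

    n_A: np.ndarray
    n_B: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        self.n_A = np.asarray(self.n_A, dtype=np.int64)
        self.n_B = np.asarray(self.n_B, dtype=np.int64)
        if self.n_A.shape != self.n_B.shape:
            raise ValueError("n_A and n_B must have equal length")
        if np.any(self.n_A < 0) or np.any(self.n_B < 0):
            raise ValueError("group counts must be non-negative")
        if np.any(self.n_A + self.n_B == 0):
            raise ValueError("empty groups may not exist in a population")

    @property
    def n_groups(self) -> int:
        return int(self.n_A.size)

    @property
    def groups(self) -> list[GroupState]:
        return [GroupState(int(a), int(b)) for a, b in zip(self.n_A, self.n_B)]

    def copy(self) -> "PopulationState":
        return PopulationState(self.n_A.copy(), self.n_B.copy(), self.t)


@dataclass
class RunResult:
    """Per-timestep trajectory of a single run.

    Arrays are aligned with `times`; `outcome` is "survived" or "extinct";
    the trajectory ends at the extinction step when the population dies
    before T.
    """

    times: np.ndarray
    n_groups: np.ndarray
    n_groups_allA: np.ndarray
    total_A: np.ndarray
    total_B: np.ndarray
    outcome: str
    final_state: PopulationState
    params: ModelParams | None = field(default=None, repr=False)
    seed: int | None = None

    @property
    def final_t(self) -> int:
        return int(self.times[-1])


# ---------------------------------------------------------------------------
# per-step operations (numpy reference implementations)
# ---------------------------------------------------------------------------


def reproduction_probs(group: GroupState, params: ModelParams) -> tuple[float, float]:
    """Per-step reproduction probabilities (p_A, p_B) for one group.

    p_A = (n_A/K)(1 - n/K), p_B = b (n_B/K)(1 - n/K) with n = n_A + n_B;
    both vanish at the splitting threshold n = K.
    """
    K, b = params.K, params.b
    n = group.size
    if n > K:
        raise ValueError("group size exceeds the splitting threshold K")
    avail = 1.0 - n / K
    return group.n_A / K * avail, b * group.n_B / K * avail


def _repro_prob_arrays(n_A, n_B, K, b):
    avail = 1.0 - (n_A + n_B) / K
    return n_A / K * avail, b * n_B / K * avail


def step_reproduction(
    pop: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """All groups gain at most one individual, in parallel from the entry state."""
    p_A, p_B = _repro_prob_arrays(pop.n_A, pop.n_B, params.K, params.b)
    u = rng.random(pop.n_groups)
    born_A = u < p_A
    born_B = (~born_A) & (u < p_A + p_B)
    return PopulationState(pop.n_A + born_A, pop.n_B + born_B, pop.t)


def death_probs(pop: PopulationState, params: ModelParams) -> np.ndarray:
    """Per-group probabilities of dying this step.

    neutral  : mu / N_g each.
    relative : mu * w_j / sum(w) with w_j = 1 - a f_{j,A}; sums to mu.
    absolute : (mu / N_g)(1 - a f_{j,A}); sums to <= mu.
    """
    n = pop.n_groups
    if n < 1:
        raise ValueError("death_probs requires at least one group")
    mu, a = params.mu, params.a
    if params.mode == "neutral":
        return np.full(n, mu / n)
    frac_A = pop.n_A / (pop.n_A + pop.n_B)
    w = 1.0 - a * frac_A
    if params.mode == "relative":
        total = w.sum()
        if total <= 0.0:
            raise DegenerateWeightsError(
                "all death weights are zero (a = 1 and every group all-A)"
            )
        return mu * w / total
    return (mu / n) * w  # absolute


def step_death(
    pop: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Remove at most one group.

    neutral/relative: with probability mu exactly one group dies, chosen by
    the normalized weights.  absolute: with probability mu one group is
    selected uniformly, then dies with probability 1 - a f_A (select-then-
    kill), so the total death probability per step is <= mu.
    """
    if pop.n_groups < 1:
        raise ValueError("step_death requires at least one group")
    if rng.random() >= params.mu:
        return pop
    if params.mode == "absolute":
        j = int(rng.integers(0, pop.n_groups))
        frac_A = pop.n_A[j] / (pop.n_A[j] + pop.n_B[j])
        if rng.random() >= 1.0 - params.a * frac_A:
            return pop
    else:
        p = death_probs(pop, params)
        j = int(rng.choice(pop.n_groups, p=p / p.sum()))
    keep = np.ones(pop.n_groups, dtype=bool)
    keep[j] = False
    return PopulationState(pop.n_A[keep], pop.n_B[keep], pop.t)


def allocate_daughters(
    n_A: int, n_B: int, rng: np.random.Generator
) -> tuple[GroupState, GroupState]:
    """Uniform allocation of a full parent's members into two daughters.

    m_A ~ U{0..n_A} and m_B ~ U{0..n_B} independently; daughters are
    (m_A, m_B) and (n_A - m_A, n_B - m_B).  Individuals are conserved.
    """
    m_A = int(rng.integers(0, n_A + 1))
    m_B = int(rng.integers(0, n_B + 1))
    return GroupState(m_A, m_B), GroupState(n_A - m_A, n_B - m_B)


def step_split(
    pop: PopulationState, params: ModelParams, rng: np.random.Generator
) -> PopulationState:
    """Split one full group if the carrying capacity allows.

    One group with n_A + n_B = K, chosen uniformly among full groups, is
    replaced by its two daughters; an empty daughter is discarded
    immediately (abortive split leaves membership unchanged).  No split
    occurs at N_g = K_g or when no group is full.
    """
    if pop.n_groups >= params.K_g:
        return pop
    full = np.flatnonzero(pop.n_A + pop.n_B == params.K)
    if full.size == 0:
        return pop
    j = int(full[rng.integers(0, full.size)])
    d1, d2 = allocate_daughters(int(pop.n_A[j]), int(pop.n_B[j]), rng)
    daughters = [d for d in (d1, d2) if d.size > 0]
    n_A = np.delete(pop.n_A, j)
    n_B = np.delete(pop.n_B, j)
    n_A = np.concatenate([n_A, [d.n_A for d in daughters]])
    n_B = np.concatenate([n_B, [d.n_B for d in daughters]])
    return PopulationState(n_A, n_B, pop.t)


# ---------------------------------------------------------------------------
# initial populations
# ---------------------------------------------------------------------------


def init_homogeneous(
    N_gA: int, N_gB: int, K: int, rng: np.random.Generator
) -> PopulationState:
    """N_gA all-A plus N_gB all-B groups, sizes uniform on {1, ..., K-1}.

    The uniform occupancy mirrors the averaging over initial states used
    by the proliferation criterion; the group type order is A-first.
    """
    if N_gA + N_gB < 1:
        raise ValueError("need at least one group")
    sizes_A = rng.integers(1, K, size=N_gA)
    sizes_B = rng.integers(1, K, size=N_gB)
    n_A = np.concatenate([sizes_A, np.zeros(N_gB, dtype=np.int64)])
    n_B = np.concatenate([np.zeros(N_gA, dtype=np.int64), sizes_B])
    return PopulationState(n_A, n_B)


def init_heterogeneous(N_g: int, K: int, rng: np.random.Generator) -> PopulationState:
    """N_g mixed groups with n_A, n_B ~ U{0, ..., K//2}, redrawn if both zero."""
    if N_g < 1:
        raise ValueError("need at least one group")
    half = K // 2
    n_A = rng.integers(0, half + 1, size=N_g)
    n_B = rng.integers(0, half + 1, size=N_g)
    empty = (n_A + n_B) == 0
    while np.any(empty):
        k = int(empty.sum())
        n_A[empty] = rng.integers(0, half + 1, size=k)
        n_B[empty] = rng.integers(0, half + 1, size=k)
        empty = (n_A + n_B) == 0
    return PopulationState(n_A, n_B)


# ---------------------------------------------------------------------------
# fused simulation kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _simulate_kernel(  # noqa: C901 - hot loop, kept flat on purpose
    n_A,
    n_B,
    n0,
    K,
    K_g,
    mu,
    a,
    b,
    mode,
    T,
    gen,
    out_ng,
    out_ngA,
    out_totA,
    out_totB,
    stop_homog,
):
    """Run T steps in place.  Returns (final_n_groups, last_recorded_step).

    Arrays n_A/n_B have capacity max(n0, K_g) + 1; active groups occupy
    the first `n` slots.  mode: 0 neutral, 1 relative, 2 absolute.
    With stop_homog, terminates early once every group is all-A or every
    group is all-B (used by rare-death fixation experiments).
    Raises ValueError on degenerate relative-mode weights.
    """
    n = n0
    # record initial state at index 0
    ngA = 0
    totA = 0
    totB = 0
    for j in range(n):
        totA += n_A[j]
        totB += n_B[j]
        if n_B[j] == 0:
            ngA += 1
    out_ng[0] = n
    out_ngA[0] = ngA
    out_totA[0] = totA
    out_totB[0] = totB
    last = 0
    for t in range(1, T + 1):
        # --- reproduction (parallel, at most one birth per group) ---
        for j in range(n):
            tot = n_A[j] + n_B[j]
            if tot < K:
                avail = 1.0 - tot / K
                p_A = n_A[j] / K * avail
                p_B = b * n_B[j] / K * avail
                u = gen.random()
                if u < p_A:
                    n_A[j] += 1
                elif u < p_A + p_B:
                    n_B[j] += 1
        # --- group death (at most one per step) ---
        if n > 0 and gen.random() < mu:
            kill = -1
            if mode == 0:
                kill = gen.integers(0, n)
            elif mode == 1:
                total_w = 0.0
                for j in range(n):
                    total_w += 1.0 - a * n_A[j] / (n_A[j] + n_B[j])
                if total_w <= 0.0:
                    raise ValueError(
                        "degenerate death weights: a = 1 with all-A population"
                    )
                u = gen.random() * total_w
                acc = 0.0
                for j in range(n):
                    acc += 1.0 - a * n_A[j] / (n_A[j] + n_B[j])
                    if u < acc:
                        kill = j
                        break
                if kill < 0:
                    kill = n - 1
            else:  # absolute: select uniformly, then kill with prob 1 - a f_A
                j = gen.integers(0, n)
                if gen.random() < 1.0 - a * n_A[j] / (n_A[j] + n_B[j]):
                    kill = j
            if kill >= 0:
                n_A[kill] = n_A[n - 1]
                n_B[kill] = n_B[n - 1]
                n -= 1
        # --- group splitting (at most one per step) ---
        if 0 < n < K_g:
            n_full = 0
            for j in range(n):
                if n_A[j] + n_B[j] == K:
                    n_full += 1
            if n_full > 0:
                pick = gen.integers(0, n_full)
                idx = -1
                c = 0
                for j in range(n):
                    if n_A[j] + n_B[j] == K:
                        if c == pick:
                            idx = j
                            break
                        c += 1
                pa, pb = n_A[idx], n_B[idx]
                m_A = gen.integers(0, pa + 1)
                m_B = gen.integers(0, pb + 1)
                if m_A + m_B == 0 or (pa - m_A) + (pb - m_B) == 0:
                    pass  # abortive split: an empty daughter is discarded
                else:
                    n_A[idx] = m_A
                    n_B[idx] = m_B
                    n_A[n] = pa - m_A
                    n_B[n] = pb - m_B
                    n += 1
        # --- record ---
        ngA = 0
        totA = 0
        totB = 0
        for j in range(n):
            totA += n_A[j]
            totB += n_B[j]
            if n_B[j] == 0:
                ngA += 1
        out_ng[t] = n
        out_ngA[t] = ngA
        out_totA[t] = totA
        out_totB[t] = totB
        last = t
        if n == 0:
            break
        if stop_homog and (ngA == n or (ngA == 0 and totA == 0)):
            break
    return n, last


def simulate(
    params: ModelParams,
    init: PopulationState,
    T: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    stop_when_homogeneous: bool = False,
) -> RunResult:
    """Run the full model for T steps (or until extinction).

    Event order within a step: reproduction -> death -> split, so a group
    that fills this step may split this step only after surviving death.
    Either a seed or an existing Generator may be supplied; identical
    (params, init, seed) give bit-identical results.  With
    stop_when_homogeneous the run also terminates once one phenotype has
    fixed in the whole population (rare-death fixation experiments).
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n0 = init.n_groups
    cap = max(n0, params.K_g) + 1
    n_A = np.zeros(cap, dtype=np.int64)
    n_B = np.zeros(cap, dtype=np.int64)
    n_A[:n0] = init.n_A
    n_B[:n0] = init.n_B
    out_ng = np.zeros(T + 1, dtype=np.int64)
    out_ngA = np.zeros(T + 1, dtype=np.int64)
    out_totA = np.zeros(T + 1, dtype=np.int64)
    out_totB = np.zeros(T + 1, dtype=np.int64)
    try:
        n_final, last = _simulate_kernel(
            n_A,
            n_B,
            n0,
            params.K,
            params.K_g,
            params.mu,
            params.a,
            params.b,
            _MODE_CODE[params.mode],
            T,
            rng,
            out_ng,
            out_ngA,
            out_totA,
            out_totB,
            stop_when_homogeneous,
        )
    except ValueError as err:  # re-raise numba error with the library type
        raise DegenerateWeightsError(str(err)) from None
    outcome = "extinct" if n_final == 0 else "survived"
    final_state = PopulationState(
        n_A[:n_final].copy(), n_B[:n_final].copy(), t=int(init.t + last)
    ) if n_final > 0 else PopulationState.__new__(PopulationState)
    if n_final == 0:
        # bypass the no-empty-group invariant for the terminal sentinel
        final_state.n_A = np.zeros(0, dtype=np.int64)
        final_state.n_B = np.zeros(0, dtype=np.int64)
        final_state.t = int(init.t + last)
    sl = slice(0, last + 1)
    return RunResult(
        times=np.arange(init.t, init.t + last + 1),
        n_groups=out_ng[sl].copy(),
        n_groups_allA=out_ngA[sl].copy(),
        total_A=out_totA[sl].copy(),
        total_B=out_totB[sl].copy(),
        outcome=outcome,
        final_state=final_state,
        params=params,
        seed=seed,
    )
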