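"""Off-lattice agent-based biofilm model with interface-restricted predation.

Cells of two phenotypes live in the 2-D half-plane above a substrate of
evenly spaced anchor points.  Social cells produce extracellular matrix,
modeled as a 100-fold larger attractive pseudo-force constant, and pay a
5-fold division-rate cost; asocial cells free-ride on the matrix.  Each
timestep runs motion -> division -> removal:

* motion — every cell feels a pairwise pseudo-force H/d^6 - (G_p+G_q)/(2 d^2)
  from every other cell and H/d^6 - (G_p/2)/d^2 from every anchor, moves a
  fixed distance D along the force direction blended with a random unit
  vector (weight F), and is reflected at the substrate;
* division — per phenotype, a Poisson number of divisions with logistic
  mean n r (1 - N/K_BF) dt duplicates uniformly chosen cells;
* removal — the topmost cell in each substrate window of width D forms
  the predation interface; a Poisson number with mean m L dt of interface
  cells is removed.  Bulk cells never die.

Death therefore scales with the colony's width while growth scales with
its bulk, which is the frequency-dependent group-level selection the
group model idealizes.  Time is measured in doubling times of asocial
cells far from capacity (1 doubling = 1/dt steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "BiofilmParams",
    "BiofilmState",
    "pair_force",
    "step_motion",
    "step_division",
    "find_interface",
    "step_removal",
    "protocol_steady_state",
    "protocol_seeding",
    "protocol_fixation",
]


@dataclass(frozen=True)
class BiofilmParams:
    """Biofilm model constants.

    All lengths are in units of the anchor spacing D; the attraction
    constant of asocial cells is calibrated so an asocial pair is
    force-free at separation D, and social cells have a 100-fold larger
    constant.  Defaults are the reference simulation values.
    """

    H: float = 1.0               # repulsion constant (arbitrary units)
    D: float = 1.0               # anchor spacing = step length = window width
    F: float = 0.5               # weight of the random direction in motion
    r_asocial: float = math.log(2.0)   # division rate far from capacity
    cost_factor: float = 5.0     # social division slowdown
    social_G_factor: float = 100.0     # social attraction multiplier
    K_BF: int = 500              # carrying capacity (cells)
    dt: float = 0.01             # timestep in doubling-time units
    L: float = 0.1               # interface death rate
    n_anchors: int = 400         # substrate anchor count
    seed_stop: int = 300         # seeding success population
    jitter: float = 1e-3         # uniqueness jitter, units of D
    offspring_jitter: float = 1e-2     # offspring displacement, units of D
    relax_steps: int = 1000      # initial relaxation (F=0, no birth/death)
    steady_steps: int = 20000    # full-dynamics steps for steady state

    @property
    def G_asocial(self) -> float:
        # calibration zero of the force law at separation D
        return self.H / self.D**4

    @property
    def G_social(self) -> float:
        return self.social_G_factor * self.G_asocial

    @property
    def r_social(self) -> float:
        return self.r_asocial / self.cost_factor

    @property
    def anchor_x(self) -> np.ndarray:
        return np.arange(self.n_anchors) * self.D

    @property
    def x_max(self) -> float:
        return (self.n_anchors - 1) * self.D

    def __post_init__(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must be in [0, 1]")
        for name in ("H", "r_asocial", "cost_factor", "dt", "L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BiofilmState:
    """Cell positions, phenotypes and accumulated time (doubling units)."""

    x: np.ndarray
    y: np.ndarray
    social: np.ndarray  # uint8, 1 = social (ECM producer)
    t: float = 0.0

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def n_social(self) -> int:
        return int(self.social.sum())

    def copy(self) -> "BiofilmState":
        return BiofilmState(self.x.copy(), self.y.copy(), self.social.copy(), self.t)


def pair_force(d: float, G_p: float, G_q: float, H: float) -> float:
    """Signed pseudo-force magnitude between two cells at distance d.

    Positive = repulsive; zero crossing at d = (2H/(G_p+G_q))^{1/4}.
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    return H / d**6 - (G_p + G_q) / (2.0 * d * d)


# ---------------------------------------------------------------------------
# jitted kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _forces(x, y, soc, n, anchor_x, H, G_a, G_s, fx, fy):
    """Net pseudo-force components on each of the first n cells (in place).

    Flat per-cell loops (self-pair masked by the d2 > 0 guard; positions
    are unique by construction) so LLVM can vectorize the inner body.
    """
    for i in range(n):
        G_i = G_s if soc[i] == 1 else G_a
        xi = x[i]
        yi = y[i]
        sx = 0.0
        sy = 0.0
        for j in range(n):
            dx = xi - x[j]
            dy = yi - y[j]
            d2 = dx * dx + dy * dy
            if d2 > 0.0:
                G_j = G_s if soc[j] == 1 else G_a
                inv = 1.0 / d2
                s = math.sqrt(inv)
                f_over_d = (H * inv * inv * inv - 0.5 * (G_i + G_j) * inv) * s
                sx += f_over_d * dx
                sy += f_over_d * dy
        # substrate anchors: averaged attraction replaced by the cell's own G/2
        for k in range(anchor_x.shape[0]):
            dx = xi - anchor_x[k]
            d2 = dx * dx + yi * yi
            if d2 > 0.0:
                inv = 1.0 / d2
                s = math.sqrt(inv)
                f_over_d = (H * inv * inv * inv - 0.5 * G_i * inv) * s
                sx += f_over_d * dx
                sy += f_over_d * yi
        fx[i] = sx
        fy[i] = sy


@njit(cache=True)
def _step_motion(x, y, soc, n, anchor_x, H, G_a, G_s, F, D, jitter, x_max, gen, fx, fy):
    _forces(x, y, soc, n, anchor_x, H, G_a, G_s, fx, fy)
    for i in range(n):
        norm = math.sqrt(fx[i] * fx[i] + fy[i] * fy[i])
        phi = 2.0 * math.pi * gen.random()
        rx = math.cos(phi)
        ry = math.sin(phi)
        if norm > 0.0:
            ux = (1.0 - F) * fx[i] / norm + F * rx
            uy = (1.0 - F) * fy[i] / norm + F * ry
        else:
            ux = rx
            uy = ry
        un = math.sqrt(ux * ux + uy * uy)
        if un == 0.0:
            phi = 2.0 * math.pi * gen.random()
            ux = math.cos(phi)
            uy = math.sin(phi)
            un = 1.0
        x[i] += D * ux / un
        y[i] += D * uy / un
        # uniqueness jitter, then reflective boundaries
        x[i] += (2.0 * gen.random() - 1.0) * jitter * D
        y[i] += (2.0 * gen.random() - 1.0) * jitter * D
        if y[i] < 0.0:
            y[i] = -y[i]
        if x[i] < 0.0:
            x[i] = -x[i]
        elif x[i] > x_max:
            x[i] = 2.0 * x_max - x[i]


@njit(cache=True)
def _divide_type(x, y, soc, n, cap, is_social, rate, K_BF, dt, disp, D, gen):
    """Poisson divisions for one phenotype; returns the new cell count."""
    n_type = 0
    for i in range(n):
        if (soc[i] == 1) == is_social:
            n_type += 1
    if n_type == 0:
        return n
    mean = n_type * rate * (1.0 - n / K_BF) * dt
    if mean <= 0.0:
        return n
    c = gen.poisson(mean)
    if c <= 0:
        return n
    if c > n_type:
        c = n_type
    # indices of this phenotype
    idx = np.empty(n_type, dtype=np.int64)
    k = 0
    for i in range(n):
        if (soc[i] == 1) == is_social:
            idx[k] = i
            k += 1
    # partial Fisher-Yates: choose c distinct parents uniformly
    for j in range(c):
        pick = j + gen.integers(0, n_type - j)
        idx[j], idx[pick] = idx[pick], idx[j]
    for j in range(c):
        if n >= cap:
            break
        p = idx[j]
        x[n] = x[p] + (2.0 * gen.random() - 1.0) * disp * D
        y[n] = abs(y[p] + (2.0 * gen.random() - 1.0) * disp * D)
        soc[n] = soc[p]
        n += 1
    return n


@njit(cache=True)
def _interface(x, y, n, D, n_bins, best):
    """Topmost cell per substrate window; returns interface size m.

    Window k is centered on anchor k (width D); `best` holds the cell
    index per window, -1 when unoccupied.
    """
    for k in range(n_bins):
        best[k] = -1
    for i in range(n):
        k = int(x[i] / D + 0.5)
        if k < 0:
            k = 0
        elif k >= n_bins:
            k = n_bins - 1
        if best[k] < 0 or y[i] > y[best[k]]:
            best[k] = i
    m = 0
    for k in range(n_bins):
        if best[k] >= 0:
            best[m] = best[k]  # compact occupied windows to the front
            m += 1
    return m


@njit(cache=True)
def _step_removal(x, y, soc, n, D, n_bins, L, dt, gen, best):
    m = _interface(x, y, n, D, n_bins, best)
    if m == 0:
        return n
    c = gen.poisson(m * L * dt)
    if c <= 0:
        return n
    if c > m:
        c = m
    # choose c distinct interface cells, remove by swap-with-last
    for j in range(c):
        pick = j + gen.integers(0, m - j)
        best[j], best[pick] = best[pick], best[j]
    doomed = np.sort(best[:c])[::-1]
    for j in range(c):
        i = doomed[j]
        n -= 1
        x[i] = x[n]
        y[i] = y[n]
        soc[i] = soc[n]
    return n


@njit(cache=True)
def _run_steps(
    x, y, soc, n, cap, anchor_x, H, G_a, G_s, F, D, jitter, disp,
    r_a, r_s, K_BF, dt, L, n_bins, x_max, gen, fx, fy, best,
    n_steps, do_division, do_removal, stop_above, stop_homog,
):
    """Advance up to n_steps; returns (n, steps_done, stop_code).

    stop codes: 0 = step budget exhausted, 1 = extinct, 2 = population
    exceeded stop_above, 3 = homogenized (single phenotype, stop_homog).
    """
    steps = 0
    while steps < n_steps:
        _step_motion(x, y, soc, n, anchor_x, H, G_a, G_s, F, D, jitter, x_max, gen, fx, fy)
        if do_division:
            n = _divide_type(x, y, soc, n, cap, False, r_a, K_BF, dt, disp, D, gen)
            n = _divide_type(x, y, soc, n, cap, True, r_s, K_BF, dt, disp, D, gen)
        if do_removal:
            n = _step_removal(x, y, soc, n, D, n_bins, L, dt, gen, best)
        steps += 1
        if n == 0:
            return n, steps, 1
        if stop_above > 0 and n > stop_above:
            return n, steps, 2
        if stop_homog:
            ns = 0
            for i in range(n):
                ns += soc[i]
            if ns == 0 or ns == n:
                return n, steps, 3
    return n, steps, 0


# ---------------------------------------------------------------------------
# python-level wrappers (single-step API used by the tests)
# ---------------------------------------------------------------------------

_CAP_SLACK = 120  # division can transiently overshoot K_BF


def _buffers(params: BiofilmParams, n: int):
    cap = max(params.K_BF + _CAP_SLACK, n + _CAP_SLACK)
    return cap, np.empty(cap), np.empty(cap), np.empty(params.n_anchors, dtype=np.int64)


def _expand(state: BiofilmState, cap: int):
    x = np.zeros(cap)
    y = np.zeros(cap)
    soc = np.zeros(cap, dtype=np.uint8)
    n = state.n
    x[:n] = state.x
    y[:n] = state.y
    soc[:n] = state.social
    return x, y, soc, n


def step_motion(
    state: BiofilmState, params: BiofilmParams, rng: np.random.Generator,
    F: float | None = None,
) -> BiofilmState:
    """One motion substep (force + random blend, fixed step D, reflection)."""
    cap, fx, fy, _ = _buffers(params, state.n)
    x, y, soc, n = _expand(state, cap)
    _step_motion(
        x, y, soc, n, params.anchor_x, params.H, params.G_asocial, params.G_social,
        params.F if F is None else F, params.D, params.jitter, params.x_max, rng, fx, fy,
    )
    return BiofilmState(x[:n].copy(), y[:n].copy(), soc[:n].copy(), state.t)


def step_division(
    state: BiofilmState, params: BiofilmParams, rng: np.random.Generator
) -> BiofilmState:
    """One division substep: per-phenotype Poisson logistic duplication."""
    cap, _, _, _ = _buffers(params, state.n)
    x, y, soc, n = _expand(state, cap)
    n = _divide_type(x, y, soc, n, cap, False, params.r_asocial, params.K_BF,
                     params.dt, params.offspring_jitter, params.D, rng)
    n = _divide_type(x, y, soc, n, cap, True, params.r_social, params.K_BF,
                     params.dt, params.offspring_jitter, params.D, rng)
    return BiofilmState(x[:n].copy(), y[:n].copy(), soc[:n].copy(), state.t)


def find_interface(state: BiofilmState, params: BiofilmParams) -> np.ndarray:
    """Indices of predation-interface cells (topmost per substrate window)."""
    if state.n == 0:
        raise ValueError("find_interface requires at least one cell")
    best = np.empty(params.n_anchors, dtype=np.int64)
    m = _interface(state.x, state.y, state.n, params.D, params.n_anchors, best)
    return np.sort(best[:m].copy())


def step_removal(
    state: BiofilmState, params: BiofilmParams, rng: np.random.Generator
) -> BiofilmState:
    """One removal substep: Poisson(m L dt) deaths among interface cells."""
    cap, _, _, best = _buffers(params, state.n)
    x, y, soc, n = _expand(state, cap)
    n = _step_removal(x, y, soc, n, params.D, params.n_anchors, params.L,
                      params.dt, rng, best)
    return BiofilmState(x[:n].copy(), y[:n].copy(), soc[:n].copy(), state.t)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------


def _seed_positions(n: int, params: BiofilmParams, rng: np.random.Generator):
    """Uniform positions in the central square of width 5% of the grid span."""
    span = params.n_anchors * params.D
    w = 0.05 * span
    cx = params.x_max / 2.0
    x = cx + (rng.random(n) - 0.5) * w
    y = rng.random(n) * w
    return x, y


def _drive(state_arrays, params, gen, n_steps, do_div, do_rem, stop_above=0,
           stop_homog=False, F=None, record_every=0):
    """Run the fused kernel, optionally recording (step, n, n_social)."""
    x, y, soc, n, cap, fx, fy, best = state_arrays
    Fw = params.F if F is None else F
    traj = []
    done = 0
    code = 0
    while done < n_steps:
        chunk = n_steps - done if record_every == 0 else min(record_every, n_steps - done)
        n, steps, code = _run_steps(
            x, y, soc, n, cap, params.anchor_x, params.H, params.G_asocial,
            params.G_social, Fw, params.D, params.jitter, params.offspring_jitter,
            params.r_asocial, params.r_social, params.K_BF, params.dt, params.L,
            params.n_anchors, params.x_max, gen, fx, fy, best,
            chunk, do_div, do_rem, stop_above, stop_homog,
        )
        done += steps
        if record_every:
            ns = int(soc[:n].sum())
            traj.append((done, n, ns))
        if code != 0:
            break
    return n, done, code, traj


def _make_arrays(x0, y0, soc0, params):
    n = x0.size
    cap = max(params.K_BF + _CAP_SLACK, n + _CAP_SLACK)
    x = np.zeros(cap)
    y = np.zeros(cap)
    soc = np.zeros(cap, dtype=np.uint8)
    x[:n] = x0
    y[:n] = y0
    soc[:n] = soc0
    fx = np.empty(cap)
    fy = np.empty(cap)
    best = np.empty(params.n_anchors, dtype=np.int64)
    return x, y, soc, n, cap, fx, fy, best


def protocol_steady_state(
    phenotype: str,
    params: BiofilmParams = BiofilmParams(),
    seed: int = 0,
    record_every: int = 100,
) -> tuple[BiofilmState, "pd.DataFrame"]:
    """Steady-state protocol: K_BF cells relax (F=0, no birth/death) for
    1000 steps, then full dynamics for 20000 steps.

    Returns the final state and a population trajectory DataFrame with
    columns (t, n, n_social), t in doubling-time units.
    """
    import pandas as pd

    if phenotype not in ("social", "asocial"):
        raise ValueError("phenotype must be 'social' or 'asocial'")
    gen = np.random.default_rng(seed)
    x0, y0 = _seed_positions(params.K_BF, params, gen)
    soc0 = np.full(params.K_BF, 1 if phenotype == "social" else 0, dtype=np.uint8)
    arrays = _make_arrays(x0, y0, soc0, params)
    n, _, _, _ = _drive(arrays, params, gen, params.relax_steps, False, False, F=0.0)
    rows = [(0.0, n, int(arrays[2][:n].sum()))]
    n, done, code, traj = _drive(
        arrays, params, gen, params.steady_steps, True, True,
        record_every=record_every,
    )
    rows += [(s * params.dt, nn, ns) for s, nn, ns in traj]
    x, y, soc = arrays[0], arrays[1], arrays[2]
    final = BiofilmState(x[:n].copy(), y[:n].copy(), soc[:n].copy(),
                         t=params.steady_steps * params.dt)
    return final, pd.DataFrame(rows, columns=["t", "n", "n_social"])


def protocol_seeding(
    phenotype: str,
    params: BiofilmParams = BiofilmParams(),
    seed: int = 0,
    max_steps: int = 500_000,
) -> dict:
    """Seeding protocol: a single founder cell; success when the population
    exceeds `seed_stop` cells, extinction when it reaches zero.

    Returns {"outcome": "success"|"extinct"|"undecided", "t": doubling
    times elapsed, "n_final": population at termination}.
    """
    if phenotype not in ("social", "asocial"):
        raise ValueError("phenotype must be 'social' or 'asocial'")
    gen = np.random.default_rng(seed)
    x0, y0 = _seed_positions(1, params, gen)
    soc0 = np.full(1, 1 if phenotype == "social" else 0, dtype=np.uint8)
    arrays = _make_arrays(x0, y0, soc0, params)
    n, _, _, _ = _drive(arrays, params, gen, params.relax_steps, False, False, F=0.0)
    n, done, code, _ = _drive(
        arrays, params, gen, max_steps, True, True, stop_above=params.seed_stop
    )
    outcome = {1: "extinct", 2: "success"}.get(code, "undecided")
    return {"outcome": outcome, "t": done * params.dt, "n_final": int(n), "seed": seed}


def protocol_fixation(
    steady_state: BiofilmState,
    params: BiofilmParams = BiofilmParams(),
    seed: int = 0,
    max_steps: int = 2_000_000,
) -> dict:
    """Fixation protocol: relabel one uniformly chosen cell of an asocial
    steady-state biofilm as social and run until the biofilm homogenizes.

    Returns {"outcome": "fixed"|"lost"|"undecided", "t": doubling times,
    "n_final": population at termination}.
    """
    if steady_state.n_social != 0:
        raise ValueError("fixation protocol expects an all-asocial steady state")
    gen = np.random.default_rng(seed)
    state = steady_state.copy()
    mutant = int(gen.integers(0, state.n))
    state.social[mutant] = 1
    arrays = _make_arrays(state.x, state.y, state.social, params)
    n, done, code, _ = _drive(
        arrays, params, gen, max_steps, True, True, stop_homog=True
    )
    soc = arrays[2]
    if code == 1:
        outcome = "lost"
    elif code == 3:
        outcome = "fixed" if soc[:n].sum() == n else "lost"
    else:
        outcome = "undecided"
    return {"outcome": outcome, "t": done * params.dt, "n_final": int(n), "seed": seed}
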