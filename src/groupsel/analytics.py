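"""Closed-form and numeric theory for the group-structured model.

Single-group dynamics form an absorbing birth chain on occupancy
``n in {0, ..., K}``: each timestep the group survives with probability
``delta`` and, conditional on survival, gains one individual with
probability ``T_n = b (n/K) (1 - n/K)``.  Absorption at ``K`` is the
splitting threshold (group proliferates), absorption at 0 is group death.
The hitting probability ``psi_n`` of the threshold, its average over
interior states, the high-survival linearization, and the resulting
phase-boundary curves (critical death probability, critical social trait
strength ``a*``, critical cheater advantage ``b*``) are all evaluated
here, together with the embedded group-composition birth-death chain in
the rare-death limit and its fixation probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "SurvivalQuery",
    "PopulationQuery",
    "DegenerateWeightsError",
    "harmonic",
    "psi_exact",
    "psi_vector",
    "psi_mean",
    "psi_mean_high_survival",
    "delta_star",
    "mu_threshold",
    "solve_psi_half",
    "group_survival_probs",
    "social_thresholds",
    "mu_small_transitions",
    "fixation_prob_mu_small",
]


class DegenerateWeightsError(ValueError):
    """All group-death weights vanish (a = 1 with an all-cooperator population)."""


@dataclass(frozen=True)
class SurvivalQuery:
    """Single-group chain parameters.

    delta : per-step group survival probability, in [0, 1].
    b     : asocial reproduction scale factor, in [1, 4] (b = 1 for
            all-cooperator groups).
    K     : splitting threshold (sites per group), >= 2.
    """

    delta: float
    b: float
    K: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if not 1.0 <= self.b <= 4.0:
            raise ValueError(f"b must be in [1, 4], got {self.b}")
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")


@dataclass(frozen=True)
class PopulationQuery:
    """Population-level parameters for threshold curves.

    mu   : per-step probability that any group death occurs.
    N_g  : initial number of groups.
    N_gA : initial number of all-cooperator groups (0 <= N_gA <= N_g).
    a    : social trait strength, in [0, 1].
    K    : splitting threshold.
    K_g  : environmental carrying capacity in groups (optional; only used
           by callers that need it).
    """

    mu: float
    N_g: int
    N_gA: int = 0
    a: float = 0.0
    K: int = 10
    K_g: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.N_gA <= self.N_g:
            raise ValueError("require 0 <= N_gA <= N_g")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")
        if self.mu < 0.0:
            raise ValueError("mu must be >= 0")
        if self.K < 2:
            raise ValueError("K must be >= 2")


def harmonic(n: int) -> float:
    """n-th harmonic number H_n = sum_{k=1}^{n} 1/k by exact summation."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return sum(1.0 / k for k in range(1, n + 1))


def _t_plus(l: np.ndarray | float, b: float, K: int):
    """Conditional birth probability T_l = b (l/K)(1 - l/K)."""
    return b * (np.asarray(l, dtype=float) / K) * (1.0 - np.asarray(l, dtype=float) / K)


def psi_vector(q: SurvivalQuery) -> np.ndarray:
    """Hitting probabilities psi_n for n = 0..K as an array.

    psi_n = prod_{l=n}^{K-1} delta T_l / (1 - delta + delta T_l), with
    psi_0 = 0 and psi_K = 1.  Evaluated in log space for K > 200 to avoid
    underflow; plain running product otherwise.
    """
    K, delta, b = q.K, q.delta, q.b
    psi = np.zeros(K + 1)
    psi[K] = 1.0
    l = np.arange(1, K)  # interior states
    t = _t_plus(l, b, K)
    factors = delta * t / (1.0 - delta + delta * t)
    if K > 200:
        # cumulative sum of logs from the top state downwards
        logs = np.log(factors)
        tail = np.cumsum(logs[::-1])[::-1]
        psi[1:K] = np.exp(tail)
    else:
        acc = 1.0
        for n in range(K - 1, 0, -1):
            acc *= factors[n - 1]
            psi[n] = acc
    if delta == 1.0:
        psi[1:] = 1.0
    return psi


def psi_exact(n: int, q: SurvivalQuery) -> float:
    """Probability that a group starting at occupancy n reaches the threshold K."""
    if not 0 <= n <= q.K:
        raise ValueError(f"n must be in [0, K], got {n}")
    return float(psi_vector(q)[n])


def psi_mean(q: SurvivalQuery) -> float:
    """Average threshold-hitting probability over interior states n = 1..K-1.

    The average reflects the uniform allocation of parent individuals to
    daughters at splitting; <psi> > 1/2 is the proliferation criterion.
    """
    return float(psi_vector(q)[1 : q.K].mean())


def psi_mean_high_survival(q: SurvivalQuery) -> float:
    """High-survival linearization <psi> ~ 1 - (1-delta) H_{K-1} K^2 / (b (K-1))."""
    K = q.K
    return 1.0 - (1.0 - q.delta) * harmonic(K - 1) * K * K / (q.b * (K - 1))


def delta_star(b: float, K: int) -> float:
    """Survival probability at which the high-survival <psi> equals 1/2.

    delta* = 1 - (K-1) b / (2 H_{K-1} K^2); decreasing in b.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 1.0 <= b <= 4.0:
        raise ValueError("b must be in [1, 4]")
    return 1.0 - (K - 1) * b / (2.0 * harmonic(K - 1) * K * K)


def mu_threshold(N_g: int, b: float, K: int) -> float:
    """Critical death probability mu* = N_g (K-1) b / (2 H_{K-1} K^2).

    High-survival-limit proliferation boundary: for mu above this value a
    population of N_g groups is more likely to decline than to grow.
    """
    return N_g * (K - 1) * b / (2.0 * harmonic(K - 1) * K * K)


def solve_psi_half(
    target: str,
    q: PopulationQuery,
    b: float = 1.0,
) -> float | int:
    """Solve <psi(1 - mu/N_g, b, K)> = 1/2 for mu or for N_g.

    target = "mu"  : returns the root in mu on (0, min(1, N_g)) by
                     bisection to absolute tolerance 1e-8.
    target = "N_g" : returns the smallest integer N_g with <psi> >= 1/2
                     at the query's mu.

    Raises ValueError when the half level is unattainable on the bracket.
    """
    K = q.K

    def mean_at_mu(mu: float, n_g: float) -> float:
        return psi_mean(SurvivalQuery(delta=1.0 - mu / n_g, b=b, K=K))

    if target == "mu":
        # mu parameterizes delta = 1 - mu/N_g; the root may exceed 1, so the
        # bracket expands from [0, 1] toward mu -> N_g (delta -> 0) if needed.
        lo = 1e-12
        hi = min(1.0, 0.5 * q.N_g)
        f = lambda mu: mean_at_mu(mu, q.N_g) - 0.5
        if f(lo) < 0:
            raise ValueError("psi mean is below 1/2 already at mu ~ 0")
        while f(hi) > 0 and hi < q.N_g * (1.0 - 1e-9):
            hi = min(2.0 * hi, q.N_g * (1.0 - 1e-9))
        if f(hi) > 0:
            raise ValueError("psi mean does not cross 1/2 on the mu bracket")
        return float(bisect(f, lo, hi, xtol=1e-8))
    if target == "N_g":
        n = 1
        while n < 10**7:
            if q.mu / n < 1.0 and mean_at_mu(q.mu, n) >= 0.5:
                return n
            n += 1
        raise ValueError("no integer N_g below 1e7 attains psi mean 1/2")
    raise ValueError(f"unknown target {target!r}")


def group_survival_probs(q: PopulationQuery, mode: str) -> tuple[float, float]:
    """Per-step survival probabilities (delta_A, delta_B) of homogeneous groups.

    relative : delta_A = 1 - mu (1-a) / (N_g - a N_gA),
               delta_B = 1 - mu / (N_g - a N_gA); both decrease with N_gA.
    absolute : delta_A = 1 - mu (1-a) / N_g, delta_B = 1 - mu / N_g;
               independent of N_gA.
    """
    mu, a, N_g, N_gA = q.mu, q.a, q.N_g, q.N_gA
    if mode == "relative":
        denom = N_g - a * N_gA
        if denom <= 0:
            raise DegenerateWeightsError(
                "relative mode requires N_g - a*N_gA > 0 (a=1 with all-A population)"
            )
        return 1.0 - mu * (1.0 - a) / denom, 1.0 - mu / denom
    if mode == "absolute":
        return 1.0 - mu * (1.0 - a) / N_g, 1.0 - mu / N_g
    raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")


@dataclass(frozen=True)
class ThresholdResult:
    """Phase-boundary values with admissibility flags.

    a_star within [0, 1] and b_star within [1, 4] mark boundaries inside
    the admissible (a, b) square; out-of-range values are returned as
    computed with the corresponding flag set False.
    """

    a_star: float
    b_star: float
    a_star_in_range: bool
    b_star_in_range: bool


def social_thresholds(q: PopulationQuery, mode: str, a: float | None = None) -> ThresholdResult:
    """High-survival-limit critical social trait a* and cheater advantage b*.

    relative : a* = ((K-1) N_g - 2 mu H K^2) / ((K-1) N_gA - 2 mu H K^2);
               b*(a) = 2 mu H K^2 / ((K-1)(N_g - a N_gA)), evaluated at the
               caller-supplied a (default a = 0).
    absolute : a* = 1 - (K-1) N_g / (2 mu H K^2);
               b*  = 2 mu H K^2 / ((K-1) N_g); both constants in (a, b).
    """
    K, mu, N_g, N_gA = q.K, q.mu, q.N_g, q.N_gA
    c = 2.0 * mu * harmonic(K - 1) * K * K
    if mode == "relative":
        a_eval = 0.0 if a is None else a
        a_star = ((K - 1) * N_g - c) / ((K - 1) * N_gA - c)
        b_star = c / ((K - 1) * (N_g - a_eval * N_gA))
    elif mode == "absolute":
        a_star = 1.0 - (K - 1) * N_g / c
        b_star = c / ((K - 1) * N_g)
    else:
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    return ThresholdResult(
        a_star=a_star,
        b_star=b_star,
        a_star_in_range=0.0 <= a_star <= 1.0,
        b_star_in_range=1.0 <= b_star <= 4.0,
    )


def mu_small_transitions(
    N_gA: int, K_g: int, mu: float, a: float, mode: str
) -> tuple[float, float]:
    """Embedded chain transition probabilities (T_down, T_up) at capacity.

    In the rare-death limit the population sits at K_g groups, all at the
    splitting threshold, and the number of all-A groups performs a
    birth-death walk: a death event removes one group and the vacancy is
    refilled by a split of a surviving group.  Both fitness modes give
    the same down/up ratio 1 - a on interior states, hence identical
    fixation behavior.
    """
    if not 0 <= N_gA <= K_g:
        raise ValueError("require 0 <= N_gA <= K_g")
    i, n = float(N_gA), float(K_g)
    if N_gA == 0 or N_gA == K_g:
        return 0.0, 0.0
    if mode == "relative":
        w = i * (1.0 - a) + (n - i)  # total death weight
        t_down = mu * ((n - i) / n) * (i * (1.0 - a) / w)
        t_up = mu * (i / n) * ((n - i) / w)
    elif mode == "absolute":
        t_down = mu * (1.0 - a) * (i / n) * ((n - i) / n)
        t_up = mu * (i / n) * ((n - i) / n)
    else:
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    return t_down, t_up


def fixation_prob_mu_small(i: int, K_g: int, a: float) -> float:
    """Fixation probability of all-A groups from i of K_g in the rare-death limit.

    Standard absorbing birth-death closed form with constant backward/forward
    ratio 1-a:  phi_i = (1 - (1-a)^i) / (1 - (1-a)^{K_g}).  Neutral a = 0
    reduces to i / K_g; a = 1 fixes from any i >= 1.
    """
    if not 0 <= i <= K_g:
        raise ValueError("require 0 <= i <= K_g")
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must be in [0, 1]")
    if i == 0:
        return 0.0
    if a == 0.0:
        return i / K_g
    if a == 1.0:
        return 1.0
    r = 1.0 - a
    return float((1.0 - r**i) / (1.0 - r**K_g))
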