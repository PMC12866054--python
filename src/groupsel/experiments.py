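"""Replicate orchestration, outcome statistics and parameter sweeps.

Outcome statistics follow the sampling-at-T convention: a run that went
extinct before T contributes N_g(T) = 0, i.e. survival indicator 0 and
group/individual composition scores 0.  Replicate alpha of M uses seed
base_seed + alpha; sweep cells use independent SeedSequence spawn keys so
any sub-grid is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import (
    ModelParams,
    PopulationState,
    RunResult,
    init_heterogeneous,
    init_homogeneous,
    simulate,
)

__all__ = [
    "InitSpec",
    "ReplicateSet",
    "SweepResult",
    "run_replicates",
    "theta_mean",
    "outcome_S",
    "composition_score",
    "mean_S_over_a",
    "sweep_grid",
    "protocol_resource_limited",
    "RESOURCE_LIMITED_PARAMS",
]


@dataclass(frozen=True)
class InitSpec:
    """Initializer description: homogeneous (N_gA all-A + N_gB all-B groups
    with uniform occupancy) or heterogeneous (N_g mixed groups, each type
    count uniform on {0..K/2})."""

    kind: str  # "homogeneous" | "heterogeneous"
    N_gA: int = 0
    N_gB: int = 0
    N_g: int = 0

    def build(self, K: int, rng: np.random.Generator) -> PopulationState:
        if self.kind == "homogeneous":
            return init_homogeneous(self.N_gA, self.N_gB, K, rng)
        if self.kind == "heterogeneous":
            return init_heterogeneous(self.N_g, K, rng)
        raise ValueError(f"unknown init kind {self.kind!r}")


@dataclass
class ReplicateSet:
    """M independent runs; run alpha is reproducible from base_seed + alpha."""

    results: list[RunResult]
    M: int
    base_seed: int
    params: ModelParams
    init_spec: InitSpec

    def __iter__(self):
        return iter(self.results)


@dataclass
class SweepResult:
    """Aggregated statistic on a 2-D parameter grid."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    cells: np.ndarray  # shape (len(axis1), len(axis2))
    statistic: str
    T: int
    M: int
    base_seed: int


def run_replicates(
    params: ModelParams,
    init_spec: InitSpec,
    T: int,
    M: int,
    base_seed: int,
    rngs: Sequence[np.random.Generator] | None = None,
) -> ReplicateSet:
    """Run M independent replicates.

    Each replicate draws its initial population and its trajectory from a
    single Generator seeded with base_seed + alpha (or from the supplied
    per-replicate Generators, used by sweep cells).
    """
    results = []
    for alpha in range(M):
        rng = rngs[alpha] if rngs is not None else np.random.default_rng(base_seed + alpha)
        init = init_spec.build(params.K, rng)
        results.append(simulate(params, init, T, rng=rng))
    return ReplicateSet(results, M, base_seed, params, init_spec)


def _sample_at(run: RunResult, T: int) -> tuple[int, int, int, int]:
    """(N_g, N_gA, total_A, total_B) at time T; zeros if extinct before T."""
    if run.final_t < T:
        if run.outcome != "extinct":
            raise ValueError(f"run ended at t={run.final_t} < T={T} without extinction")
        return 0, 0, 0, 0
    i = T - int(run.times[0])
    return (
        int(run.n_groups[i]),
        int(run.n_groups_allA[i]),
        int(run.total_A[i]),
        int(run.total_B[i]),
    )


def theta_mean(reps: ReplicateSet, T: int) -> float:
    """Fraction of replicates surviving to T (mean of the survival indicator)."""
    return float(np.mean([_sample_at(r, T)[0] > 0 for r in reps.results]))


def outcome_S(run: RunResult, T: int) -> float:
    """Group-level outcome score S(T) = 2 N_gA(T)/N_g(T) - 1; 0 on extinction.

    N_gA counts groups containing no B individuals; +1 means every
    surviving group is all-A, -1 means none is.
    """
    ng, ngA, _, _ = _sample_at(run, T)
    if ng == 0:
        return 0.0
    return 2.0 * ngA / ng - 1.0


def composition_score(run: RunResult, T: int) -> float:
    """Individual-level score 2 n_A/(n_A+n_B) - 1 over all groups; 0 on extinction."""
    ng, _, tot_A, tot_B = _sample_at(run, T)
    if ng == 0:
        return 0.0
    return 2.0 * tot_A / (tot_A + tot_B) - 1.0


_STATS: dict[str, Callable[[RunResult, int], float]] = {
    "S": outcome_S,
    "composition": composition_score,
    "theta": lambda run, T: float(_sample_at(run, T)[0] > 0),
}


def mean_statistic(reps: ReplicateSet, T: int, statistic: str) -> float:
    f = _STATS[statistic]
    return float(np.mean([f(r, T) for r in reps.results]))


def mean_S_over_a(sweep: SweepResult) -> np.ndarray:
    """<S>_a: column-wise mean of <S(a, b)> over the a-axis for each b.

    Expects axis1 = a, axis2 = b.  At the harsh-environment reference
    parameters the profile is non-monotonic in b: near zero for small b
    (extinction-dominated), declining, then rising once both group types
    can proliferate.
    """
    if sweep.axis1_name != "a":
        raise ValueError("mean_S_over_a expects axis1 to be the social trait a")
    return sweep.cells.mean(axis=0)


def _cell_rngs(base_seed: int, i: int, j: int, M: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(base_seed, spawn_key=(i, j))
    return [np.random.default_rng(s) for s in ss.spawn(M)]


def sweep_grid(
    params_base: ModelParams,
    axis1: tuple[str, Sequence[float]],
    axis2: tuple[str, Sequence[float]],
    init_spec: InitSpec,
    T: int,
    M: int,
    base_seed: int,
    statistic: str = "S",
) -> SweepResult:
    """Aggregate a statistic over a 2-D parameter grid.

    Each cell (i, j) runs M replicates with an independent, deterministic
    seed stream derived from (base_seed, i, j, alpha); the aggregated
    statistic ("theta", "S" or "composition") is stored per cell.
    """
    name1, vals1 = axis1
    name2, vals2 = axis2
    cells = np.zeros((len(vals1), len(vals2)))
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            kw = {name1: v1, name2: v2}
            if "K" in kw:
                kw["K"] = int(kw["K"])
            params = ModelParams(**{**params_base.__dict__, **kw})
            reps = run_replicates(
                params, init_spec, T, M, base_seed, rngs=_cell_rngs(base_seed, i, j, M)
            )
            cells[i, j] = mean_statistic(reps, T, statistic)
    return SweepResult(
        axis1_name=name1,
        axis1_values=np.asarray(vals1, dtype=float),
        axis2_name=name2,
        axis2_values=np.asarray(vals2, dtype=float),
        cells=cells,
        statistic=statistic,
        T=T,
        M=M,
        base_seed=base_seed,
    )


def fixation_experiment(
    mode: str,
    M: int = 2000,
    base_seed: int = 0,
    K: int = 10,
    K_g: int = 10,
    mu: float = 0.01,
    a: float = 0.5,
    N_gA: int = 5,
    max_T: int = 1_000_000,
) -> dict:
    """Empirical fixation frequency of the social type in the rare-death limit.

    Initializes N_gA all-A plus K_g - N_gA all-B groups, all at the
    splitting threshold K (the population sits at its carrying capacity),
    and runs each replicate until one phenotype fixes.  In the mu << 1
    limit both fitness modes reduce to the same embedded birth-death
    chain with backward/forward ratio 1 - a, so the observed frequency
    should match analytics.fixation_prob_mu_small(N_gA, K_g, a).
    """
    params = ModelParams(K=K, K_g=K_g, mu=mu, a=a, b=1.0, mode=mode)
    n_A = np.concatenate([np.full(N_gA, K), np.zeros(K_g - N_gA, dtype=np.int64)])
    n_B = np.concatenate([np.zeros(N_gA, dtype=np.int64), np.full(K_g - N_gA, K)])
    outcomes = {"fixed_A": 0, "fixed_B": 0, "extinct": 0, "undecided": 0}
    for alpha in range(M):
        init = PopulationState(n_A.copy(), n_B.copy())
        run = simulate(params, init, max_T, seed=base_seed + alpha,
                       stop_when_homogeneous=True)
        if run.outcome == "extinct":
            outcomes["extinct"] += 1
        elif run.total_B[-1] == 0:
            outcomes["fixed_A"] += 1
        elif run.total_A[-1] == 0:
            outcomes["fixed_B"] += 1
        else:
            outcomes["undecided"] += 1
    decided = outcomes["fixed_A"] + outcomes["fixed_B"]
    freq = outcomes["fixed_A"] / decided if decided else float("nan")
    return {"mode": mode, "M": M, "freq_A": freq, **outcomes}


#: Resource-limited extinction protocol parameters: the carrying capacity
#: K_g sits below the proliferation threshold of all-A groups but above
#: that of all-B groups, so sociality taking over collapses the population.
RESOURCE_LIMITED_PARAMS = ModelParams(K=20, K_g=45, mu=0.5, a=0.75, b=4.0, mode="relative")

_COLLAPSE_SCENARIOS = ("allA", "allB", "mixed_homog", "heterog")


def protocol_resource_limited(
    params: ModelParams = RESOURCE_LIMITED_PARAMS,
    scenario: str = "mixed_homog",
    T: int = 5000,
    M: int = 50,
    base_seed: int = 0,
    N_g: int = 30,
) -> ReplicateSet:
    """Resource-limited extinction scenarios with N_g initial groups.

    allA / allB: homogeneous populations of one group type; mixed_homog:
    equal numbers of all-A and all-B groups; heterog: mixed groups with
    uniform type counts.  Full trajectories are recorded for each run.
    """
    if scenario not in _COLLAPSE_SCENARIOS:
        raise ValueError(f"scenario must be one of {_COLLAPSE_SCENARIOS}")
    if scenario == "allA":
        spec = InitSpec("homogeneous", N_gA=N_g, N_gB=0)
    elif scenario == "allB":
        spec = InitSpec("homogeneous", N_gA=0, N_gB=N_g)
    elif scenario == "mixed_homog":
        spec = InitSpec("homogeneous", N_gA=N_g // 2, N_gB=N_g - N_g // 2)
    else:
        spec = InitSpec("heterogeneous", N_g=N_g)
    return run_replicates(params, spec, T, M, base_seed)
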