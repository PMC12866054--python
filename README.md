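# groupsel

Multilevel-selection simulation and analytics for cooperator–cheater
coevolution in group-structured populations, with an agent-based biofilm
counterpart.

## The problem

Cooperators (social individuals, *A*) pay a growth cost for a trait that
protects their *group*; cheaters (asocial, *B*) skip the cost and
reproduce faster by a factor `b`.  When groups can die, split at a size
threshold `K`, and compete under a carrying capacity of `K_g` groups,
individual-level and group-level selection pull in opposite directions.
This package provides:

* a fast, seeded, discrete-time simulator of the group model with three
  group-fitness modes (`neutral`, `relative`, `absolute`);
* closed-form analytics: the threshold-hitting probability
  `psi_n = prod_{l=n}^{K-1} delta*T_l / (1 - delta + delta*T_l)` of a
  single group (with `T_l = b (l/K)(1 - l/K)` and per-step survival
  `delta`), the proliferation criterion `<psi> > 1/2`, the critical
  death probability `mu* = N_g (K-1) b / (2 H_{K-1} K^2)`, phase
  boundaries `a*` and `b*(a)`, and the rare-death fixation probability
  `phi_i = (1-(1-a)^i)/(1-(1-a)^{K_g})`;
* experiment orchestration (replicates, 2-D parameter sweeps, outcome
  statistics `<Theta>`, `S(T)`, composition scores);
* an off-lattice biofilm model where extracellular-matrix production is
  the social trait and death is restricted to the colony surface, with
  steady-state, seeding and mutant-fixation protocols.

The headline phenomenon: in harsh environments, cooperators persist
*only* when strong cheaters are present — fast-growing asocial groups
carry the population over the proliferation threshold, after which
group selection eliminates them.

## Worked example

```python
import numpy as np
import groupsel as gs

# harsh environment: death probability 0.7 per step, 20 initial groups
params = gs.ModelParams(K=10, K_g=70, mu=0.7, a=0.9, b=3.8, mode="relative")
init = gs.init_homogeneous(N_gA=10, N_gB=10, K=10, rng=np.random.default_rng(0))
run = gs.simulate(params, init, T=3000, seed=1)
print(run.outcome, run.n_groups[-1], run.n_groups_allA[-1])
# survived 70 70

# theory: critical cheater advantage at a=0 and critical social trait
q = gs.PopulationQuery(mu=0.7, N_g=20, N_gA=10, K=10)
th = gs.social_thresholds(q, "relative", a=0.0)
print(round(th.b_star, 5), round(th.a_star, 5))
# 2.20031 0.70594
```

The run survives with all 70 groups all-cooperator: at `b = 3.8` the
cheater groups first multiply the population above the survival
threshold, then lose to the protected cooperator groups.  The two
printed numbers are the analytic phase boundaries: below
`b* ≈ 2.2` (at `a = 0`) the whole population would instead go extinct,
and `a* ≈ 0.706` is the social-trait strength above which cooperator
proliferation requires progressively stronger cheaters.

The same model family is exposed on the command line:

```bash
groupsel analytic --k 10 --n-g 20 --n-g-a 10 --mu 0.7 --mode relative --out thresholds.csv
groupsel simulate --preset collapse --seed 1 --out runs/
groupsel sweep --preset relative-landscape-small --seed 1 --out sweep/
groupsel biofilm seed --phenotype asocial --trials 10 --seed 1 --out biofilm/
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time: the
maximal admissible cheater advantage (`b = 4`) from the reproduction
probabilities; the common value of `psi_n` across all start states when
group death is absent (`delta = 1`); and the biofilm seeding success
counts out of 100 independent trials for each founder phenotype.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes about a minute (dominated by the 200 seeded biofilm
colonies plus one-time JIT compilation) and writes one JSON object with
a value and problem size per quantity.

## Layout

- `src/groupsel/model.py` — group-structured simulator (numba-fused loop)
- `src/groupsel/analytics.py` — hitting probabilities, thresholds, fixation
- `src/groupsel/experiments.py` — replicates, statistics, sweeps, protocols
- `src/groupsel/biofilm.py` — off-lattice biofilm agent-based model
- `src/groupsel/config.py`, `cli.py` — validated configs, presets, CLI
- `docs/methods.md` — model assumptions, parameter meanings, numerical
  choices and known limitations
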