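# Methods

`groupsel` simulates and analyzes a two-level selection model of
cooperator–cheater coevolution: stochastic birth of individuals inside
groups, death and fission of whole groups, and — as a mechanistic
counterpart — an off-lattice biofilm in which the same tension between
individual growth cost and group-level protection arises from spatial
structure alone.

## Group-structured model

### State and elementary processes

A population is a set of groups; group *j* holds `n_A` cooperators
(social individuals, type A) and `n_B` cheaters (asocial, type B) on
`K` sites, the remaining sites being unconsumed resources.  Every
discrete timestep applies, in order:

1. **Reproduction** (parallel over groups).  With the entry composition,
   one new A appears with probability `(n_A/K)(1 - n/K)` and one new B
   with probability `b (n_B/K)(1 - n/K)`, `n = n_A + n_B`.  The factor
   `b ∈ [1, 4]` is the cheater's growth advantage; the two probabilities
   sum to at most 1 precisely when `b ≤ 4` (maximum at `n_A = 0`,
   `n_B = K/2`).  A full group (`n = K`) cannot reproduce.
2. **Group death** (at most one per step).  A death event occurs with
   probability `mu`; the victim is chosen by weights `w_j = 1 - a f_j`,
   where `f_j` is the cooperator fraction of group *j* and `a ∈ [0, 1]`
   the social trait strength.
   * *neutral*: uniform victim (`a` ignored), total death probability
     exactly `mu`;
   * *relative*: victim drawn with normalized weights, total exactly
     `mu` — protection of one group necessarily redistributes risk onto
     the others;
   * *absolute*: a uniformly selected group is killed with probability
     `w_j` (select-then-kill), so the total death probability is `≤ mu`
     and each group's risk depends only on its own composition.
3. **Splitting** (at most one per step).  If the number of groups is
   below the carrying capacity `K_g` and at least one group is full, one
   full group (uniform) is replaced by two daughters with
   `m_A ~ U{0..n_A}`, `m_B ~ U{0..n_B}` members; an empty daughter is
   discarded (abortive split — membership unchanged).

A run terminates at the horizon `T` or at extinction.  Statistics follow
the sampling-at-`T` convention: extinct runs contribute survival 0 and
score 0.

### Analytics

A lone group is an absorbing birth chain on `n ∈ {0..K}`: it survives a
step with probability `delta` and then gains a member with probability
`T_n = b (n/K)(1 - n/K)`.  The threshold-hitting probability is the
product

    psi_n = prod_{l=n}^{K-1} delta T_l / (1 - delta + delta T_l),

and `<psi>` — its mean over interior states, reflecting the uniform
daughter allocation — exceeds 1/2 exactly when a daughter group is more
likely to split again than to die, the proliferation criterion.  With
the time-0 bound `delta = 1 - mu/N_g` frozen (the population-level
approximation used throughout; time-varying `delta` is out of scope),
expanding `<psi>` to first order in `1 - delta` gives

    <psi> ≈ 1 - (1 - delta) H_{K-1} K^2 / (b (K-1)),

with `H` the harmonic number, hence the critical death probability
`mu* = N_g (K-1) b / (2 H_{K-1} K^2)` and, via the mode-specific group
survival probabilities `delta_A`, `delta_B`, the phase boundaries `a*`
and `b*(a)` in the social-trait / cheater-advantage plane.  The
expansion parameter is `eps = (1-delta) H_{K-1} K^2 / (b(K-1))`; the
linearization is accurate for `eps ≪ 1` and degrades visibly once
`eps ≳ 0.1` (at `delta = 0.999`, `b = 1` this means `K ≳ 40`).  The
exact `<psi> = 1/2` level set is found by bisection (absolute tolerance
1e-8, bracket expanded in `mu` up to `delta → 0`); integer targets
(`N_g`) return the smallest integer satisfying the criterion.  `psi`
products switch to log space for `K > 200` to avoid underflow.

In the rare-death limit (`mu ≪ 1`, population pinned at `K_g` groups,
every group at the splitting threshold between death events), the count
of all-A groups performs an embedded birth–death walk whose
backward/forward ratio is `1 - a` in *both* fitness modes, giving the
common fixation probability

    phi_i = (1 - (1-a)^i) / (1 - (1-a)^{K_g}).

The closed form is the standard absorbing birth–death solution; it is
validated in the tests against an exhaustive linear-system solve and
against both simulators.

### Numerical and design choices

* Event order within a step is reproduction → death → split: a group
  that fills this step splits this step only if it survives death.  The
  three processes are defined per step without an intrinsic order; this
  is one admissible serialization and is fixed for reproducibility.
* `U(0, n)` is the inclusive discrete uniform `{0, ..., n}`.
* Either daughter may be empty; both cases abort symmetrically.
* Relative mode with `a = 1` and an all-cooperator population has zero
  total death weight; `death_probs` and the simulator raise
  `DegenerateWeightsError` rather than divide (the reference heatmap
  grids step `a` by 0.033 from 0 and never hit `a = 1` exactly).
* Homogeneous initial groups draw occupancy uniformly from
  `{1, ..., K-1}`, mirroring the averaging over initial states in
  `<psi>`; heterogeneous groups draw each type count from
  `U{0..K/2}`, redrawing the (0,0) outcome because empty groups are
  undefined.
* Replicate α uses seed `base_seed + α`; sweep cells spawn independent
  `SeedSequence` streams keyed by `(base_seed, i, j)`, so any sub-grid
  reruns identically in isolation.  Fixed seeds give bit-identical
  trajectories (the step functions and the fused numba kernel share one
  `numpy.random.Generator`).

## Biofilm model

Cells live at continuous 2-D positions above a line of 400 substrate
anchors with spacing `D` (the model's length unit).  Social cells
produce extracellular matrix: their attraction constant is `100 G` with
`G = H/D^4` calibrated so an asocial pair is force-free at separation
`D`, and they divide five-fold slower.  Each step runs motion →
division → removal:

* **Motion** — pairwise pseudo-force `H/d^6 - (G_p + G_q)/(2 d^2)` plus
  anchor terms with the cell's own `G/2`; the unit force direction is
  blended with a random unit vector (weight `F = 0.5`), the cell moves
  exactly `D`, reflects at the substrate (`y ≥ 0`) and at the domain
  ends, and receives a uniqueness jitter of `1e-3 D` per coordinate.
* **Division** — per phenotype a Poisson count with the logistic mean
  `n r (1 - N/K_BF) dt` (clamped at zero above capacity), `r = ln 2`
  for asocial cells, `r/5` for social; offspring appear at the parent
  plus `1e-2 D` displacement.
* **Removal** — the topmost cell per substrate window of width `D` forms
  the predation interface of size `m`; a Poisson count with mean
  `m L dt` (`L = 0.1`) of interface cells is removed.  Bulk cells never
  die.

Time is measured in asocial doubling times: `dt = 0.01`, so one doubling
is 100 steps.  Protocols: *steady state* (500 cells relax 1000 steps
with `F = 0` and no birth/death, then 20 000 full steps), *seeding* (a
single founder; success when the population exceeds 300 cells before
extinction), *fixation* (relabel one cell of an asocial steady state
social; run until one phenotype remains).

### What the stated world does and does not reproduce

A 500-cell asocial steady-state colony in this geometry is compact:
measured footprint ≈ 22 `D` (calibration run, seed 42), so the interface
holds ≈ 22 cells and the per-step removal mean is ≈ 0.022 — the
population equilibrates within a few cells of `K_BF`.  Two consequences:

* **Seeding** success rates come out higher than the reference counts
  (84/100 asocial, 39/100 social at seed 800 versus 72 and 19): early
  predation relative to growth is about half as strong here.  The
  reference geometry is underdetermined (1-D line of anchors versus 2-D
  anchor grid in a 3-D simulation, interface window width, domain span);
  these choices are fixed a priori in this package and are not tuned.
  The qualitative result — non-producers seed several-fold more
  successfully than producers — is robust.
* **Fixation** of a single social mutant is slow: with the population a
  few cells below `K_BF`, the logistic factor throttles all division, and
  the protected mutant lineage expands on the scale of millions of
  timesteps rather than the tens of thousands a more strongly predated
  colony would need.  Protocol runs therefore take a `max_steps` budget
  and report `undecided` honestly when neither absorption occurs.

The model deliberately omits nutrient fields, matrix diffusion, and
mechanical pressure; it is a minimal demonstration that interface-
restricted death plus a growth-costly adhesion trait reproduces the
group-model phenomenology, not a calibrated biofilm simulator.

## Scaled-down presets

The full reference heatmaps (≈ 900–3000 cells × 50 replicates × 3000–
5000 steps) are not desk scale; `*_small` presets with coarser grids and
`M = 10` are provided as first-class configurations.  The acceptance
tests state in their docstrings where a protocol is scaled down and what
the full-scale counterpart is.
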