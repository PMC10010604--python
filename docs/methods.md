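# Methods

## Model

`confinesim` describes a tumour as a set of clones, each a triplet
(c_a, c_n, c_M) of alive cells, necrotic cells, and a shared mutation set.
Four assumptions underpin the model: (i) driver mutations are rare and
carry non-negative fitness effects; (ii) the population is well mixed (no
explicit cell positions); (iii) the tumour is spherical with one cell per
unit volume; (iv) growth is confined to a proliferating shell.

Time advances in discrete steps. The per-step turnover probability
`step_size` plays the role of both the death probability and the baseline
birth probability, so the unmutated, unconfined system is homeostatic
(birth and death probabilities equal); each clone's birth probability is
then scaled by its fitness and by the confinement fractions, and clamped
into [0, 1]:

    p_death = step_size
    p_birth = min(1, fit(c) · frac(C) · local(c) · step_size)
    p_necro = 1 − frac(C) · local(c)

Births, deaths, mutated newborns and newly necrotic cells are independent
binomial draws from the step-start counts (simultaneous-update semantics:
deaths are never taken from the step's newborns, and the global fraction
`frac` and each clone's `local` are computed once per step from the
step-start state). Each mutated newborn founds a new one-cell clone whose
mutation set extends its parent's by one fresh id (infinite sites). At most
one driver per division is allowed; with realistic mutation probabilities
(θ_mut ≪ 1) this is immaterial.

Fitness is additive: fit(c) = 1 + Σ F(m). The founder's identifying
mutation carries effect 0, so the unmutated system has fitness exactly 1 —
required for homeostasis. Newly drawn effects come from one of four
distributions with mean ≈ θ_fit: `const` (point mass), `uni` (uniform on
[0, 2θ_fit]), `exp` (exponential), `norm` (normal with location θ_fit and
scale θ_fit/2 truncated to [0, ∞)). The truncation places the lower bound
two standard deviations below the location, giving expectation
1.0276·θ_fit (the scale θ_fit/2 is fixed by that printed expectation).
Children always draw an effect; with θ_fit = 0 every distribution is the
point mass at zero and no generator state is consumed.

### Confinement geometry

The tumour volume equals C_a + C_n. The core radius is
max(r_total − 1/θ_conf, 0) with r_total = (3(C_a+C_n)/4π)^{1/3}; the shell
volume is the total volume minus the core volume, and the shell fraction
is min(shell_volume / C_a, 1), with the conventions frac = 0 for an
extinct population and frac = 1 for θ_conf = 0. The clamp reading is
deliberate: the fraction must be a probability for the necrosis complement
1 − frac·local to make sense, and for θ_conf → 1 the shell volume
approaches the sphere's surface area (surface growth), for θ_conf → 0 the
whole sphere proliferates. `local` is the same function applied to a
single clone's own (c_a, c_n) with θ_local.

A consequence worth knowing when choosing scales: under global
confinement every clone accrues its own necrotic cells, which inflate the
clone's volume and keep its *local* shell fraction clamped at 1 until the
clone is both large and fast-growing. Combined confinement
(θ_conf > θ_local > 0) therefore behaves exactly like global-only
confinement until populations approach ~10⁷ cells, which is where the
linear-to-branched transition emerges.

### Runs, restarts, checkpoints

Runs start from C⁰ = {(1, 0, {m₀})} (configurable `init_cells` for
calibration experiments that start from 100 cells). Stop conditions are
checked after each full step in the order extinction, population ceiling
(C_a + C_n > max_pop), step ceiling (t = max_steps). A run that terminates
below `min_pop` total cells before `max_steps` is discarded and restarted
from a fresh deterministic sub-stream derived from (seed, restart index),
so results are reproducible regardless of how many restarts occur.
`max_restarts` defaults to 1000 as a guard against pathological
parameters; at the default parametrization (θ_mut = 2·10⁻⁵) the expected
number of restarts from a single founder cell is itself on the order of
several hundred — roughly 1/√(θ_mut · E[F/(1+F)]) — so experiments
routinely pass a much larger cap.

Checkpoints (totals plus both metrics) are recorded the first time the
alive population reaches each power of two, collapsed to one record per
step when growth jumps several thresholds, anchored at one cell; the
terminal state is always recorded as a final checkpoint, because with
confinement the stop condition acts on C_a + C_n and the last
alive-doubling may long precede termination. A run's summary point is the
final checkpoint at which the metrics are defined (rare accepted runs end
extinct with a necrotic core above `min_pop`).

### Defaults

| parameter | default | meaning |
|---|---|---|
| `step_size` | 0.01 | turnover probability per step; calibrated so homeostatic populations of ≥100 cells essentially never die within 1000 steps |
| `min_pop` | 1000 | minimum final population for a run to count |
| `max_pop` | 1000·2²⁰ | ≈10⁹ cells ≈ >1 cm³ tumour; 20 doublings from `min_pop` |
| `max_steps` | 10⁶ | ≈10⁴ founder generations at step_size 0.01 |
| θ_mut | 2·10⁻⁵ | driver probability per division (literature-derived) |
| θ_fit | 0.1 | mean fitness gain per driver (literature-derived) |
| `dist` | `exp` | fitness-effect distribution |
| θ_conf, θ_local | 0 | confinement off unless studied |
| `metric_cutoff` | 0.001 | population-fraction filter for metrics; the source analyses state a cutoff exists but not its value — 0.001 is this package's configurable choice, and driver medians proved insensitive to it over 0.001–0.02 |

## Metrics

Mean drivers per cell d̄ = Σ |c_M| c_a / C̃_a and clonal diversity
D = (Σ (c_a/C̃_a)²)⁻¹ are computed over the filtered clone set
C̃ = {c : c_a ≥ C_a · cutoff} using alive cells only; necrotic cells never
enter the metrics. D has floor 1 (single clone), equals k for k equal
clones, and is robust to clones of vanishing relative size. Muller-plot
and phylogeny exports use a separate 1% display cutoff: only clones whose
alive fraction ever reached 1% at a checkpoint appear, with non-displayed
ancestors contracted out of the tree and clones ending below 1000 alive
cells flagged extinct (`x` suffix).

## Fitting

A dataset is a set of per-sample (d̄, D) points. Simulations are scored
against it with the symmetric mean nearest-neighbour distance
S(X_s, X_d) = mean_s min-dist-to-data + mean_d min-dist-to-sim in the raw
(d̄, D) plane — no axis normalization, matching the score's definition;
users should be aware the two axes have different natural scales.
`grid_fit` runs a batch of seeded simulations per (θ_conf, θ_local) grid
cell (default grid {0, 0.125, 0.25, 0.5, 1, 2}²), pools each cell's final
points into one cloud, and scores the pool (per-run scoring with
averaging is available via `pooling="per_run"`; pooling is the default as
the score is defined between the full simulation set and the data).

## Implementation and numerics

The public per-step semantics live in the object layer
(`core.step_clone`, `engine.advance`), which follows a strict
reproducibility contract: one seeded `numpy.random.Generator` per run,
clones processed in ascending clone id, draws ordered B_d, B_b, B_m, B_n,
then one fitness effect per child, with degenerate draws (n = 0 or p = 0,
or θ_fit = 0 effects) skipped without consuming generator state. Skipping
makes the model's reduction chain literal: θ_local = 0 consumes the exact
stream of a global-only model, θ_conf = 0 of a mutation/fitness-only
model, θ_mut = 0 of pure turnover — which the test suite verifies
bitwise against independently written sub-model simulators.

`engine.run` executes whole runs through a numba-jitted array kernel
(`_kernel.py`): the restart phase burns millions of tiny steps per
accepted run, which is far beyond what per-clone Python objects can
sustain. The kernel stores clones as flat arrays (mutation sets are never
materialized — each clone's set is its lineage path, and the driver count
is depth + 1), retires clones with no alive cells from the stepping loop
while keeping their necrotic volume in the totals, and reseeds its own
generator per attempt. Kernel and object layer are cross-checked
distributionally in the tests (Kolmogorov–Smirnov on homeostatic final
sizes; chi-square of clone-level binomials against a per-cell Bernoulli
oracle at α = 0.001).

Numerical details: binomial draws with p ≥ 1 return n deterministically;
the truncated normal is sampled by rejection (acceptance ≈ 0.977);
population totals use 64-bit integers (safe beyond 10¹⁸ cells); diversity
is computed as (Σc_a)²/Σc_a² in float64. Ties in the fitting grid resolve
to the lexicographically smallest (θ_conf, θ_local) pair.

## Synthetic data

`fixtures.generate_fixture` emits per-sample (d̄, D) tables clustered
where the four evolutionary modes live: `nonspatial` (drivers ≈ N(2.0,
0.6), diversity 1 + |N(0, 0.35)|), `linear` (N(5.7, 1.2), 1 + |N(0,
0.9)|), `branched` (N(4.0, 1.0), lognormal around 80), `mixed` (N(8.2,
1.5), lognormal around 12.6), clipped to d̄ ≥ 1, D ≥ 1. The centres
follow the metric signatures of the four regimes; the spreads are chosen
to resemble the sample scatter of small multi-sample cohorts. These
fixtures mimic only the location and spread of cohort summary points —
not sampling noise, sequencing error, or within-tumour sampling design —
so tests passing against them show the fitting machinery ranks
confinement regimes correctly, not that any particular real cohort would
be fit well. Parameter-recovery tests instead use `simulate_dataset`,
which builds the dataset from actual runs at a known grid cell.

## Problem sizes used by the test suite

Stochastic end-to-end checks run at the following scales, chosen to keep
the default suite within a practical wall-clock budget while testing each
claim at the scale where it holds: truncated-normal calibration with 10⁶
Monte-Carlo draws; turnover calibration with 1000 replicates × 1000 steps
(plus 100 replicates at step_size 0.1 for the converse); unconfined-mode
signature as a scaled surrogate (50 runs to 10⁶ cells; full-size driver
burden grows logarithmically with population size, so the surrogate
asserts the qualitative signature: median d̄ < 3, median D < 2);
mid-sweep frequency at full size (100 runs to 1000·2²⁰ cells at θ_conf =
0.5, expecting the mid-sweep fraction P(D ≤ 1.5) ≈ 0.39 ± 0.10);
mode ordering at full size (20 runs per condition: none, θ_conf = 0.5,
θ_local = 0.5, and (0.5, 0.125)); oracle equivalence with 10⁵ (and 5·10⁴)
replicates; parameter recovery on the reduced grid {0, 0.5, 2} × {0, 0.5}
at 10⁶ cells, 20 runs per cell, 5 repetitions.

## Known limitations

- The geometry is strictly spherical; non-spherical or anisotropic
  confinement is out of scope (any growth law sublinear in population
  size could replace the shell construction).
- Fitness accumulation is additive only; the sampler is the single
  extension point for other accumulation schemes.
- Necrotic cells never degrade; tumour volume is monotone, which is what
  makes deep-confinement runs terminate by total volume rather than alive
  count.
- Metrics describe clone-level composition; there is no single-cell
  sampling noise model, so comparisons to sequencing-derived cohort
  points inherit whatever biases produced those points.
- Under the default parametrization, full-size unconfined runs in this
  implementation centre near a median of ~2.8 drivers per cell and
  diversity ~1.5; directional behaviour across confinement regimes and
  the mid-sweep frequency reproduce the reference behaviour, but exact
  unconfined driver medians are sensitive to conventions (metric cutoff,
  checkpoint timing) that the available description does not fully pin
  down.
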