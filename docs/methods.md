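# Methods

This note documents the models, estimators and numerical choices behind
`scfskit`, in the order data flows through the pipeline.

## Generative model (synthetic_data)

The synthetic module emulates the statistical structure of a single-cell
force spectroscopy (SCFS) adhesion study of fibroblast lines expressing
different fibronectin-binding integrin classes.

**Mean force profile.** For each condition the mean adhesion force over
contact time t is a saturating exponential

    F̄(t) = f_floor + f_max · (1 − exp(−t/τ)),

the simplest three-parameter monotone curve with a plateau, matching the
qualitative "strengthening with contact time" shape of such experiments.
`f_floor` (N) is the nonspecific adhesion level (the pan-knockout control is
floor-only, `f_max = 0`), `f_max` (N) the specific plateau, `τ` (s) the
saturation timescale. Parameters are configuration, not code.

**Variability.** A measured force is
`max(0, e_c · F̄(t) + N(0, meas_sd))`, where `e_c` is a per-cell lognormal
multiplier with unit mean and relative s.d. `cell_sd_rel` (default 0.25),
drawn once per cell and shared across all contact times — this reproduces
both the long-tailed single-cell dot clouds and the within-cell correlation
across times that makes whole-cell bootstrap resampling the correct unit.
`meas_sd` (default 0.15 nN) is within-cell measurement noise. The truncation
at zero reflects that adhesion forces are reported as non-negative
magnitudes. No quantitative variance decomposition is available from
published dot plots, so these defaults are assumptions, stated once and not
tuned.

**Default study conditions.** Four conditions mirror the experimental cell
lines: a floor-only control (`pKO`, 0.15 nN), an αV-class-only line
(`pKO-aV`, plateau 1.6 nN, τ = 60 s), an α5β1-only line (`pKO-b1`, plateau
3.6 nN, τ = 45 s — roughly twice the 120 s adhesion of the αV-carrying
lines, the published competition signature) and the double-reconstituted
line (`pKO-aV-b1`, plateau 1.8 nN, τ = 60 s). Magnitudes are in the nN
range typical for fibroblast SCFS at these contact times; the published
figure data are not deposited, so only the qualitative pattern (floor-only
control; β1-only ≈ 2× at 120 s) is constrained. Single-molecule binding
probabilities use the published values: 0.25 (unperturbed double line),
0.40 (α5β1 blocked), 0.12 (αV class blocked), 0.10 (nonspecific).

**Retract curves.** A curve's retract force is the pointwise minimum of a
cell-detachment ramp (−F at the surface, relaxing linearly to baseline over
the first 40% of travel) and per-event loading ramps that descend to −step
over 50 samples and jump back to baseline at the event position, plus linear
baseline drift (`drift_slope · height`) and i.i.d. Gaussian force noise
(`noise_sd`, default 10 pN). Events are confined to the first 70% of travel
so the final 30% is guaranteed clean baseline for tail fitting. Before
noise, the baseline-corrected global minimum is exactly
−max(F, largest event step); with no events it is −F, which provides the
construction oracle used throughout the tests. Default acquisition follows
common practice: 0.06 N/m cantilever, 5 µm/s retract, 2 nN cell-scale
setpoint (200 pN single-molecule), 310 K. The synthetic retract range is
5 µm at 2 kHz (2,000 samples; 2 µm for single-molecule curves) — a
down-scaled but structurally faithful trace chosen to keep simulation
studies cheap.

**Rupture forces.** Single-molecule rupture forces are truncated normal,
mean 60 pN, s.d. 15 pN, floor 20 pN. Published rupture forces are not
reported for this assay; the distribution was chosen to sit above the
default noise floor so that detection is threshold-limited, and it is fully
configurable.

**Thermal noise.** Deflection traces are i.i.d. Gaussian with equipartition
variance k_B·T/k, plus optional linear drift. This intentionally omits the
Lorentzian spectral shape of a real cantilever: the calibration estimator is
the simple equipartition form, and the generator is its exact inverse.

**Seeding.** One master seed; the generator for condition i, cell j is
`default_rng(SeedSequence([seed, i, j]))`. Adding a condition or cell never
perturbs existing draws, and a fixed configuration reproduces every output
file byte-for-byte.

**What the generator does not emulate.** No cell mechanics (cortical
tension, membrane tethers, WLC elasticity), no approach-segment indentation,
no spatial structure, no drift nonlinearity, no correlated (1/f) force
noise. Passing tests therefore demonstrate correctness of the estimators
under the stated statistical model, not robustness to every instrumental
artefact of real curves.

## Curve processing

**Baseline.** Ordinary least squares on the far tail of the retract segment
(final 30% of travel, ≥ 10 samples required), one pass of outlier rejection
at 3× the robust noise scale (MAD/0.6745), then refit. The fitted line is
subtracted from the whole retract segment; the robust noise s.d. of the tail
residuals is carried in the curve metadata. The operation is idempotent to
within tail noise. Vendor software performs an equivalent correction with
unpublished rules; the rules here are explicit and configurable
(`tail_fraction`).

**Adhesion force.** −min(corrected retract force), clipped at zero (a
pure-noise curve reports 0, not a small negative). This is definitionally
identical to the brute-force array minimum, and the test suite asserts exact
equality on mixed noise/drift batches.

**Rupture events.** An event is an upward force step completed within a
short window (default 5 samples) preceded by a negative (adhesive)
excursion. Because single-bond steps can be only a few times the per-sample
noise, both detector statistics are window means over `avg_window = 10`
samples: a candidate index requires (i) post-gap mean − pre-gap mean
> k_sigma · σ·√(2/10) and (ii) pre-gap mean < −k_sigma · σ/√10, with
k_sigma = 5 and σ the robust tail noise. Runs of adjacent candidates are
merged, keeping the largest step. With 10 pN noise this resolves steps down
to roughly 25 pN while holding the false-event rate per pure-noise curve
well below 1%. On noise-free curves (σ = 0) any strictly positive step after
a negative excursion qualifies, and localisation is exact to one sample.

**Specific binding.** A single-molecule curve is called bound iff ≥ 1
rupture event is detected and the minimum of the 10-sample running mean of
the corrected force lies below −k_sigma·σ/√10. Using the averaged minimum
(rather than the raw sample minimum) keeps the depth check consistent with
the step check: a raw-minimum rule at 5σ = 50 pN would censor every rupture
below ~50 pN and bias the binding probability down by several points in the
0.25–0.40 regimes. The binding probability is estimated per cell (binomial
MLE: bound fraction) and summarised as mean ± s.d. over cells with the
pooled curve count n; a single-cell group reports s.d. 0 with
`sd_defined=False` rather than NaN.

**Spring constant.** Linear detrend then k = k_B·T/var(deflection)
(sample variance, ddof = 1). No power-spectral-density fit and no mode-shape
correction factors: the estimator is exactly testable against the
equipartition generator, is scale-equivariant (k(c·x) = k(x)/c²), and
recovers 0.06 N/m within 3% at n = 10⁵. Traces shorter than 10³ samples or
with zero variance are rejected.

## Statistics

**Medians and Mann–Whitney.** Per-condition, per-time sample medians
(midpoint rule for even n). Median comparisons use the two-tailed
Mann–Whitney U test: exact null distribution for tie-free samples with both
n ≤ 8 (verified in tests against full enumeration of rank assignments),
tie-corrected normal approximation with continuity correction otherwise.

**Adhesion strengthening.** The slope statistic is the unweighted mean of
discrete slopes (F₂−F₁)/(t₂−t₁) over consecutive pairs of the sorted
contact-time grid, computed from per-time medians. On an exactly linear
profile it recovers the rate for any grid; it requires ≥ 2 time points.

**Bootstrap.** Resampling draws whole cells with replacement — the cell is
the repeated-measures unit, since one fibroblast is probed at all contact
times — and all groups are resampled to the smallest group's cell count
("samples of equal size"). Default B = 100 replicates (the study's choice;
p-value granularity at B = 100 is coarse, and B is configurable with a
minimum of 10). Within the slope test both groups draw resampling indices
from identically seeded generators, so comparing a dataset with itself under
one seed yields identical replicates and p = 1 exactly.

**Inference on bootstrap replicates.** Two methods are implemented:

* `percentile` (default): the two-sided bootstrap percentile test,
  p = 2·min(#{d_b ≤ 0}, #{d_b ≥ 0})/B, applied to the replicate slope
  difference (slope test) or the replicate ε (interaction test, per time).
  This is the standard bootstrap hypothesis test: under the null the
  observed statistic is of the same order as the bootstrap spread, and the
  rejection rule is equivalent to checking whether 0 falls outside the
  central bootstrap interval. The acceptance tests measure its operating
  characteristics at the study's design size (10 cells/condition, B = 100,
  200 simulated experiments): per-time null rejection within [0.01, 0.08]
  at α = 0.05, power ≥ 0.9 against a twofold slope ratio, and ≥ 0.9
  detection of the competition-scenario negative ε at 120 s.
* `wilcoxon`: a two-tailed Wilcoxon applied directly to the B bootstrap
  replicates — rank-sum between the two groups' replicate slopes, or
  one-sample signed-rank of the replicate ε against zero (Pratt handling of
  zeros, normal approximation for B ≥ 20). Treating replicates as B
  exchangeable observations ignores that their spread *is* the sampling
  uncertainty of one observed statistic, so the test is strongly
  anti-conservative: a characterisation test in the suite shows it
  rejecting a true additive null in well over half of simulated
  experiments. It is retained because the procedure appears in the applied
  literature; it is not recommended for inference, and the default is the
  calibrated percentile method.

**Interaction statistic.** ε = F_AB + F_0 − F_A − F_B on per-condition
medians per contact time, evaluated per bootstrap replicate. Per-time
p-values are reported raw and Holm-adjusted across the time grid; the
pooled p is the smallest Holm-adjusted value, so both per-time and
whole-grid readings are available. The per-time sign
(positive/negative/none) uses the raw p against α (default 0.05) and the
median replicate ε.

## Degenerate inputs and tie-breaks

Errors are raised for: negative contact times; non-positive τ, spring
constant or temperature; events outside (or in the reserved tail of) the
retract range; retract tails under 10 samples; empty cell groups; B < 10;
fewer than 2 shared contact times; unknown or missing condition labels
(named in the message); duplicate (cell, condition, time) records; unknown
configuration keys. Ties: Mann–Whitney falls back to the tie-corrected
normal approximation; signed-rank zeros use Pratt's method; the percentile
p counts zeros on both sides (a replicate difference of exactly 0
contributes to both tails, pushing p toward 1, the conservative direction).

## Problem sizes

Defaults follow the study design: contact times {5, 20, 50, 120} s, 10
cells per condition, one curve per cell and time. Simulation studies in the
tests and the acceptance script use 200 (tests) or 100 (script) simulated
experiments for rejection rates, 20 cells × 200 curves per single-molecule
regime, 1,000 curves for recovery error, and 10⁵-sample thermal traces —
sizes chosen to give stable Monte-Carlo estimates while keeping a full run
in tens of seconds.

## Known limitations

* The event detector and baseline rules are this package's explicit choices;
  equivalence with proprietary vendor software cannot be asserted.
* ε is defined on medians of independent condition samples; no mixed-effects
  modelling of the cell hierarchy is attempted.
* The percentile bootstrap test at n = 10 cells relies on the bootstrap
  approximation for medians at small n; its measured level (≈ 0.03–0.06) is
  close to, but not exactly, nominal.
* Binding-probability recovery assumes the generator's rupture-force scale;
  real assays with rupture forces near the noise floor would need a lower
  detection threshold and would pay in false positives.
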