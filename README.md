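# scfskit

Single-cell force spectroscopy (SCFS) analysis toolkit: force–distance curve
processing, adhesion-strengthening slope statistics and an additive-null
interaction statistic for dissecting how two receptor classes jointly build
cell adhesion.

## The scientific problem

In AFM-based SCFS a live cell bound to a cantilever is pressed onto a
ligand-coated substrate and retracted after a defined contact time; the
largest downward cantilever deflection after baseline correction is the
**adhesion force**. Probing fibroblast lines that express αV-class and/or
α5β1 integrins against fibronectin fragments over contact times of
5–120 s yields three quantitative questions this package answers:

1. **Curve level** — extract the adhesion force, detect discrete rupture
   events, call specific binding on single-molecule curves (200 pN setpoint,
   ~zero contact time), estimate the per-cell binding probability, and
   calibrate the cantilever spring constant from thermal noise via
   equipartition (k = k_B·T / var(deflection)).
2. **Strengthening** — summarise adhesion build-up as the average of discrete
   slopes s = (F₂ − F₁)/(t₂ − t₁) over adjacent contact times of the
   per-time medians, and compare groups with an equal-size bootstrap over
   whole cells (each fibroblast is probed at every contact time, so the cell
   is the resampling unit).
3. **Interaction** — per contact time, quantify the deviation from an
   additive null model for two receptor classes A and B:

   ε = F_AB + F_0 − F_A − F_B

   where F_AB, F_A, F_B, F_0 are the adhesion forces of the
   double-expressing, single-expressing and receptor-free conditions.
   ε < 0 indicates competition, ε > 0 cooperation; ε = 0 is tested on
   bootstrap resamples.

Because the original raw measurements are not publicly deposited, the package
ships a first-class synthetic-data module that emulates the measurement
structure with known ground truth — saturating-exponential mean force
profiles with lognormal cell-to-cell and Gaussian within-cell variability,
full retract curves with rupture events, and thermal-noise traces — so every
estimator is validated against the generator (see `docs/methods.md`).

Two inference methods are available for the bootstrap tests:
`method="percentile"` (default; calibrated two-sided bootstrap percentile
test) and `method="wilcoxon"` (a two-tailed Wilcoxon applied directly to the
bootstrap replicates, as sometimes practised; it is strongly
anti-conservative and provided for comparability only — `docs/methods.md`
quantifies this).

## Worked example

```python
import scfskit as sk
from scfskit.stats import AdhesionDataset

table = sk.simulate_adhesion_table(sk.default_study_config(seed=42))
ds = AdhesionDataset(table)

print(sk.median_forces(ds, "pKO-b1"))

res = sk.slope_difference_test(ds, ds, condition_a="pKO-b1",
                               condition_b="pKO-aV-b1", B=100, seed=0)
print(res.slope_obs, res.p_value, res.stars)

it = sk.interaction_test(ds, ["pKO-aV-b1", "pKO-aV", "pKO-b1", "pKO"],
                         B=100, seed=0)
for j, t in enumerate(it.contact_times):
    print(t, it.epsilon_obs[j], it.p_per_time[j], it.sign[j])
```

prints (formatted):

```
pKO-b1 median adhesion (nN): {5.0: 0.64, 20.0: 1.44, 50.0: 2.8, 120.0: 3.84}
{'pKO-b1': '37.8 pN/s', 'pKO-aV-b1': '14.8 pN/s'} p = 0.0 ****
t=    5 s  epsilon=-0.31 nN  p=0.120  sign=none
t=   20 s  epsilon=-1.26 nN  p=0.000  sign=negative
t=   50 s  epsilon=-2.46 nN  p=0.000  sign=negative
t=  120 s  epsilon=-3.45 nN  p=0.000  sign=negative
```

The medians strengthen and saturate with contact time; the α5β1-only line
strengthens adhesion roughly twice as fast as the double-expressing line
(37.8 vs 14.8 pN/s, significant at the star convention ****p < 0.0001); and
the interaction statistic is significantly negative at late contact times —
the competition signature: the joint condition adheres far less than the sum
of the single-receptor conditions.

The same pipeline is scriptable from the shell:

```sh
scfskit simulate --config run.yaml --out out/
scfskit extract --curves out/curves --out out/
scfskit analyze-slopes --dataset out/dataset.csv --group-a pKO-b1 --group-b pKO-aV-b1
scfskit analyze-interaction --dataset out/dataset.csv --conditions pKO-aV-b1,pKO-aV,pKO-b1,pKO
scfskit analyze-binding --features out/features.csv
scfskit calibrate --trace trace.txt --temperature 310
```

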