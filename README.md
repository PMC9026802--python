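# pmtperf

Quantitative DCE-MRI perfusion modelling and decision-tree classification of
prevascular mediastinal tumor (PMT) subtypes — lymphoma, thymoma and thymic
carcinoma.

Preoperative subtype calls matter clinically: lymphoma is treated medically
while resectable thymic epithelial tumors (TETs) go to surgery without biopsy,
so a noninvasive discriminator built from dynamic contrast-enhanced MRI is
valuable. `pmtperf` implements the full computational chain behind such a
clinical-perfusion classifier, for imaging scientists who want to reproduce,
stress-test or extend it:

1. **Relaxometry** — spoiled gradient-echo (SPGR) signal model
   `S = M0 sin α (1 − E1)/(1 − E1 cos α)`, `E1 = exp(−TR/T1)`; two-point
   variable-flip-angle T1 mapping (5°/15°), and per-frame inversion of the
   dynamic series to gadolinium concentration via
   `1/T1(t) = 1/T1_0 + r1 C(t)`.
2. **Pharmacokinetics** — the extended Tofts–Kermode model
   `C_t(t) = K_trans ∫ C_p(τ) e^{−k_ep(t−τ)} dτ + v_p C_p(t)`,
   fitted by deterministic multi-start nonlinear least squares over
   `(K_trans, k_ep, v_p)` with `v_e = K_trans/k_ep`; time-to-peak (TTP) and
   maximum concentration complete the six perfusion predictors.
3. **Morphometrics** — tumor volume, face-counted surface area and maximum
   3D diameter from a binary mask with anisotropic spacing.
4. **CART** — Gini-impurity decision trees grown from scratch over the
   10-predictor table (age + 6 perfusion + 3 size), normalized
   impurity-decrease variable importance, plus the three published
   fixed-cutoff trees (age 32 yr → v_e 0.175×10⁻³ → k_ep 2.649×10⁻³;
   tumor volume 45 183.5 mm³; k_ep 2.1489/1.009×10⁻³).
5. **Evaluation** — confusion matrices with one-vs-rest
   sensitivity/specificity, ROC/AUC (Mann–Whitney identity, Hanley–McNeil
   95 % CI), Mann–Whitney U tests with Benjamini–Hochberg FDR control, and
   an integer-consistency reconstructor for printed 2×2 performance figures.
6. **Synthetic data** — quantile-matched cohort generator calibrated to the
   published per-subtype medians/inter-quartiles, and 4D SPGR phantoms with
   known ground-truth kinetics so the whole chain is testable end to end.

## Worked example

Fit the extended Tofts model to a simulated tumor curve (2 % noise) on the
protocol grid (TR 4 ms, 2.5 s frames, 3 min 24 s):

```python
import numpy as np
from pmtperf import (AcquisitionParams, ArterialInputFunction, TissueKinetics,
                     tofts_forward, ExtendedToftsModel)
from pmtperf.relaxometry import ConcentrationCurve

acq = AcquisitionParams()
aif = ArterialInputFunction.parametric(acq.frame_times())
truth = TissueKinetics.from_rates(ktrans=0.3, kep=1.5, vp=0.03)
ct = tofts_forward(truth, aif)
rng = np.random.default_rng(0)
noisy = ConcentrationCurve(ct.times_s, ct.values + rng.normal(0, 0.02 * ct.values.max(), ct.values.size))
res = ExtendedToftsModel(noisy, aif).fit()
print(res.summary())
```

```
Extended Tofts model fit
========================
  Ktrans      0.291305  min^-1
  kep          1.44606  min^-1
  ve          0.201448  (Ktrans/kep)
  vp         0.0305918
  RSS       0.00537584   converged: True
```

The fit recovers the generating parameters (0.3, 1.5, 0.03) to within a few
percent at this noise level; with zero noise recovery is < 0.1 %.

Classify a calibrated 62-patient synthetic cohort with the published
fixed-cutoff subtype tree:

```python
from pmtperf import published_tree, confusion, classwise_performance
from pmtperf.cohort import sample_cohort, table2_cohort_spec, FEATURE_COLUMNS

table = sample_cohort(table2_cohort_spec(seed=0))
tree = published_tree("pmt3")
pred = tree.predict(table[list(FEATURE_COLUMNS)])
cm = confusion(table["subtype"], pred, tree.classes)
print(classwise_performance(cm).rounded().as_dict())
```

```
{'classes': ['lymphoma', 'thymic_carcinoma', 'thymoma'],
 'sensitivity_pct': {'lymphoma': 70.6, 'thymic_carcinoma': 78.6, 'thymoma': 77.4},
 'specificity_pct': {'lymphoma': 100.0, 'thymic_carcinoma': 81.3, 'thymoma': 80.6},
 'accuracy_pct': 75.81}
```

Each per-class number is a one-vs-rest rate (e.g. the tree finds 12 of the 17
lymphomas, and never calls a TET a lymphoma on this draw); the overall
accuracy is the diagonal fraction, 47/62.

The `perf` command line exposes the same stages
(`perf simulate | concentrations | fit-tofts | morpho | cart | evaluate | run`);
`perf run --seed 0 --out mydir` executes the full synthetic study and writes a
checksum manifest for reproducibility.

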