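# Methods

## Signal model and relaxometry

The dynamic series is modelled as a spoiled gradient echo in steady state,

    S = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR / T1),

with TR = 4 ms and calibration flip angles 5° and 15° (the dynamic frames are
assumed acquired at 15°; the protocol lists both angles without assigning
roles, so this is a stated assumption). Baseline (T1₀, M0) come from the
two-point variable-flip-angle linearization: with y = S/sin α and
x = S/tan α the two measurements lie on y = E1·x + M0(1 − E1), giving an
exact closed-form inversion. Pairs whose implied E1 falls outside (0, 1) have
no physical solution and are rejected with a diagnostic rather than clamped.

Contrast concentration follows from per-frame inversion of the same equation:
1/T1(t) = 1/T1₀ + r1·C(t). The equilibrium scale is re-anchored on the mean
of the pre-contrast frames so baseline concentration is exactly zero; this
absorbs gain differences between the calibration and dynamic acquisitions.
Frames at or above the SPGR saturation ceiling invert to NaN, are logged, and
are excluded from downstream fitting instead of aborting the curve.

Defaults with units: r1 = 5.0 L·mmol⁻¹·s⁻¹ (gadobutrol at 3 T; the protocol
names the agent and field strength but no relaxivity — configurable);
hematocrit 0.42 applied only to the aortic curve, C_p = C_blood/(1 − Hct);
echo-time (T2*) effects neglected at TE = 2 ms; no B1 correction.

## Extended Tofts–Kermode model

Tissue concentration is

    C_t(t) = Ktrans · ∫₀ᵗ C_p(τ) e^{−kep(t−τ)} dτ + vp · C_p(t),

with Ktrans (min⁻¹) the plasma→EES transfer constant, kep = Ktrans/ve
(min⁻¹), ve and vp volume fractions (ve + vp ≤ 1). The convolution uses the
exponential-kernel recursion that is exact when C_p is piecewise linear
between samples; a series expansion takes over below kep·Δt = 10⁻⁴ to avoid
cancellation. At the 2.5 s frame spacing this makes the forward model
accurate to ~10⁻⁴ relative to refined quadrature of the same interpolated
input (the residual sampling error of the input itself is separate and
irreducible at fixed frame spacing).

Fitting minimizes the sum of squared residuals over (Ktrans, kep, vp) with
bounds [0, 10] × [10⁻⁴, 20] min⁻¹ × [0, 0.5] and ve reported as Ktrans/kep,
from a fixed 3 × 3 × 2 multi-start grid (Ktrans ∈ {0.01, 0.1, 1},
kep ∈ {0.1, 1, 10}, vp ∈ {0.01, 0.1}); no random initialization, so fits are
bit-reproducible. An all-zero curve short-circuits to zero kinetics. The
parameterization was chosen so that both kep and ve can be reported while
keeping three free parameters. Noiseless recovery is < 0.1 % per parameter;
the fit is exactly scale-equivariant (scaling C_t and C_p together leaves all
parameters unchanged).

TTP is the time of the global maximum of the tissue curve minus the bolus
arrival of the input (first frame where C_p exceeds 5 % of its peak — the
origin is a convention, stated because none is standard); earliest frame wins
ties, and an all-flat curve returns 0 with a degenerate flag. Cmax is the
curve maximum.

## Arterial input function

The parametric plasma curve is a gamma-variate first-pass bolus (peak
amplitude 6 mM, shape 2, scale 4.5 s, arrival 10 s) plus a slow washout term
(1.1 mM, rate 4.5 × 10⁻³ s⁻¹, 30 s rise), zero before arrival. These values
give a peak and tail typical of a 0.1 mmol/kg bolus at 2 mL/s read in the
descending aorta. Measured inputs can be wrapped directly from samples.

## Morphometrics

Volume = foreground count × voxel volume. Surface area counts exposed faces
under 6-connectivity (array border = background); this is deterministic and
exactly testable but overestimates smooth surfaces (up to ~1.5× for a
sphere). Maximum diameter is the largest center-to-center distance between
surface voxels in physical mm (a convex-hull reduction accelerates large
masks); it understates a corner-to-corner caliper by at most one voxel
diagonal. Whether the original measurement was 3D or single-slice is
unknowable from the published cutoffs; 3D was chosen and stated.

## CART

Greedy binary partitioning minimizing weighted Gini impurity
G = 1 − Σ p_k², exhaustive over every feature and every midpoint of
consecutive sorted unique values. Boundary convention: value ≤ threshold
goes left. Determinism is guaranteed by explicit tie-breaks (impurity, then
declared feature order, then smaller threshold). Defaults target small
clinical cohorts: max depth 3 (subtype tree), 1 (lymphoma-subtype), 2
(invasiveness) — the published depths — with min_samples_split 4,
min_samples_leaf 2, no pruning. Missing values are rejected; surrogate
splits (used by some commercial CART implementations) are deliberately out
of scope. Importance per feature is the sample-fraction-weighted impurity
decrease summed over its split nodes, normalized to 100 % of the maximum.

The three published trees are encoded with their printed cutoffs exactly.
The published text gives cutoffs and depths but not which side of each
cutoff carries which label, nor which branch of the subtype tree hosts the
v_e and k_ep nodes. Defaults follow the direction of the group statistics
(lymphoma younger; carcinoma higher v_e and lower k_ep than thymoma; the
v_e/k_ep nodes sit on the older branch). The Hodgkin volume direction and
the invasiveness leaf labels are not derivable from published marginals;
the defaults (Hodgkin = larger volume; invasive = lowest-k_ep leaf) are
package choices and every leaf is overridable via the `orientation`
argument.

## Evaluation statistics

Sensitivity/specificity are one-vs-rest from the K×K confusion matrix;
accuracy is the diagonal fraction. Display rounding is half-up (1 decimal
for rates, 2 for accuracy) with full precision retained internally. AUC uses
the Mann–Whitney identity (ties count ½), reported in the direction giving
≥ 0.5 with the direction recorded; the 95 % CI is Hanley–McNeil by default
(a subject-resampling bootstrap is available behind a flag). The
Mann–Whitney U test uses midranks, a tie-corrected normal approximation with
continuity correction, and exact enumeration of all group assignments when
n₁ + n₂ ≤ 12 (the exact path also handles ties). Exhaustive enumeration
shows the continuity-corrected normal p never strays more than 0.0511 from
the exact law at these sizes. FDR control is Benjamini–Hochberg step-up
(the procedure family was not named in the source; BH is the standard
choice), applied per 10-test comparison family. All tests are two-sided.

The confusion-matrix reconstructor enumerates every integer 2×2 matrix on n
subjects whose rounded sensitivity/specificity match a printed pair — an
audit tool: the invasiveness pair (71.4 %, 95.8 %, n = 31) pins a unique
matrix (TP 5, FN 2, TN 23, FP 1; accuracy 90.32 %), while the
lymphoma-subtype pair (75 %, 100 %, n = 17) is consistent with positive-class
sizes 4, 8, 12 or 16 but not with the cohort's 6 Hodgkin cases — an
inconsistency the package exposes rather than resolves.

## Synthetic data

The cohort generator fits two-parameter distributions to each published
(median, q1, q3) cell: log-normal for the nine strictly positive, right-
skewed predictors (location = ln median, matched exactly; scale =
ln(q3/q1)/(2z₀.₇₅), the least-squares compromise on the log-quartiles) and a
quantile-matched normal for age (scale = (q3 − q1)/(2z₀.₇₅); negative draws
resampled). Variables are independent within subtype — only marginals are
published — and sub-labels (Hodgkin 6/11, invasive 6/25) are count-assigned
without their own feature shift. Consequences: learned trees on synthetic
cohorts recover marginally-driven splits but cannot reproduce any real
feature correlations, and the two binary trees have no real signal to find
in synthetic data beyond chance; passing tests therefore validate the
computational chain, not clinical performance. Rate/fraction/concentration
columns stay on the printed 10⁻³ scale (on which the published cutoffs are
expressed, and which is physically small for tissue — reproduced as printed,
without unit reinterpretation); time and size columns are converted to
s/mm³/mm²/mm.

Phantoms are small labelled box grids (default 16×16×4 at 2×2×5 mm, 82
frames at 2.5 s): the aortic region carries the blood-corrected input, tumor
regions the Tofts forward model, both mapped to SPGR signal with the
acquisition parameters; additive Gaussian noise on the magnitude signal
(adequate at the simulated SNRs; a Rician model was considered and left
out). With zero noise the full chain recovers ground-truth kinetics to
~10⁻¹³ relative (requirement: 0.5 %). Frame count = floor(duration/Δt) + 1
including t = 0.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; the pipeline fans a
single global seed out to stages by fixed offsets and records SHA-256
checksums of every artifact in a manifest. Calibration checks use 10⁵ draws
(2 % tolerance on medians); the noisy-fit recovery study uses 50 replicates
at 2 % noise; CART split-search verification enumerates ~200 random ≤12-row
instances against a brute-force oracle, plus an exhaustive property sweep.

## Known limitations

Single-ROI (mean-curve) fitting only — no voxelwise maps or spatial
regularization; no B1/T2* correction; no motion, anatomy or coil modelling
in phantoms; no surrogate splits or cost-complexity pruning; the multinomial
logistic regression companion analysis is out of scope. The generator's
independence assumption understates multivariate structure, so multivariate
performance numbers from synthetic cohorts are not comparable to real-cohort
values.
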