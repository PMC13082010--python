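# Methods

## The FD contrast

FLAIR and DIR are inversion-recovery sequences. Under idealized conditions —
perfect 180° inversions, instantaneous excitation, complete spoiling — the
magnitude signal of each factorizes as

    S = M0 · A(T1; timings) · exp(−TE / T2)

with longitudinal recovery factors

    A_FLAIR(T1) = |1 − 2 e^(−TI/T1) + e^(−TR/T1)|
    A_DIR(T1)   = |1 − 2 e^(−TI_2/T1) + 2 e^(−TI_1/T1) − e^(−TR/T1)|

where for DIR the first inversion precedes readout by TI_1 (the long
interval, nulling CSF) and the second by TI_2 (the short interval, nulling
normal-appearing white matter). The derived contrast is

    FD = (FLAIR − DIR) / FLAIR = 1 − (A_DIR / A_FLAIR) · e^(−(TE_D − TE_F)/T2)

so the proton density M0 cancels exactly and FD is a pure function of T1, T2
and the sequence timings. With the default timings (FLAIR TR 15000 / TE 90 /
TI 3100 ms; DIR TR 15000 / TE 100 / TI_1 3800 / TI_2 470 ms), FD is ≈ 0.883
for white-matter-like tissue (T1 850 ms, T2 70 ms) and ≈ 0.687 for
gray-matter-like tissue (1300/90 ms): FD is high where tissue is
myelin-/lipid-rich, and a demyelination-like shift (T1 and T2 both
lengthening) lowers it (850/70 → 950/80 gives 0.883 → 0.825).

Model assumptions worth stating: the ±exp(−TR/T1) steady-state terms are kept
(negligible at TR = 15 s for brain T1 but they keep the closed form exact);
signals are magnitudes, matching synthetic magnitude images (a signed mode
exists for debugging); B1/B0 inhomogeneity, slice profiles, magnetization
transfer and multi-compartment water exchange are outside the model. The
printed DIR inversion times do not state their reference points; we adopt the
standard convention above and expose both intervals as `ti_long`/`ti_short`.

## FD map derivation

The fixed order of operations is: parenchyma mask (GM+WM) → exclusion of
voxels whose FLAIR signal is below `epsilon_rel` times the within-mask FLAIR
maximum (default 1e−6; near-zero denominators at CSF boundaries) → voxel-wise
ratio → clipping of negative values to zero (DIR > FLAIR arises from noise
and partial volume; counted in `n_clipped`) → per-subject min–max scaling of
the within-mask values to [0, 1] → optional Gaussian smoothing (default
4 mm FWHM) before voxel-wise statistics. ROI means are taken from the
unsmoothed normalized maps. Excluded voxels are NaN in memory and removed
from the subject's mask; writers emit 0 plus the mask as a separate volume so
files stay standard. Smoothing uses the masked-renormalization convention
(smooth the zero-filled volume and divide by the smoothed mask) so values
outside the mask never bleed in and a constant field stays constant;
per-subject smoothing uses that subject's own possibly-reduced mask, and
voxels invalid in any subject are dropped listwise by the voxel-wise models.

## The phantom cohort generator

The generator exists so that every downstream stage — contrast synthesis, FD
derivation, group statistics, classification, voxel-wise regression — can be
tested against a known ground truth without any data download. It emulates a
two-group study (healthy controls n = 16, mild cognitive impairment n = 17)
of co-registered T1/T2/PD/myelin-fraction volumes.

**Geometry.** A 48³ grid of 1.3 mm voxels (configurable, ≥ 32 per axis): a
deep white-matter ellipsoid; three callosum-like midline blocks (genu, body,
splenium); a central CSF ventricle surrounded by a periventricular
partial-volume shell; and twelve gray-matter spheres named for the
olfactory–limbic structures a study of odor identification would target
(bilateral hippocampus, amygdala, thalamus, insula and anterior olfactory
nucleus; left orbitofrontal cortex and parahippocampal gyrus). Geometry is
deterministic given the shape; every analysis ROI has ≥ 60 voxels so
cluster-extent tests are exercised. The label volume doubles as the ROI
atlas.

The partial-volume shell deserves a note. Its voxels have CSF-like relaxation
(T1 4800 ms, T2 800 ms) but sit inside the parenchyma mask, as
tissue/CSF-boundary voxels do in a T1-segmentation mask. There DIR exceeds
FLAIR, the ratio goes negative, and the clipping rule sets FD = 0 — which
pins every subject's within-mask minimum at zero exactly as in real FD maps.
Without such a compartment the per-subject minimum is set by whichever
anatomical ROI has the lowest FD, and in the impaired group that is an
*affected* ROI, so min–max scaling would contaminate unaffected ROIs with a
group effect that is an artifact of the phantom's purity, not of the
pipeline. The shell and the ventricle are mask compartments, not targets, and
are excluded from ROI statistics.

**Tissue model.** Class means (3T-typical literature values, configurable):
WM T1 850 ms, T2 70 ms, PD 0.70, myelin fraction 0.30; GM 1300/90/0.85/0.10;
CSF 4300/1500/1.00/0. Per subject and ROI, a fractional myelin deviation
δ ~ N(0, 0.12) is drawn; T1 and T2 move against it through coupling
coefficients (T1: −0.4·δ, T2: −0.5·δ — demyelination lengthens both), plus
independent relaxation jitter of 2% so FD is myelin-linked but not a
deterministic function of myelin. Within tissue, a smooth per-subject random
field (6 mm FWHM, 10% relative sd) modulates myelin and drags T1/T2 along
through the same couplings, with a smaller independent 2% relaxation field;
this is what gives the voxel-wise statistics many quasi-independent units, as
real within-tissue heterogeneity does. Finally 3% i.i.d. voxel noise is
applied to the quantitative maps and absolute N(0, 0.02) noise to the
observed MVF.

**Disease effect.** The MCI group carries multiplicative shifts — T1 +12%,
T2 +14%, myelin −15% — in an affected-ROI set (bilateral hippocampus and
anterior olfactory nucleus, left amygdala/thalamus/orbitofrontal cortex,
callosal body and splenium). These defaults were chosen for comfortable
power at n = 16/17 on a desk-scale phantom and are not estimates of any
real-world effect size.

**Observed MVF.** A share parameter w ∈ [0, 1] (default 1) controls how much
of the myelin-related variance the MVF map captures: the subject deviation
and the spatial field split into a component MVF sees (weight √w) and one it
misses (weight √(1−w)), and the disease shift on the MVF mean is scaled by w.
At w = 1, MVF is a nearly perfect myelin proxy and adjusting for it removes
the FD–odor association, as it should. At w < 1 (the `partial_mvf`
configuration, w = 0.5) part of the microstructural signal is visible to FD
through relaxation but not to MVF — the mechanism by which an FD–behavior
association can survive a voxel-wise MVF covariate. Note this attenuation
must be a *variance split*, not a scaling: scaling MVF's deviation leaves it
collinear with the myelin direction across subjects, and regression
adjustment removes collinear signal completely regardless of its scale.

**Covariates.** Age is truncated-normal per group (HC 63.50 ± 6.55, MCI
70.35 ± 8.09, bounds 50–90), so age–group confounding is on by default and
the ANCOVA age covariate does real work. The odor-identification score
(0–20) is `round(clip(a + b·m̄ + ε))` where m̄ is the subject's mean myelin
fraction over the olfactory labels (both hippocampi, insulae and anterior
olfactory nuclei, including spatial heterogeneity). The coefficients (a, b)
are solved in closed form so the expected group means equal the configured
targets 16.50 (HC) and 13.94 (MCI); ε has sd 1.75, chosen so the HC
odor-score sd comes out near the printed 2.16 (the myelin-mediated variance
contributes the rest). The generator does not reproduce the larger MCI
odor-score spread (4.49), which would require heteroscedastic noise. Null
configurations sever the link (b = 0) because a calibrated link is undefined
when the groups have no myelin difference, and calibration-style tests need
odor independent of the maps.

**Reproducibility.** All randomness flows from one integer seed through
per-subject `SeedSequence` child streams; a cohort is bit-identical under
the same seed and configuration.

## Statistical procedures

*Group comparison.* Per ROI, ordinary least squares of the ROI mean on an
intercept, an MCI indicator and age; two-sided t test of the group
coefficient (residual df = n − 3). P-values are reported uncorrected, with an
optional Benjamini–Hochberg column off by default. Summary-statistic tests
use the Welch form (it reproduces the printed demographic p-values more
closely than the pooled form, which is also provided) and the Pearson
chi-square without continuity correction for 2×2 tables.

*Classification.* Features are ROI means (FD, MVF, or both concatenated),
z-scored and PCA-reduced to the smallest number of components explaining
≥ 85% of the variance. Model 1 uses components only; model 2 appends age;
model 3 appends age and odor score. Stratified five-fold cross-validation
fits the scaler, PCA and an unpenalized-ML logistic regression (tiny-ridge
fallback under separation) on training rows only; a whole-sample-PCA mode
exists behind a flag for comparison. Performance is the pooled AUC over
held-out scores concatenated across folds (equivalently midrank pair
counting). Folds are deterministic given the seed.

*Voxel-wise models.* At each masked voxel, OLS of the (smoothed, normalized)
map value on intercept + predictor + covariates, optionally + that voxel's
value from a second modality (the image covariate). The implementation is a
vectorized batched normal-equations solve; voxels with rank-deficient
designs (detected by a relative determinant floor) or near-zero residual
variance are flagged invalid rather than raised. Suprathreshold voxels
(two-sided p below threshold, with the requested sign) are grouped into
connected components — default 26-connectivity, configurable to 6 or 18,
since the convention is rarely stated — and components below the extent
threshold k are discarded. Default thresholds follow the analysis they
mirror: p < 0.005 with k ≥ 40 for FD models and k ≥ 10 for MVF–odor;
p < 0.0001 with k ≥ 100 for the across-subject FD–MVF correlation map.

## Numerical and design choices

- Voxel indices are 0-based everywhere; cluster tables also report the peak's
  atlas label.
- Degenerate min–max input (constant map) is defined as all zeros with a
  `degenerate` flag rather than an error.
- The FLAIR recovery factor crosses zero near T1 ≈ 4.5 s at the default
  timings; `fd_analytic` raises on an exact zero and the epsilon exclusion
  handles the near-null neighbourhood in map space.
- Logistic fits treat convergence warnings as failures and fall back to a
  ridge penalty of 1e−6.
- The pooled AUC is computed over whichever subjects received held-out
  scores, which equals all subjects under the standard full fold split.

## Problem sizes used by the test suite and acceptance script

Calibration and power claims are Monte-Carlo estimates at 48³ resolution:
the test suite uses 100 null and 50 planted-effect replicate cohorts for the
ROI-level checks and 8-cohort batches for the voxel-wise checks; the
acceptance script uses 40/25/6. These sizes give standard errors comfortably
inside the asserted bands while keeping a full run in the minutes range on
one CPU.

## Known limitations

The phantom is geometric, not anatomical: pure-tissue ROIs (no partial-volume
mixing beyond the periventricular shell), no cortical ribbon, no spatial
normalization step (volumes are generated co-registered, so MNI warping is
out of scope). Age affects no tissue parameter, so age adjustment corrects
confounding of the group contrast only through the group–age association.
Noise on quantitative maps is Gaussian (a Rician option applies to
synthesized contrasts, off by default); scanner artifacts, motion and
B1 effects are not modeled. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's statistics under a controlled
generative model, not performance on real acquisitions.
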