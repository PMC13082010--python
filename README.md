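# fdcontrast

Toolkit for the **FD contrast** — a normalized FLAIR–DIR difference derived
from synthetic MRI that is sensitive to myelin- and lipid-related relaxation
behavior — together with the simulation and statistics needed to study it on
digital relaxometry phantoms.

## The problem

Quantitative myelin imaging (myelin volume fraction, MVF) requires
specialized multi-compartment modeling, while routine synthetic MRI already
produces FLAIR and DIR contrasts from the same voxel-wise T1/T2/PD maps.
Both contrasts are inversion-recovery signals of the form
S = M0·A(T1)·e^(−TE/T2); DIR's two inversions null CSF *and*
normal-appearing white matter, FLAIR's single inversion nulls CSF only.
Their normalized difference

    FD = (FLAIR − DIR) / FLAIR = 1 − (A_DIR / A_FLAIR) · e^(−(TE_D − TE_F)/T2)

cancels proton density exactly and is high precisely where FLAIR retains
signal that DIR suppresses — myelin-/lipid-rich tissue. At the default
timings (FLAIR TR/TE/TI = 15000/90/3100 ms; DIR TR/TE/TI₁/TI₂ =
15000/100/3800/470 ms), white-matter-like tissue gives FD ≈ 0.88,
gray-matter-like ≈ 0.69, and a demyelination-like T1/T2 lengthening strictly
lowers FD. The package is written for imaging scientists who want to derive
FD maps, test their statistical behavior, and benchmark the surrounding
analysis pipeline (ROI ANCOVA, PCA + logistic classification, voxel-wise
regression with cluster-extent thresholding, FD–MVF correspondence) against
cohorts with known ground truth.

Because no public cohort accompanies this design, the package ships a seeded
phantom generator: a two-group study (16 healthy controls, 17 with mild
cognitive impairment) of co-registered T1/T2/PD/myelin volumes with
demyelination-like shifts planted in olfactory–limbic ROIs and an
odor-identification score linked to olfactory-ROI myelin. See
`docs/methods.md` for the full generative model and its limitations.

## Worked example

```python
from fdcontrast import fd_analytic, simulate_cohort
from fdcontrast.pipeline import derive_fd_maps
from fdcontrast.phantom import analysis_rois
from fdcontrast.roistats import roi_table, ancova_table, crossval_classify

print(f"FD(WM 850/70)  = {fd_analytic((850, 70, 0.7)):.3f}")
print(f"FD(GM 1300/90) = {fd_analytic((1300, 90, 0.85)):.3f}")

cohort = simulate_cohort(16, 17, seed=7)            # two-group phantom cohort
fdmaps, mask = derive_fd_maps(cohort)               # synthesize, ratio, clip, scale
cov = cohort.covariates_frame()
table = roi_table(fdmaps, cohort.phantom, index=cov["id"])[analysis_rois(cohort.phantom)]
anc = ancova_table(table, cov["group"], cov["age"])  # FD ~ group + age, per ROI
print(anc.loc[["hippocampus_l", "cc_splenium", "insula_l"],
              ["diff_hc_minus_mci", "t", "p"]].round(4))
res = crossval_classify(table, cov["group"], cov, model=1, seed=7)
print(f"pooled 5-fold CV AUC (model 1): {res.auc:.3f}")
```

Output:

```
FD(WM 850/70)  = 0.883
FD(GM 1300/90) = 0.687
               diff_hc_minus_mci       t       p
hippocampus_l             0.0334 -3.0834  0.0044
cc_splenium               0.0263 -1.8500  0.0742
insula_l                 -0.0113  0.8777  0.3871
pooled 5-fold CV AUC (model 1): 0.993
```

The hippocampus — an ROI carrying the planted disease effect — shows a
significant age-adjusted FD reduction in the impaired group
(`diff_hc_minus_mci > 0` means controls are higher), the unaffected insula
does not, and the ROI-feature classifier separates the groups. On another
seed the borderline ROIs shift, as they should at n = 33.

A command-line interface wraps the same library calls:

```bash
fdcontrast simulate --n-hc 16 --n-mci 17 --seed 7 --out cohort/
fdcontrast synth --t1 t1.nii.gz --t2 t2.nii.gz --pd pd.nii.gz --modality FLAIR -o flair.nii.gz
fdcontrast fd --flair flair.nii.gz --dir dir.nii.gz --mask mask.nii.gz -o fd.nii.gz
fdcontrast run-all --seed 7 --out results/       # full pipeline + manifest
```

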