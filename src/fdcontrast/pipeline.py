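"""End-to-end orchestration: simulate -> synthesize -> FD -> statistics.

Every stage is a thin call into the library modules; `run_pipeline` writes
the artifact directory (volumes, tables, JSON results, manifest with hashes)
and is what the ``run-all`` CLI subcommand wraps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fdpipe import BrainMask, FDMap, compute_fd, minmax_normalize, smooth_volume
from .io import save_yaml, write_volume
from .phantom import (
    Cohort,
    CohortConfig,
    analysis_rois,
    parenchyma_mask,
    simulate_cohort,
    write_cohort,
)
from .relaxometry import (
    DEFAULT_DIR,
    DEFAULT_FLAIR,
    DIRSequenceParams,
    IRSequenceParams,
    synthesize_contrast,
)
from .roistats import ancova_table, crossval_classify, roi_table
from .voxelwise import cluster_threshold, crossmodal_correlation, massunivariate_regression

__all__ = [
    "RunConfig",
    "derive_fd_maps",
    "classification_grid",
    "voxelwise_analyses",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Resolved settings for one full phantom-cohort analysis run."""

    seed: int = 7
    cohort: CohortConfig = field(default_factory=CohortConfig)
    flair: IRSequenceParams = DEFAULT_FLAIR
    dir: DIRSequenceParams = DEFAULT_DIR
    epsilon_rel: float = 1e-6
    normalize: bool = True
    fwhm_mm: float = 4.0
    k_folds: int = 5
    var_threshold: float = 0.85
    p_voxel: float = 0.005
    k_fd: int = 40
    k_mvf: int = 10
    p_corr: float = 1e-4
    k_corr: int = 100
    connectivity: int = 26


def derive_fd_maps(
    cohort: Cohort,
    flair_params: IRSequenceParams = DEFAULT_FLAIR,
    dir_params: DIRSequenceParams = DEFAULT_DIR,
    epsilon_rel: float = 1e-6,
    normalize: bool = True,
) -> tuple[list[FDMap], BrainMask]:
    """Synthesize FLAIR/DIR for every subject and derive (normalized) FD maps."""
    mask = parenchyma_mask(cohort.phantom)
    fdmaps = []
    for s in cohort.subjects:
        flair = synthesize_contrast(s.maps, flair_params, "FLAIR")
        dirv = synthesize_contrast(s.maps, dir_params, "DIR")
        fdm = compute_fd(flair, dirv, mask, epsilon_rel=epsilon_rel)
        if normalize:
            fdm = minmax_normalize(fdm)
        fdmaps.append(fdm)
    return fdmaps, mask


def smoothed_maps(fdmaps, cohort: Cohort, fwhm_mm: float, mask: BrainMask):
    """Per-subject masked smoothing of FD (FDMap) or plain volumes.

    An FDMap is smoothed within its own (possibly epsilon-reduced) mask so
    excluded voxels stay NaN for that subject instead of bleeding into
    neighbours; downstream voxel-wise analyses drop them listwise.
    """
    vs = cohort.phantom.voxel_size
    out = []
    for m in fdmaps:
        if isinstance(m, FDMap):
            out.append(smooth_volume(m.fd, fwhm_mm, vs, m.mask))
        else:
            out.append(smooth_volume(np.asarray(m, dtype=float), fwhm_mm, vs, mask))
    return out


def classification_grid(
    fd_table: pd.DataFrame,
    mvf_table: pd.DataFrame,
    covariates: pd.DataFrame,
    labels,
    atlas,
    k_folds: int = 5,
    seed: int = 0,
    var_threshold: float = 0.85,
) -> dict:
    """The full ROI-set x model x feature-set classification table.

    FD and MVF run models 1-3 on all/GM/WM ROI sets; the combined FD+MVF
    feature set runs model 1 only (the head-to-head comparison).
    """
    gm = [nm for nm in fd_table.columns if atlas.label_table[atlas.id_of(nm)][1] == "GM"]
    wm = [nm for nm in fd_table.columns if atlas.label_table[atlas.id_of(nm)][1] == "WM"]
    roi_sets = {"all": list(fd_table.columns), "gm": gm, "wm": wm}
    out = {}
    for roi_set, cols in roi_sets.items():
        for feature_set, table in (("FD", fd_table[cols]), ("MVF", mvf_table[cols])):
            for model in (1, 2, 3):
                res = crossval_classify(
                    table, labels, covariates, model=model, k_folds=k_folds,
                    seed=seed, var_threshold=var_threshold,
                    feature_set=feature_set, roi_set=roi_set,
                )
                out[f"{roi_set}/{feature_set}/model{model}"] = res
        combined = pd.concat(
            [fd_table[cols].add_prefix("fd_"), mvf_table[cols].add_prefix("mvf_")], axis=1
        )
        res = crossval_classify(
            combined, labels, covariates, model=1, k_folds=k_folds, seed=seed,
            var_threshold=var_threshold, feature_set="FD+MVF", roi_set=roi_set,
        )
        out[f"{roi_set}/FD+MVF/model1"] = res
    return out


def voxelwise_analyses(cohort: Cohort, fd_smooth, mvf_smooth, mask: BrainMask, cfg: RunConfig) -> dict:
    """Models A/B (FD-odor), MVF-odor, and the FD-MVF correspondence map."""
    cov = cohort.covariates_frame()
    odor = cov["odor_id"].to_numpy(dtype=float)
    age = cov["age"].to_numpy(dtype=float)[:, None]

    model_a = massunivariate_regression(fd_smooth, odor, age, mask=mask)
    model_b = massunivariate_regression(
        fd_smooth, odor, age, image_covariate=mvf_smooth, mask=mask
    )
    mvf_model = massunivariate_regression(mvf_smooth, odor, age, mask=mask)
    corr = crossmodal_correlation(fd_smooth, mvf_smooth, mask)

    clusters = {
        "fd_odor_model_a": cluster_threshold(
            model_a, cfg.p_voxel, cfg.k_fd, cfg.connectivity, "positive"
        ),
        "fd_odor_model_b": cluster_threshold(
            model_b, cfg.p_voxel, cfg.k_fd, cfg.connectivity, "positive"
        ),
        "mvf_odor": cluster_threshold(
            mvf_model, cfg.p_voxel, cfg.k_mvf, cfg.connectivity, "positive"
        ),
    }
    from .voxelwise import StatMap

    corr_stat = StatMap(
        t=corr.r, p=corr.p, df=corr.n - 2, valid=corr.valid,
        mask=mask.mask, descriptor={"kind": "fd-mvf correlation"},
    )
    clusters["fd_mvf_corr"] = cluster_threshold(
        corr_stat, cfg.p_corr, cfg.k_corr, cfg.connectivity, "positive"
    )
    return {
        "model_a": model_a,
        "model_b": model_b,
        "mvf_model": mvf_model,
        "correlation": corr,
        "clusters": clusters,
    }


def _cluster_table(clusters, atlas) -> pd.DataFrame:
    rows = []
    for name, cset in clusters.items():
        for i, c in enumerate(cset.clusters, start=1):
            lid = atlas.labels[c.peak_index]
            roi = atlas.label_table.get(int(lid), ("background", "-"))[0]
            rows.append(
                {
                    "analysis": name,
                    "cluster": i,
                    "size": c.size,
                    "peak_stat": c.peak_stat,
                    "peak_i": c.peak_index[0],
                    "peak_j": c.peak_index[1],
                    "peak_k": c.peak_index[2],
                    "peak_roi": roi,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "analysis", "cluster", "size", "peak_stat",
            "peak_i", "peak_j", "peak_k", "peak_roi",
        ],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run every stage on a fresh phantom cohort and write the artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_yaml(config, outdir / "config.yaml")

    n_hc, n_mci = config.cohort.n_hc, config.cohort.n_mci
    if n_hc + n_mci == 0:
        (outdir / "manifest.json").write_text(
            json.dumps({"seed": config.seed, "n_subjects": 0, "note": "empty cohort"}, indent=2)
        )
        return outdir
    cohort = simulate_cohort(n_hc, n_mci, config.cohort, seed=config.seed)
    write_cohort(cohort, outdir / "cohort")

    fdmaps, mask = derive_fd_maps(
        cohort, config.flair, config.dir, config.epsilon_rel, config.normalize
    )
    vs = cohort.phantom.voxel_size
    for s, m in zip(cohort.subjects, fdmaps):
        write_volume(np.nan_to_num(m.fd, nan=0.0), outdir / "fd" / f"{s.id}_fd.nii.gz", vs)
    write_volume(mask.mask.astype(np.uint8), outdir / "fd" / "analysis_mask.nii.gz", vs)

    atlas = cohort.phantom
    cov = cohort.covariates_frame()
    labels = cov["group"].to_numpy()
    rois = analysis_rois(atlas)
    fd_tab = roi_table(fdmaps, atlas, index=cov["id"])[rois]
    mvf_tab = roi_table([s.mvf_vol for s in cohort.subjects], atlas, mask, index=cov["id"])[rois]
    fd_tab.to_csv(outdir / "roi_fd.tsv", sep="\t")
    mvf_tab.to_csv(outdir / "roi_mvf.tsv", sep="\t")

    anc_fd = ancova_table(fd_tab, labels, cov["age"])
    anc_mvf = ancova_table(mvf_tab, labels, cov["age"])
    anc_fd.to_csv(outdir / "ancova_fd.tsv", sep="\t")
    anc_mvf.to_csv(outdir / "ancova_mvf.tsv", sep="\t")

    grid = classification_grid(
        fd_tab, mvf_tab, cov, labels, atlas,
        k_folds=config.k_folds, seed=config.seed, var_threshold=config.var_threshold,
    )
    (outdir / "classification.json").write_text(
        json.dumps({k: round(v.auc, 4) for k, v in grid.items()}, indent=2)
    )

    fd_sm = smoothed_maps(fdmaps, cohort, config.fwhm_mm, mask)
    mvf_sm = smoothed_maps([s.mvf_vol for s in cohort.subjects], cohort, config.fwhm_mm, mask)
    vw = voxelwise_analyses(cohort, fd_sm, mvf_sm, mask, config)
    write_volume(np.nan_to_num(vw["model_a"].t, nan=0.0), outdir / "voxelwise" / "fd_odor_t.nii.gz", vs)
    write_volume(np.nan_to_num(vw["model_a"].p, nan=1.0), outdir / "voxelwise" / "fd_odor_p.nii.gz", vs)
    write_volume(vw["model_a"].valid.astype(np.uint8), outdir / "voxelwise" / "valid_mask.nii.gz", vs)
    write_volume(np.nan_to_num(vw["correlation"].r, nan=0.0), outdir / "voxelwise" / "fd_mvf_r.nii.gz", vs)
    _cluster_table(vw["clusters"], atlas).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "n_hc": n_hc,
        "n_mci": n_mci,
        "thresholds": {
            "epsilon_rel": config.epsilon_rel,
            "fwhm_mm": config.fwhm_mm,
            "p_voxel": config.p_voxel,
            "k_fd": config.k_fd,
            "k_mvf": config.k_mvf,
            "p_corr": config.p_corr,
            "k_corr": config.k_corr,
        },
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
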