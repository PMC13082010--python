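"""Mass-univariate maps: per-voxel regression, cluster extent, correlation.

At each masked voxel the map value is regressed on an intercept, the
predictor of interest, scalar covariates, and optionally that voxel's value
from a second image modality (an image covariate, the device used to ask
whether the FD-odor association survives adjustment for local myelin).
Suprathreshold voxels are grouped into connected components and filtered by
a minimum cluster extent k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .fdpipe import BrainMask

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterSet",
    "CorrelationMap",
    "massunivariate_regression",
    "cluster_threshold",
    "crossmodal_correlation",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """Per-voxel t and p volumes for one regression coefficient."""

    t: np.ndarray
    p: np.ndarray
    df: int
    valid: np.ndarray
    mask: np.ndarray
    descriptor: dict = field(default_factory=dict)


@dataclass
class Cluster:
    voxels: np.ndarray        # (m, 3) integer indices
    size: int
    peak_stat: float
    peak_index: tuple[int, int, int]


@dataclass
class ClusterSet:
    clusters: list
    p_thresh: float
    k_min: int
    connectivity: int
    sign: str

    def __len__(self) -> int:
        return len(self.clusters)

    def label_volume(self, shape) -> np.ndarray:
        """1-based cluster-id volume (0 = no cluster) in rank order."""
        out = np.zeros(shape, dtype=np.int32)
        for i, c in enumerate(self.clusters, start=1):
            out[tuple(c.voxels.T)] = i
        return out


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps], axis=0)
    return arr


def massunivariate_regression(
    maps,
    predictor,
    covariates=None,
    image_covariate=None,
    mask: BrainMask | None = None,
) -> StatMap:
    """Per-voxel OLS of map value on the predictor (+ covariates).

    ``maps`` is a sequence of per-subject 3D volumes; ``covariates`` an
    (n_subjects, n_cov) array or None; ``image_covariate`` an optional
    matching sequence of volumes whose voxel value joins the design at that
    voxel. Returns t and two-sided p for the predictor coefficient. Voxels
    with a rank-deficient design or (near-)zero residual variance are marked
    invalid (t and p set to NaN), never raised.
    """
    Y4 = _stack(maps)
    n = Y4.shape[0]
    pred = np.asarray(predictor, dtype=float)
    if pred.shape != (n,):
        raise ValueError(f"predictor length {pred.shape} does not match {n} subjects")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match number of subjects")
    C4 = None
    if image_covariate is not None:
        C4 = _stack(image_covariate)
        if C4.shape != Y4.shape:
            raise ValueError("image covariate grid/subject mismatch with maps")

    m = mask.mask if mask is not None else np.ones(Y4.shape[1:], dtype=bool)
    # listwise: drop voxels non-finite in any subject for any input
    finite = np.isfinite(Y4).all(axis=0)
    if C4 is not None:
        finite &= np.isfinite(C4).all(axis=0)
    m = m & finite

    Y = Y4[:, m]                                      # (n, V)
    base_cols = [np.ones(n), pred]
    if cov is not None:
        base_cols.extend(cov.T)
    B = np.column_stack(base_cols)                    # (n, k)
    k = B.shape[1]
    ncols = k + (1 if C4 is not None else 0)
    if n < ncols + 2:
        raise ValueError(f"need at least {ncols + 2} subjects for {ncols} design columns")
    df = n - ncols
    V = Y.shape[1]
    j = 1  # predictor column index

    if C4 is None:
        G = B.T @ B
        Ginv = np.linalg.inv(G)
        beta = Ginv @ (B.T @ Y)                       # (k, V)
        resid = Y - B @ beta
        ssr = np.einsum("nv,nv->v", resid, resid)
        sigma2 = ssr / df
        se = np.sqrt(np.maximum(sigma2 * Ginv[j, j], 0.0))
        valid_v = se > np.sqrt(np.finfo(float).eps) * np.sqrt(
            np.maximum(np.einsum("nv,nv->v", Y, Y), 1e-300) / n
        )
        tvals = np.full(V, np.nan)
        tvals[valid_v] = beta[j, valid_v] / se[valid_v]
    else:
        C = C4[:, m]                                  # (n, V)
        # batched normal equations with a per-voxel extra column
        BtB = B.T @ B                                 # (k, k)
        BtC = B.T @ C                                 # (k, V)
        CtC = np.einsum("nv,nv->v", C, C)
        G = np.empty((V, ncols, ncols))
        G[:, :k, :k] = BtB
        G[:, :k, k] = BtC.T
        G[:, k, :k] = BtC.T
        G[:, k, k] = CtC
        Xty = np.empty((V, ncols))
        Xty[:, :k] = (B.T @ Y).T
        Xty[:, k] = np.einsum("nv,nv->v", C, Y)
        # singular designs (e.g. constant image covariate collinear with the
        # intercept): detect via determinant relative to the diagonal scale
        detG = np.linalg.det(G)
        scale = np.prod(np.maximum(np.einsum("vii->vi", G), 1e-300), axis=1)
        singular = np.abs(detG) <= 1e-10 * scale
        G_safe = G.copy()
        G_safe[singular] = np.eye(ncols)
        beta = np.linalg.solve(G_safe, Xty[..., None])[..., 0]   # (V, ncols)
        yty = np.einsum("nv,nv->v", Y, Y)
        ssr = yty - np.einsum("vc,vc->v", beta, Xty)
        sigma2 = np.maximum(ssr, 0.0) / df
        Ginv = np.linalg.inv(G_safe)
        se = np.sqrt(np.maximum(sigma2 * Ginv[:, j, j], 0.0))
        valid_v = (~singular) & (
            se > np.sqrt(np.finfo(float).eps) * np.sqrt(np.maximum(yty, 1e-300) / n)
        )
        tvals = np.full(V, np.nan)
        tvals[valid_v] = beta[valid_v, j] / se[valid_v]

    pvals = np.full(V, np.nan)
    pvals[valid_v] = 2.0 * stats.t.sf(np.abs(tvals[valid_v]), df)

    shape = Y4.shape[1:]
    t_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    t_map[m] = tvals
    p_map[m] = pvals
    valid[m] = valid_v
    desc = {
        "predictor": "predictor",
        "n_covariates": 0 if cov is None else cov.shape[1],
        "image_covariate": C4 is not None,
        "n_subjects": n,
    }
    return StatMap(t=t_map, p=p_map, df=df, valid=valid, mask=m, descriptor=desc)


def cluster_threshold(
    statmap: StatMap,
    p_thresh: float,
    k_min: int,
    connectivity: int = 26,
    sign: str = "positive",
) -> ClusterSet:
    """Connected suprathreshold components of size >= ``k_min``.

    Sign selects voxels with positive, negative, or any-direction statistics;
    clusters are sorted by size (descending), ties broken by peak |t|.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if sign not in ("positive", "negative", "two-sided"):
        raise ValueError(f"unknown sign {sign!r}")

    supra = statmap.valid & (statmap.p < p_thresh)
    if sign == "positive":
        supra &= statmap.t > 0
    elif sign == "negative":
        supra &= statmap.t < 0
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labeled, n_comp = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(labeled == lab)
        if len(idx) < k_min:
            continue
        tvals = statmap.t[tuple(idx.T)]
        peak = int(np.argmax(np.abs(tvals)))
        clusters.append(
            Cluster(
                voxels=idx,
                size=len(idx),
                peak_stat=float(tvals[peak]),
                peak_index=tuple(int(v) for v in idx[peak]),
            )
        )
    clusters.sort(key=lambda c: (-c.size, -abs(c.peak_stat)))
    return ClusterSet(
        clusters=clusters,
        p_thresh=p_thresh,
        k_min=k_min,
        connectivity=connectivity,
        sign=sign,
    )


@dataclass
class CorrelationMap:
    r: np.ndarray
    p: np.ndarray
    n: int
    valid: np.ndarray


def crossmodal_correlation(fd_maps, mvf_maps, mask: BrainMask | None = None) -> CorrelationMap:
    """Per-voxel Pearson correlation between two modalities across subjects.

    Voxels where either modality is constant across subjects are invalid
    (r and p set to NaN).
    """
    A = _stack(fd_maps)
    Bv = _stack(mvf_maps)
    if A.shape != Bv.shape:
        raise ValueError("modalities must share subjects and grid")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    m = mask.mask if mask is not None else np.ones(A.shape[1:], dtype=bool)
    m = m & np.isfinite(A).all(axis=0) & np.isfinite(Bv).all(axis=0)

    X = A[:, m]
    Y = Bv[:, m]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt(np.einsum("nv,nv->v", Xc, Xc))
    sy = np.sqrt(np.einsum("nv,nv->v", Yc, Yc))
    valid_v = (sx > 0) & (sy > 0)
    r = np.full(X.shape[1], np.nan)
    r[valid_v] = np.einsum("nv,nv->v", Xc, Yc)[valid_v] / (sx[valid_v] * sy[valid_v])
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, np.nan)
    rr = r[valid_v]
    with np.errstate(divide="ignore"):
        tstat = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, 1e-300))
    p[valid_v] = 2.0 * stats.t.sf(np.abs(tstat), n - 2)

    shape = A.shape[1:]
    r_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    r_map[m] = r
    p_map[m] = p
    valid[m] = valid_v
    return CorrelationMap(r=r_map, p=p_map, n=n, valid=valid)
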