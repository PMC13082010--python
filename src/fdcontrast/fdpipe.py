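"""FD map derivation: masking, low-FLAIR exclusion, clipping, scaling, smoothing.

Order of operations is fixed: brain mask -> epsilon exclusion -> ratio ->
clip negatives -> per-subject min-max scaling -> (optional) smoothing.
Outside-mask voxels are NaN in memory; writers replace them with 0 and save
the mask alongside so files stay standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .relaxometry import ContrastVolume

__all__ = ["BrainMask", "FDMap", "compute_fd", "minmax_normalize", "smooth_volume"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BrainMask:
    """Boolean parenchyma (GM+WM) mask restricting every FD computation."""

    mask: np.ndarray
    provenance: Literal["from-labels", "supplied"] = "supplied"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("brain mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FDMap:
    """An FD volume with its mask and preprocessing bookkeeping.

    ``fd`` is NaN outside the mask. ``n_excluded`` counts voxels dropped from
    the mask for sub-threshold FLAIR; ``n_clipped`` counts negative ratios set
    to zero. ``degenerate`` flags a constant map normalized to all zeros.
    """

    fd: np.ndarray
    mask: BrainMask
    n_clipped: int = 0
    n_excluded: int = 0
    normalized: bool = False
    degenerate: bool = False

    def values(self) -> np.ndarray:
        """Within-mask FD values as a flat array."""
        return self.fd[self.mask.mask]


def _as_array(vol) -> np.ndarray:
    if isinstance(vol, ContrastVolume):
        return vol.signal
    return np.asarray(vol, dtype=float)


def compute_fd(flair, dir, mask: BrainMask, epsilon_rel: float = 1e-6) -> FDMap:
    """Unnormalized FD map (FLAIR - DIR) / FLAIR within the mask.

    Voxels whose FLAIR signal falls below ``epsilon_rel`` times the within-mask
    FLAIR maximum are removed from the mask (near-zero denominators, typically
    deep CSF or brain edges) and counted in ``n_excluded``. Negative ratios —
    noise or partial volume making DIR > FLAIR — are set to zero and counted
    in ``n_clipped``.
    """
    f = _as_array(flair)
    d = _as_array(dir)
    if f.shape != d.shape or f.shape != mask.mask.shape:
        raise ValueError(
            f"shape mismatch: flair {f.shape}, dir {d.shape}, mask {mask.mask.shape}"
        )
    if not epsilon_rel > 0:
        raise ValueError(f"epsilon_rel must be positive, got {epsilon_rel}")

    m = mask.mask
    fmax = f[m].max()
    if fmax <= 0:
        raise ValueError("FLAIR is non-positive everywhere in the mask")
    keep = m & (f >= epsilon_rel * fmax)
    n_excluded = int(m.sum() - keep.sum())
    if not keep.any():
        raise ValueError("no voxels survive the FLAIR epsilon exclusion")

    fd = np.full(f.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (f[keep] - d[keep]) / f[keep]
    n_clipped = int((ratio < 0).sum())
    fd[keep] = np.clip(ratio, 0.0, None)
    return FDMap(
        fd=fd,
        mask=BrainMask(keep, provenance=mask.provenance),
        n_clipped=n_clipped,
        n_excluded=n_excluded,
        normalized=False,
    )


def minmax_normalize(fdmap: FDMap) -> FDMap:
    """Linearly rescale the within-mask FD values to span [0, 1] exactly.

    Idempotent; rank order is preserved. A constant map is defined as all
    zeros with ``degenerate=True``.
    """
    m = fdmap.mask.mask
    vals = fdmap.fd[m]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(fdmap.fd.shape, np.nan)
    if hi == lo:
        out[m] = 0.0
        degenerate = True
    else:
        out[m] = (vals - lo) / (hi - lo)
        degenerate = False
    return FDMap(
        fd=out,
        mask=fdmap.mask,
        n_clipped=fdmap.n_clipped,
        n_excluded=fdmap.n_excluded,
        normalized=True,
        degenerate=degenerate,
    )


def smooth_volume(
    vol: np.ndarray,
    fwhm_mm: float,
    voxel_size,
    mask: BrainMask | None = None,
) -> np.ndarray:
    """Masked Gaussian smoothing with a kernel of given FWHM in mm.

    The per-axis sigma is ``fwhm / (2 sqrt(2 ln 2)) / voxel_size``. With a
    mask, the volume is zero-filled outside, smoothed, and renormalized by the
    smoothed mask (masked-mean convention) so outside values never bleed in
    and a constant field stays constant up to numerical tolerance.
    ``fwhm_mm = 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (vol.ndim,))
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size
    if mask is None:
        return ndimage.gaussian_filter(vol, sigma=sigma)
    m = mask.mask.astype(float)
    num = ndimage.gaussian_filter(np.where(mask.mask, vol, 0.0), sigma=sigma)
    den = ndimage.gaussian_filter(m, sigma=sigma)
    out = np.full(vol.shape, np.nan)
    inside = mask.mask & (den > 0)
    out[inside] = num[inside] / den[inside]
    return out
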