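"""Closed-form inversion-recovery signal models and the analytic FD contrast.

The FD metric is the normalized FLAIR-DIR difference FD = (FLAIR - DIR) / FLAIR.
Both contrasts are modeled under idealized inversion recovery (perfect 180deg
inversions, instantaneous excitation, complete spoiling), so each signal
factorizes as ``pd * A(T1; timings) * exp(-TE / T2)`` where ``A`` is the
longitudinal recovery factor. In the ratio the proton density cancels, making
FD a pure function of T1, T2 and the sequence timings:

    FD = 1 - (A_DIR / A_FLAIR) * exp(-(TE_DIR - TE_FLAIR) / T2)

With clinical FLAIR/DIR timings FD is high in myelin-/lipid-rich tissue
(short T1/T2), which is what makes it a practical myelin-sensitive surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

__all__ = [
    "RelaxationTriplet",
    "IRSequenceParams",
    "DIRSequenceParams",
    "QuantitativeMaps",
    "ContrastVolume",
    "DEFAULT_FLAIR",
    "DEFAULT_DIR",
    "flair_signal",
    "dir_signal",
    "fd_analytic",
    "synthesize_contrast",
]


@dataclass(frozen=True)
class RelaxationTriplet:
    """Voxel relaxation properties: T1 and T2 in ms, proton density in [0, 1]."""

    t1: float
    t2: float
    pd: float

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise ValueError(f"t1 must be positive, got {self.t1}")
        if not self.t2 > 0:
            raise ValueError(f"t2 must be positive, got {self.t2}")
        if not 0.0 <= self.pd <= 1.0:
            raise ValueError(f"pd must lie in [0, 1], got {self.pd}")


@dataclass(frozen=True)
class IRSequenceParams:
    """Single-inversion (FLAIR-type) sequence timings in ms."""

    tr: float
    te: float
    ti: float

    def __post_init__(self) -> None:
        if not 0 < self.ti < self.tr:
            raise ValueError(f"require 0 < ti < tr, got ti={self.ti}, tr={self.tr}")
        if not self.te > 0:
            raise ValueError(f"te must be positive, got {self.te}")


@dataclass(frozen=True)
class DIRSequenceParams:
    """Double-inversion sequence timings in ms.

    ``ti_long`` is the first-inversion-to-readout interval, ``ti_short`` the
    second-inversion-to-readout interval (standard DIR convention: the long
    delay nulls CSF, the short one normal-appearing white matter).
    """

    tr: float
    te: float
    ti_long: float
    ti_short: float

    def __post_init__(self) -> None:
        if not 0 < self.ti_short < self.ti_long < self.tr:
            raise ValueError(
                "require 0 < ti_short < ti_long < tr, got "
                f"ti_short={self.ti_short}, ti_long={self.ti_long}, tr={self.tr}"
            )
        if not self.te > 0:
            raise ValueError(f"te must be positive, got {self.te}")


#: Default synthetic-contrast timings (ms): FLAIR nulls CSF; DIR nulls WM + CSF.
DEFAULT_FLAIR = IRSequenceParams(tr=15000.0, te=90.0, ti=3100.0)
DEFAULT_DIR = DIRSequenceParams(tr=15000.0, te=100.0, ti_long=3800.0, ti_short=470.0)


@dataclass
class QuantitativeMaps:
    """Co-registered T1 / T2 / PD volumes for one subject (shared grid)."""

    t1_vol: np.ndarray
    t2_vol: np.ndarray
    pd_vol: np.ndarray
    voxel_size: tuple[float, float, float] = (1.3, 1.3, 1.3)

    def __post_init__(self) -> None:
        shapes = {self.t1_vol.shape, self.t2_vol.shape, self.pd_vol.shape}
        if len(shapes) != 1:
            raise ValueError(f"t1/t2/pd volumes must share a grid, got shapes {shapes}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1_vol.shape


@dataclass
class ContrastVolume:
    """A synthesized magnitude contrast volume plus its sequence provenance."""

    signal: np.ndarray
    modality: Literal["FLAIR", "DIR"]
    params: Union[IRSequenceParams, DIRSequenceParams]


def _validate_relax_arrays(t1, t2) -> None:
    if np.any(np.asarray(t1) <= 0):
        raise ValueError("t1 must be positive everywhere")
    if np.any(np.asarray(t2) <= 0):
        raise ValueError("t2 must be positive everywhere")


def flair_recovery(t1, params: IRSequenceParams, *, signed: bool = False):
    """Longitudinal recovery factor A_F(T1) for a single inversion.

    ``|1 - 2 exp(-TI/T1) + exp(-TR/T1)|``; the +exp(-TR/T1) term is the
    steady-state correction (negligible at TR = 15 s but kept exact).
    """
    t1 = np.asarray(t1, dtype=float)
    a = 1.0 - 2.0 * np.exp(-params.ti / t1) + np.exp(-params.tr / t1)
    return a if signed else np.abs(a)


def dir_recovery(t1, params: DIRSequenceParams, *, signed: bool = False):
    """Recovery factor A_D(T1) for two perfect inversions before readout."""
    t1 = np.asarray(t1, dtype=float)
    a = (
        1.0
        - 2.0 * np.exp(-params.ti_short / t1)
        + 2.0 * np.exp(-params.ti_long / t1)
        - np.exp(-params.tr / t1)
    )
    return a if signed else np.abs(a)


def _unpack(relax):
    if isinstance(relax, RelaxationTriplet):
        return relax.t1, relax.t2, relax.pd
    t1, t2, pd = relax
    return t1, t2, pd


def flair_signal(relax, params: IRSequenceParams = DEFAULT_FLAIR, *, signed: bool = False):
    """FLAIR magnitude signal ``pd * A_F(T1) * exp(-TE/T2)``.

    ``relax`` is a :class:`RelaxationTriplet` or an (t1, t2, pd) triple of
    scalars/arrays (broadcast voxel-wise).
    """
    t1, t2, pd = _unpack(relax)
    _validate_relax_arrays(t1, t2)
    t2 = np.asarray(t2, dtype=float)
    out = np.asarray(pd, dtype=float) * flair_recovery(t1, params, signed=signed) * np.exp(
        -params.te / t2
    )
    return float(out) if out.ndim == 0 else out


def dir_signal(relax, params: DIRSequenceParams = DEFAULT_DIR, *, signed: bool = False):
    """DIR magnitude signal ``pd * A_D(T1) * exp(-TE/T2)``."""
    t1, t2, pd = _unpack(relax)
    _validate_relax_arrays(t1, t2)
    t2 = np.asarray(t2, dtype=float)
    out = np.asarray(pd, dtype=float) * dir_recovery(t1, params, signed=signed) * np.exp(
        -params.te / t2
    )
    return float(out) if out.ndim == 0 else out


def fd_analytic(
    relax,
    flair: IRSequenceParams = DEFAULT_FLAIR,
    dir: DIRSequenceParams = DEFAULT_DIR,
):
    """Analytic FD value ``1 - (A_D/A_F) exp(-(TE_D - TE_F)/T2)``.

    Equals (flair_signal - dir_signal) / flair_signal exactly and is
    independent of proton density (M0 cancellation). Raises where the FLAIR
    recovery factor vanishes (the ratio is undefined there).
    """
    t1, t2, _ = _unpack(relax)
    _validate_relax_arrays(t1, t2)
    t2 = np.asarray(t2, dtype=float)
    a_f = flair_recovery(t1, flair)
    if np.any(a_f == 0):
        raise ZeroDivisionError("FLAIR recovery factor is zero: FD undefined")
    a_d = dir_recovery(t1, dir)
    out = 1.0 - (a_d / a_f) * np.exp(-(dir.te - flair.te) / t2)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def synthesize_contrast(
    maps: QuantitativeMaps,
    params: Union[IRSequenceParams, DIRSequenceParams, None] = None,
    modality: Literal["FLAIR", "DIR"] | None = None,
    *,
    signed: bool = False,
) -> ContrastVolume:
    """Voxel-wise contrast synthesis from quantitative maps.

    Either ``modality`` or ``params`` (or both, consistently) must be given;
    defaults fall back to the standard clinical timings.
    """
    if params is None and modality is None:
        raise ValueError("specify modality and/or params")
    if params is None:
        params = DEFAULT_FLAIR if modality == "FLAIR" else DEFAULT_DIR
    if modality is None:
        modality = "FLAIR" if isinstance(params, IRSequenceParams) else "DIR"
    if modality == "FLAIR":
        if not isinstance(params, IRSequenceParams):
            raise TypeError("FLAIR synthesis needs IRSequenceParams")
        sig = flair_signal((maps.t1_vol, maps.t2_vol, maps.pd_vol), params, signed=signed)
    elif modality == "DIR":
        if not isinstance(params, DIRSequenceParams):
            raise TypeError("DIR synthesis needs DIRSequenceParams")
        sig = dir_signal((maps.t1_vol, maps.t2_vol, maps.pd_vol), params, signed=signed)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return ContrastVolume(signal=np.asarray(sig), modality=modality, params=params)
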