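"""Seeded two-group digital relaxometry phantoms.

Generates co-registered T1/T2/PD/myelin-fraction volumes on a labeled
geometric "brain": a deep white-matter ellipsoid with three callosum-like
tract blocks, a central CSF ventricle, and spherical gray-matter ROIs named
after the olfactory-limbic structures a group study would target
(hippocampus, amygdala, thalamus, insula, orbitofrontal cortex, anterior
olfactory nucleus, parahippocampal gyrus).

The impaired group (MCI) carries demyelination-like relaxation shifts
(T1 up, T2 up, myelin fraction down) restricted to configurable ROIs, and an
odor-identification score linked linearly to the subject's mean myelin
fraction over olfactory ROIs, so every downstream analysis (group ANCOVA,
classification, voxel-wise odor regression, FD-MVF correspondence) has a
planted ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .fdpipe import BrainMask
from .relaxometry import QuantitativeMaps

__all__ = [
    "LabelPhantom",
    "TissueClassParams",
    "GroupEffect",
    "CohortConfig",
    "Subject",
    "Cohort",
    "build_label_phantom",
    "simulate_subject",
    "simulate_cohort",
    "parenchyma_mask",
    "ODOR_ROIS",
    "DEFAULT_AFFECTED_ROIS",
]

TissueClass = Literal["CSF", "GM", "WM"]

#: ROIs whose mean myelin fraction drives the odor-identification score.
ODOR_ROIS = (
    "hippocampus_l",
    "hippocampus_r",
    "insula_l",
    "insula_r",
    "aon_l",
    "aon_r",
)

#: ROIs carrying the demyelination-like shift in the impaired group by default.
DEFAULT_AFFECTED_ROIS = (
    "hippocampus_l",
    "hippocampus_r",
    "amygdala_l",
    "thalamus_l",
    "orbitofrontal_l",
    "aon_l",
    "aon_r",
    "cc_body",
    "cc_splenium",
)

# (name, fractional center, radius scale). GM ROIs are spheres (radius scale
# is relative to the default GM radius; the anterior olfactory nuclei are
# genuinely small structures), callosum segments are boxes on the midline.
# Spheres are painted last, so where a large ROI brushes a neighbour the
# sphere wins and the invariant check guards minimum sizes.
_GM_ROIS: list[tuple[str, tuple[float, float, float], float]] = [
    ("hippocampus_l", (0.30, 0.38, 0.38), 1.0),
    ("hippocampus_r", (0.70, 0.38, 0.38), 1.0),
    ("amygdala_l", (0.32, 0.60, 0.34), 1.0),
    ("amygdala_r", (0.68, 0.60, 0.34), 1.0),
    ("thalamus_l", (0.36, 0.50, 0.58), 1.0),
    ("thalamus_r", (0.64, 0.50, 0.58), 1.0),
    ("insula_l", (0.20, 0.55, 0.50), 1.0),
    ("insula_r", (0.80, 0.55, 0.50), 1.0),
    ("orbitofrontal_l", (0.36, 0.72, 0.44), 1.0),
    ("parahippocampal_l", (0.24, 0.26, 0.26), 1.0),
    ("aon_l", (0.43, 0.84, 0.30), 0.75),
    ("aon_r", (0.57, 0.84, 0.30), 0.75),
]
_CC_ROIS: list[tuple[str, tuple[float, float, float]]] = [
    ("cc_genu", (0.50, 0.68, 0.58)),
    ("cc_body", (0.50, 0.52, 0.62)),
    ("cc_splenium", (0.50, 0.36, 0.58)),
]

#: CSF-like relaxation for the periventricular partial-volume shell. These
#: voxels sit inside the parenchyma mask (as they do in a T1-segmentation
#: mask) but have near-null FLAIR recovery and DIR > FLAIR, so they exercise
#: the negative-FD clipping rule and pin each subject's within-mask minimum
#: at zero, as in real FD maps.
PV_SHELL_PARAMS = dict(t1=4800.0, t2=800.0, pd=0.90, myelin=0.0)


@dataclass
class LabelPhantom:
    """Integer-label ROI atlas volume (label 0 = background)."""

    labels: np.ndarray
    label_table: dict[int, tuple[str, TissueClass]]
    voxel_size: tuple[float, float, float]

    def id_of(self, name: str) -> int:
        for lid, (nm, _) in self.label_table.items():
            if nm == name:
                return lid
        raise KeyError(f"no ROI named {name!r}")

    def names(self) -> list[str]:
        return [nm for nm, _ in self.label_table.values()]

    def ids_by_class(self, tissue_class: TissueClass) -> list[int]:
        return [lid for lid, (_, tc) in self.label_table.items() if tc == tissue_class]

    def roi_mask(self, name: str) -> np.ndarray:
        return self.labels == self.id_of(name)

    def counts(self) -> dict[str, int]:
        return {
            nm: int((self.labels == lid).sum())
            for lid, (nm, _) in self.label_table.items()
        }


def build_label_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size: tuple[float, float, float] = (1.3, 1.3, 1.3),
    seed: int | None = None,
    k_min_cluster: int = 60,
) -> LabelPhantom:
    """Deterministic label phantom; geometry depends only on ``shape``.

    The ``seed`` argument is accepted for interface symmetry with the
    stochastic generators; the geometry itself is deterministic, so identical
    calls always return identical volumes.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError(f"each extent must be >= 32 to place all ROIs, got {shape}")

    nx, ny, nz = shape
    ix, iy, iz = np.indices(shape)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0

    def ellipsoid(center_frac, semi_frac):
        c = np.array(center_frac) * (np.array(shape) - 1)
        s = np.array(semi_frac) * np.array(shape)
        return (
            ((ix - c[0]) / s[0]) ** 2
            + ((iy - c[1]) / s[1]) ** 2
            + ((iz - c[2]) / s[2]) ** 2
        ) <= 1.0

    labels = np.zeros(shape, dtype=np.int32)
    table: dict[int, tuple[str, TissueClass]] = {}

    # deep WM envelope
    wm = ellipsoid((0.5, 0.5, 0.5), (0.36, 0.40, 0.34))
    labels[wm] = 1
    table[1] = ("deep_wm", "WM")

    # central CSF ventricle with a partial-volume shell inside the mask
    shell = ellipsoid((0.5, 0.5, 0.52), (0.085, 0.15, 0.085))
    labels[shell] = 3
    table[3] = ("periventricular_pv", "GM")
    vent = ellipsoid((0.5, 0.5, 0.52), (0.06, 0.12, 0.06))
    labels[vent] = 2
    table[2] = ("ventricle", "CSF")

    # callosum-like tract blocks (midline boxes)
    hx = max(3, round(0.080 * nx))
    hy = max(2, round(0.055 * ny))
    hz = max(2, round(0.050 * nz))
    next_id = 4
    for name, (fx, fy, fz) in _CC_ROIS:
        c = np.array([fx * (nx - 1), fy * (ny - 1), fz * (nz - 1)])
        box = (
            (np.abs(ix - c[0]) <= hx)
            & (np.abs(iy - c[1]) <= hy)
            & (np.abs(iz - c[2]) <= hz)
        )
        labels[box] = next_id
        table[next_id] = (name, "WM")
        next_id += 1

    # gray-matter ROI spheres
    r0 = max(3.0, 0.0875 * min(shape))
    for name, (fx, fy, fz), rscale in _GM_ROIS:
        r = max(3.0, rscale * r0)
        c = np.array([fx * (nx - 1), fy * (ny - 1), fz * (nz - 1)])
        sphere = ((ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2) <= r**2
        labels[sphere] = next_id
        table[next_id] = (name, "GM")
        next_id += 1

    phantom = LabelPhantom(labels=labels, label_table=table, voxel_size=tuple(voxel_size))
    # minimum-size guard applies to the analysis ROIs (where cluster tests
    # run), not to the CSF/partial-volume mask compartments
    bad = {
        nm: n
        for nm, n in phantom.counts().items()
        if n < k_min_cluster and nm not in NON_ANALYSIS_ROIS
    }
    if bad:
        raise ValueError(
            f"shape {shape} too small: ROIs below {k_min_cluster} voxels: {bad}"
        )
    return phantom


#: Mask compartments that are not anatomical target ROIs: excluded from ROI
#: statistics (the ventricle lies outside the parenchyma mask entirely; the
#: periventricular shell is partial volume, not a structure).
NON_ANALYSIS_ROIS = ("ventricle", "periventricular_pv")


def analysis_rois(phantom: LabelPhantom) -> list[str]:
    """Names of the atlas ROIs that enter group statistics and classification."""
    return [nm for nm in phantom.names() if nm not in NON_ANALYSIS_ROIS]


def parenchyma_mask(phantom: LabelPhantom) -> BrainMask:
    """Combined GM+WM analysis mask (ventricle and background excluded)."""
    keep = np.isin(
        phantom.labels, phantom.ids_by_class("GM") + phantom.ids_by_class("WM")
    )
    return BrainMask(keep, provenance="from-labels")


@dataclass(frozen=True)
class TissueClassParams:
    """Class-mean relaxation and myelin values (T1/T2 in ms)."""

    t1: float
    t2: float
    pd: float
    myelin: float


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative mean shifts applied to affected ROIs in the MCI group."""

    dt1_rel: float = 0.12
    dt2_rel: float = 0.14
    dmyelin_rel: float = -0.15


@dataclass
class CohortConfig:
    """Full generation parameters for a two-group phantom cohort.

    Subject-level biology: each ROI draws a fractional myelin deviation
    ``delta ~ N(0, myelin_rel_sd)``; T1 and T2 move against it through the
    coupling coefficients (demyelination lengthens both), plus independent
    relaxation jitter, so the FD contrast tracks myelin without being a
    deterministic function of it. ``mvf_deviation_share`` < 1 attenuates how
    much of the subject deviation the observed MVF volume carries, giving the
    FD maps signal partially independent of MVF.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (1.3, 1.3, 1.3)
    n_hc: int = 16
    n_mci: int = 17
    tissue: dict = field(
        default_factory=lambda: {
            "WM": TissueClassParams(t1=850.0, t2=70.0, pd=0.70, myelin=0.30),
            "GM": TissueClassParams(t1=1300.0, t2=90.0, pd=0.85, myelin=0.10),
            "CSF": TissueClassParams(t1=4300.0, t2=1500.0, pd=1.00, myelin=0.0),
        }
    )
    group_effects: dict = field(
        default_factory=lambda: {name: GroupEffect() for name in DEFAULT_AFFECTED_ROIS}
    )
    roi_overrides: dict = field(
        default_factory=lambda: {
            "periventricular_pv": TissueClassParams(**PV_SHELL_PARAMS)
        }
    )
    myelin_rel_sd: float = 0.12
    t1_coupling: float = 0.4
    t2_coupling: float = 0.5
    indep_relax_rel_sd: float = 0.02
    # smooth within-tissue heterogeneity (per-subject random fields):
    # myelin varies spatially and drags T1/T2 along through the couplings;
    # a smaller independent relaxation field decorrelates FD from myelin.
    myelin_field_rel_sd: float = 0.10
    relax_field_rel_sd: float = 0.02
    field_fwhm_mm: float = 6.0
    voxel_noise_rel: float = 0.03
    mvf_noise_sd: float = 0.02
    # Fraction of the myelin-related variance (subject deviations, spatial
    # field, and the disease shift) that the observed MVF map captures.
    # 1.0 makes MVF a perfect myelin proxy; below 1.0 part of the
    # microstructural signal is visible to FD (through relaxation) but not
    # to MVF — an imperfect multi-compartment fit.
    mvf_deviation_share: float = 1.0
    age_hc: tuple[float, float] = (63.50, 6.55)
    age_mci: tuple[float, float] = (70.35, 8.09)
    age_bounds: tuple[float, float] = (50.0, 90.0)
    odor_link: Literal["calibrated", "none"] = "calibrated"
    odor_hc_mean: float = 16.50
    odor_mci_mean: float = 13.94
    odor_eps_sd: float = 1.75
    odor_max: int = 20

    @classmethod
    def null(cls, **kwargs) -> "CohortConfig":
        """No planted effects: groups exchangeable, odor independent of maps."""
        kwargs.setdefault("group_effects", {})
        kwargs.setdefault("odor_link", "none")
        kwargs.setdefault("age_mci", (63.50, 6.55))
        return cls(**kwargs)

    @classmethod
    def partial_mvf(cls, share: float = 0.5, **kwargs) -> "CohortConfig":
        """Observed MVF carries only part of the subject myelin deviation."""
        kwargs.setdefault("mvf_deviation_share", share)
        return cls(**kwargs)


@dataclass
class Subject:
    id: str
    group: Literal["HC", "MCI"]
    age: float
    odor_id: int
    maps: QuantitativeMaps
    mvf_vol: np.ndarray
    truth: dict


@dataclass
class Cohort:
    subjects: list
    phantom: LabelPhantom
    config: CohortConfig
    seed: int

    def covariates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "odor_id": [s.odor_id for s in self.subjects],
            }
        )


def _roi_means_for_group(phantom: LabelPhantom, config: CohortConfig, group: str):
    """Per-label subject-mean tissue parameters after group shifts."""
    out = {}
    for lid, (name, tclass) in phantom.label_table.items():
        base = config.roi_overrides.get(name, config.tissue[tclass])
        eff = config.group_effects.get(name) if group == "MCI" else None
        if eff is None:
            out[lid] = (base.t1, base.t2, base.pd, base.myelin)
        else:
            out[lid] = (
                base.t1 * (1.0 + eff.dt1_rel),
                base.t2 * (1.0 + eff.dt2_rel),
                base.pd,
                base.myelin * (1.0 + eff.dmyelin_rel),
            )
    return out


def _expected_odor_myelin(phantom: LabelPhantom, config: CohortConfig, group: str) -> float:
    counts = phantom.counts()
    means = _roi_means_for_group(phantom, config, group)
    name_to_id = {nm: lid for lid, (nm, _) in phantom.label_table.items()}
    num = den = 0.0
    for roi in ODOR_ROIS:
        lid = name_to_id[roi]
        n = counts[roi]
        num += n * means[lid][3]
        den += n
    return num / den


def odor_link_coefficients(phantom: LabelPhantom, config: CohortConfig) -> tuple[float, float]:
    """Closed-form (a, b) for odor = a + b * mean-olfactory-myelin.

    Calibrated so the expected group means equal the configured targets.
    With ``odor_link='none'`` the slope is zero and both groups share the HC
    target mean.
    """
    if config.odor_link == "none":
        return config.odor_hc_mean, 0.0
    e_hc = _expected_odor_myelin(phantom, config, "HC")
    e_mci = _expected_odor_myelin(phantom, config, "MCI")
    if abs(e_hc - e_mci) < 1e-12:
        raise ValueError(
            "cannot calibrate the odor link: groups have identical expected "
            "olfactory-ROI myelin; use odor_link='none' for null cohorts"
        )
    b = (config.odor_hc_mean - config.odor_mci_mean) / (e_hc - e_mci)
    a = config.odor_hc_mean - b * e_hc
    return a, b


def _smooth_unit_field(shape, fwhm_mm, voxel_size, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with given FWHM."""
    from scipy import ndimage

    white = rng.standard_normal(shape)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size, float)
    field = ndimage.gaussian_filter(white, sigma=sigma)
    sd = field.std()
    return field / sd if sd > 0 else field


def simulate_subject(
    phantom: LabelPhantom,
    config: CohortConfig,
    group: Literal["HC", "MCI"],
    rng: np.random.Generator,
    subject_id: str = "sub-000",
    odor_coeffs: tuple[float, float] | None = None,
) -> Subject:
    """Draw one subject: ROI-level biology, voxel noise, covariates."""
    if rng is None:
        raise ValueError("an explicit numpy Generator is required (no global state)")
    if odor_coeffs is None:
        odor_coeffs = odor_link_coefficients(phantom, config)
    a, b = odor_coeffs

    means = _roi_means_for_group(phantom, config, group)
    shape = phantom.labels.shape
    t1 = np.full(shape, 800.0)
    t2 = np.full(shape, 60.0)
    pdv = np.zeros(shape)
    myelin_true = np.zeros(shape)
    mvf_signal = np.zeros(shape)

    # MVF observes a fraction w of the myelin-related variance: subject
    # deviations and the spatial field split into a component MVF sees
    # (weight sqrt(w)) and one it misses (weight sqrt(1-w)); the disease
    # shift on the MVF mean is scaled by w directly.
    w = float(config.mvf_deviation_share)
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"mvf_deviation_share must lie in [0, 1], got {w}")
    sw, sh = np.sqrt(w), np.sqrt(1.0 - w)

    base_means = _roi_means_for_group(phantom, config, "HC")
    truth = {}
    for lid, (name, tclass) in phantom.label_table.items():
        m_t1, m_t2, m_pd, m_my = means[lid]
        if m_my > 0:
            d_obs = rng.normal(0.0, config.myelin_rel_sd * sw)
            d_hid = rng.normal(0.0, config.myelin_rel_sd * sh)
        else:
            d_obs = d_hid = 0.0
        delta = d_obs + d_hid
        eta1, eta2 = rng.normal(0.0, config.indep_relax_rel_sd, size=2)
        s_my = float(np.clip(m_my * (1.0 + delta), 0.0, 1.0))
        s_t1 = m_t1 * (1.0 - config.t1_coupling * delta) * (1.0 + eta1)
        s_t2 = m_t2 * (1.0 - config.t2_coupling * delta) * (1.0 + eta2)
        # MVF mean carries only the visible fraction of the disease shift
        m_my_base = base_means[lid][3]
        m_my_mvf = m_my_base + w * (m_my - m_my_base)
        s_mvf = float(np.clip(m_my_mvf * (1.0 + d_obs), 0.0, 1.0))
        sel = phantom.labels == lid
        t1[sel] = s_t1
        t2[sel] = s_t2
        pdv[sel] = m_pd
        myelin_true[sel] = s_my
        mvf_signal[sel] = s_mvf
        truth[name] = {"t1": s_t1, "t2": s_t2, "pd": m_pd, "myelin": s_my, "delta": delta}

    # smooth within-tissue heterogeneity: a myelin field drags T1/T2 along
    # through the couplings; independent relaxation fields decorrelate FD
    # from myelin at voxel scale
    nz = phantom.labels > 0
    h_my, h_rel = config.myelin_field_rel_sd, config.relax_field_rel_sd
    if h_my > 0 or h_rel > 0:
        vs, fw = phantom.voxel_size, config.field_fwhm_mm
        f_obs = _smooth_unit_field(shape, fw, vs, rng)
        f_hid = _smooth_unit_field(shape, fw, vs, rng)
        r1_field = _smooth_unit_field(shape, fw, vs, rng)
        r2_field = _smooth_unit_field(shape, fw, vs, rng)
        m_field = sw * f_obs + sh * f_hid
        has_my = myelin_true > 0
        myelin_true[has_my] *= 1.0 + h_my * m_field[has_my]
        mvf_signal[has_my] *= 1.0 + h_my * sw * f_obs[has_my]
        my_mod = np.where(has_my, h_my * m_field, 0.0)
        t1[nz] *= (1.0 - config.t1_coupling * my_mod[nz]) * (1.0 + h_rel * r1_field[nz])
        t2[nz] *= (1.0 - config.t2_coupling * my_mod[nz]) * (1.0 + h_rel * r2_field[nz])
        np.clip(myelin_true, 0.0, 1.0, out=myelin_true)
        np.clip(mvf_signal, 0.0, 1.0, out=mvf_signal)

    # voxel-level noise, proportional to the local tissue value
    v = config.voxel_noise_rel
    if v > 0:
        t1[nz] *= 1.0 + rng.normal(0.0, v, size=int(nz.sum()))
        t2[nz] *= 1.0 + rng.normal(0.0, v, size=int(nz.sum()))
        pdv[nz] = np.clip(pdv[nz] * (1.0 + rng.normal(0.0, v, size=int(nz.sum()))), 0.0, 1.0)
    np.clip(t1, 1.0, None, out=t1)
    np.clip(t2, 1.0, None, out=t2)
    mvf = mvf_signal.copy()
    if config.mvf_noise_sd > 0:
        mvf[nz] += rng.normal(0.0, config.mvf_noise_sd, size=int(nz.sum()))
    np.clip(mvf, 0.0, 1.0, out=mvf)

    mu, sd = config.age_hc if group == "HC" else config.age_mci
    lo, hi = config.age_bounds
    age = float(
        stats.truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd, random_state=rng)
    )

    # mean myelin fraction of the actual map over the olfactory labels: this
    # includes the spatial heterogeneity the subject carries, not just the
    # ROI-level draw
    name_to_id = {nm: lid for lid, (nm, _) in phantom.label_table.items()}
    odor_sel = np.isin(phantom.labels, [name_to_id[r] for r in ODOR_ROIS])
    mean_my = float(myelin_true[odor_sel].mean())
    score = a + b * mean_my + rng.normal(0.0, config.odor_eps_sd)
    odor = int(np.clip(round(score), 0, config.odor_max))

    maps = QuantitativeMaps(
        t1_vol=t1, t2_vol=t2, pd_vol=pdv, voxel_size=phantom.voxel_size
    )
    truth["_mean_olfactory_myelin"] = mean_my
    return Subject(
        id=subject_id, group=group, age=age, odor_id=odor, maps=maps, mvf_vol=mvf, truth=truth
    )


def simulate_cohort(
    n_hc: int = 16,
    n_mci: int = 17,
    config: CohortConfig | None = None,
    seed: int | None = None,
    phantom: LabelPhantom | None = None,
) -> Cohort:
    """Generate a full two-group cohort from one top-level seed.

    Each subject draws from an independent child stream of the seed, so the
    cohort is bit-reproducible and insensitive to consumption order.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if config is None:
        config = CohortConfig()
    config.n_hc, config.n_mci = n_hc, n_mci
    if phantom is None:
        phantom = build_label_phantom(config.shape, config.voxel_size)
    coeffs = odor_link_coefficients(phantom, config)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_hc + n_mci)
    subjects = []
    groups = ["HC"] * n_hc + ["MCI"] * n_mci
    for i, (grp, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        subjects.append(
            simulate_subject(
                phantom, config, grp, rng, subject_id=f"sub-{i + 1:03d}", odor_coeffs=coeffs
            )
        )
    return Cohort(subjects=subjects, phantom=phantom, config=config, seed=seed)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject NIfTI volumes, the label atlas, and covariates.tsv."""
    from .io import write_volume

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = cohort.phantom.voxel_size
    write_volume(cohort.phantom.labels.astype(np.int16), outdir / "atlas_labels.nii.gz", vs)
    for s in cohort.subjects:
        sdir = outdir / s.id
        sdir.mkdir(exist_ok=True)
        write_volume(s.maps.t1_vol, sdir / "t1.nii.gz", vs)
        write_volume(s.maps.t2_vol, sdir / "t2.nii.gz", vs)
        write_volume(s.maps.pd_vol, sdir / "pd.nii.gz", vs)
        write_volume(s.mvf_vol, sdir / "mvf.nii.gz", vs)
    df = cohort.covariates_frame()
    df.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    return outdir
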