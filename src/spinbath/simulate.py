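"""Synthetic cohorts, ground-truth tissue parameters, and noisy MT phantoms.

The generator emulates the study design the analysis expects: three groups
(healthy controls, premanifest mutation carriers, manifest patients) of 10
subjects each, caudate tissue parameters that shift with disease burden
(restricted-pool fraction elevated and restricted-pool T2 shortened in
manifest disease), Rician magnitude noise, and demographics matching the
clinical cohort (carriers age ~40.6 +/- 9.1 with CAG ~42.5 +/- 2.4;
patients ~54.2 +/- 12.7 with CAG ~43.7 +/- 2.8).

Every generator is a pure function of its inputs and the configured seed.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .acquisition import MTAcquisition
from .clinical import disease_burden_score
from .model import steady_state_signal
from .stack_io import MTImageStack
from .tissue import TissueParameters

GROUPS = ("control", "premanifest", "manifest")

# physiological sampling bounds; resampling beyond these aborts
PARAM_BOUNDS = {
    "f": (0.001, 0.35),
    "kr": (1.0, 100.0),
    "t2r": (5e-6, 20e-6),
    "t2f": (30e-3, 120e-3),
    "t1f": (0.5, 3.0),
    "sdf": (0.2, 2.0),
}

COHORT_COLUMNS = ["subject_id", "group", "sex", "age_years", "cag_repeats", "dbs"]


class EffectConfigError(ValueError):
    """Raised for an invalid synthetic-effect configuration."""


class StackConstructionError(ValueError):
    """Raised when the phantom geometry cannot be constructed."""


class GroupEffect(BaseModel):
    """Ground-truth distribution of one group's caudate tissue and demographics."""

    model_config = ConfigDict(extra="forbid")

    f_mean: float
    f_sd: float = 0.005
    kr_mean: float = 20.0
    kr_sd: float = 1.0
    t2r_mean_s: float
    t2r_sd_s: float = 0.25e-6
    t2f_mean_s: float = 60e-3
    t2f_sd_s: float = 1.5e-3
    t1f_mean_s: float = 1.20
    t1f_sd_s: float = 0.03
    sdf_mean: float = 1.0
    sdf_sd: float = 0.015
    age_mean: float = 48.0
    age_sd: float = 13.0
    cag_mean: Optional[float] = None
    cag_sd: Optional[float] = None
    p_female: float = 0.5
    dbs_reference: float = 0.0
    # only the transition group tracks disease burden continuously; manifest
    # disease is modeled as a plateau at the group mean
    dbs_coupled: bool = False

    @model_validator(mode="after")
    def _check(self) -> "GroupEffect":
        if not 0.0 <= self.f_mean <= 0.35:
            raise EffectConfigError("group mean pool ratio outside [0, 0.35]")
        if not 5e-6 <= self.t2r_mean_s <= 20e-6:
            raise EffectConfigError("group mean T2r outside [5, 20] microseconds")
        if not 30e-3 <= self.t2f_mean_s <= 120e-3:
            raise EffectConfigError("group mean T2f outside [30, 120] ms")
        for name in ("f_sd", "kr_sd", "t2r_sd_s", "t2f_sd_s", "t1f_sd_s", "sdf_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise EffectConfigError(f"{name} must be nonnegative")
        if (self.cag_mean is None) != (self.cag_sd is None):
            raise EffectConfigError("cag_mean and cag_sd must be given together")
        if not 0.0 <= self.p_female <= 1.0:
            raise EffectConfigError("p_female must be in [0, 1]")
        return self


def default_group_effects() -> dict[str, GroupEffect]:
    """Default group-level ground truth.

    Pool ratio rises and restricted-pool T2 falls from controls through
    premanifest carriers to manifest patients, with overlapping spreads so a
    disease-burden continuum ("transition zone") exists rather than three
    well-separated islands.
    """
    return {
        "control": GroupEffect(
            f_mean=0.10, t2r_mean_s=11.0e-6, t2f_mean_s=60e-3, t1f_mean_s=1.20,
            sdf_mean=1.00, age_mean=48.0, age_sd=13.0, p_female=0.5,
        ),
        "premanifest": GroupEffect(
            f_mean=0.11, t2r_mean_s=10.5e-6, t2f_mean_s=62e-3, t1f_mean_s=1.25,
            sdf_mean=0.98, age_mean=40.6, age_sd=9.1, cag_mean=42.5, cag_sd=2.4,
            p_female=0.9, dbs_reference=284.2, dbs_coupled=True,
        ),
        "manifest": GroupEffect(
            f_mean=0.14, t2r_mean_s=9.5e-6, t2f_mean_s=66e-3, t1f_mean_s=1.30,
            sdf_mean=0.92, age_mean=54.2, age_sd=12.7, cag_mean=43.7, cag_sd=2.8,
            p_female=0.5, dbs_reference=444.4,
        ),
    }


class EffectConfig(BaseModel):
    """Full configuration of the synthetic-data generator."""

    model_config = ConfigDict(extra="forbid")

    groups: dict[str, GroupEffect] = Field(default_factory=default_group_effects)
    # disease-progress units per disease-burden unit: for a DBS-coupled group
    # the whole tissue-parameter mean vector interpolates monotonically
    # between the control-like and manifest-like endpoints as the subject's
    # DBS departs from the group reference
    dbs_coupling: float = 1.0 / 300.0
    snr: float = 100.0  # Rician SNR at M0; inf disables noise
    lr_correlation: float = 0.8  # left/right hemisphere parameter correlation
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EffectConfig":
        missing = set(GROUPS) - set(self.groups)
        if missing:
            raise EffectConfigError(f"missing group configuration: {sorted(missing)}")
        if not self.snr > 0:
            raise EffectConfigError("snr must be positive (use inf for noiseless)")
        if not -1.0 < self.lr_correlation < 1.0:
            raise EffectConfigError("lr_correlation must be in (-1, 1)")
        return self


def _subject_rng(effect: EffectConfig, subject_id: str, stream: int) -> np.random.Generator:
    # stable per-subject stream independent of call order
    return np.random.default_rng(
        np.random.SeedSequence([effect.seed, zlib.crc32(subject_id.encode()), stream])
    )


def generate_cohort(n_per_group: int, effect: EffectConfig) -> pd.DataFrame:
    """Draw a cohort table: id, group, sex, age, CAG repeats, disease burden.

    Controls carry no CAG expansion and hence no disease-burden score.
    Deterministic under a fixed ``effect.seed``.
    """
    if n_per_group < 1:
        raise EffectConfigError("n_per_group must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([effect.seed, 0xC0407, 0]))
    rows = []
    for group in GROUPS:
        ge = effect.groups[group]
        for i in range(n_per_group):
            age = float(rng.normal(ge.age_mean, ge.age_sd))
            while age < 18.0:
                age = float(rng.normal(ge.age_mean, ge.age_sd))
            age = round(age, 1)
            sex = "F" if rng.random() < ge.p_female else "M"
            if ge.cag_mean is None:
                cag, dbs = None, None
            else:
                cag = int(np.clip(round(rng.normal(ge.cag_mean, ge.cag_sd)), 36, 60))
                dbs = round(disease_burden_score(age, cag), 1)
            rows.append(
                {
                    "subject_id": f"{group[:3]}{i + 1:02d}",
                    "group": group,
                    "sex": sex,
                    "age_years": age,
                    "cag_repeats": cag,
                    "dbs": dbs,
                }
            )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df["cag_repeats"] = df["cag_repeats"].astype("Int64")
    return df


_MEAN_ATTRS = {
    "f": "f_mean", "kr": "kr_mean", "t2r": "t2r_mean_s",
    "t2f": "t2f_mean_s", "t1f": "t1f_mean_s", "sdf": "sdf_mean",
}


def _group_param_means(subject: Mapping, effect: EffectConfig) -> dict[str, float]:
    """Tissue-parameter means for one subject.

    Uncoupled groups sit at their configured means.  For a DBS-coupled
    (transition) group each parameter's mean slides monotonically along the
    control -> manifest axis with the subject's disease burden: the group
    mean is reproduced at the reference DBS, and the shift saturates at the
    control-like and manifest-like endpoints.
    """
    ge = effect.groups[str(subject["group"])]
    means = {name: getattr(ge, attr) for name, attr in _MEAN_ATTRS.items()}
    dbs = subject.get("dbs")
    if ge.dbs_coupled and dbs is not None and not pd.isna(dbs):
        lo_g, hi_g = effect.groups["control"], effect.groups["manifest"]
        ds = effect.dbs_coupling * (float(dbs) - ge.dbs_reference)
        for name, attr in _MEAN_ATTRS.items():
            lo, hi = getattr(lo_g, attr), getattr(hi_g, attr)
            if hi == lo:
                continue
            s_ref = (means[name] - lo) / (hi - lo)
            s = float(np.clip(s_ref + ds, 0.0, 1.0))
            means[name] = lo + s * (hi - lo)
    return means


def sample_tissue_parameters(
    subject: Mapping, effect: EffectConfig, max_resample: int = 100
) -> tuple[TissueParameters, TissueParameters]:
    """Draw (left, right) caudate ground truth for one subject.

    The subject's disease burden shifts the pool ratio around the group mean
    (monotone coupling); left and right hemispheres share a configurable
    correlation.  Draws falling outside physiological bounds are resampled a
    bounded number of times; detailed balance is implicit (``kf = f * kr``).
    """
    group = str(subject["group"])
    if group not in effect.groups:
        raise EffectConfigError(f"unknown group {group!r}")
    rng = _subject_rng(effect, str(subject["subject_id"]), stream=1)
    means = _group_param_means(subject, effect)
    ge = effect.groups[group]
    sds = {
        "f": ge.f_sd, "kr": ge.kr_sd, "t2r": ge.t2r_sd_s,
        "t2f": ge.t2f_sd_s, "t1f": ge.t1f_sd_s, "sdf": ge.sdf_sd,
    }
    rho = effect.lr_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    sampled: dict[str, tuple[float, float]] = {}
    for name in ("f", "kr", "t2r", "t2f", "t1f", "sdf"):
        lo, hi = PARAM_BOUNDS[name]
        mu, sd = means[name], sds[name]
        for _ in range(max_resample):
            pair = mu + sd * (chol @ rng.standard_normal(2))
            if lo <= pair[0] <= hi and lo <= pair[1] <= hi:
                sampled[name] = (float(pair[0]), float(pair[1]))
                break
        else:
            raise EffectConfigError(
                f"could not sample {name} within physiological bounds for "
                f"{subject['subject_id']} (mean {mu:g})"
            )

    def build(side: int) -> TissueParameters:
        return TissueParameters(
            f=sampled["f"][side], kr=sampled["kr"][side], t2r=sampled["t2r"][side],
            t2f=sampled["t2f"][side], t1f=sampled["t1f"][side], sdf=sampled["sdf"][side],
        )

    return build(0), build(1)


BACKGROUND_TISSUE = TissueParameters(f=0.08, kr=15.0, t2r=12e-6, t2f=70e-3, t1f=1.4, sdf=0.9)

DEFAULT_GRID_SHAPE = (32, 32, 16)
# ellipsoid semi-axes (voxels) give caudate-like ROIs of ~150 voxels each
_NC_SEMI_AXES = (2.8, 4.8, 2.8)


def ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    dist2 = sum(((idx[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3))
    return dist2 <= 1.0


def add_rician_noise(
    volume: np.ndarray,
    snr: float,
    rng: np.random.Generator,
    reference: float,
) -> np.ndarray:
    """Rician magnitude noise: |x + n1 + i n2| with per-channel SD = reference/snr.

    ``snr = inf`` returns the input unchanged; outputs are nonnegative.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    volume = np.asarray(volume, dtype=float)
    if np.isinf(snr):
        return volume.copy()
    sigma = reference / snr
    n1 = rng.normal(0.0, sigma, volume.shape)
    n2 = rng.normal(0.0, sigma, volume.shape)
    return np.sqrt((volume + n1) ** 2 + n2**2)


def simulate_subject_stack(
    params_left: TissueParameters,
    params_right: TissueParameters,
    acq: MTAcquisition,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    snr: float = 100.0,
    seed: int = 0,
    background: TissueParameters = BACKGROUND_TISSUE,
) -> MTImageStack:
    """Build one subject's noisy MT phantom.

    Two ellipsoidal caudate masks receive their hemisphere's noiseless
    forward signal scaled by the spin density; the remaining voxels carry a
    fixed background tissue.  Rician noise (SNR referenced to the mean
    in-mask M0) is then applied to M0 and every offset volume.  The T1 and
    T2f maps are emitted noiseless, standing in for separately acquired
    relaxometry.
    """
    nx, ny, nz = grid_shape
    center_l = (0.32 * nx, 0.5 * ny, 0.5 * nz)
    center_r = (0.68 * nx, 0.5 * ny, 0.5 * nz)
    mask_l = ellipsoid_mask(grid_shape, center_l, _NC_SEMI_AXES)
    mask_r = ellipsoid_mask(grid_shape, center_r, _NC_SEMI_AXES)
    if np.any(mask_l & mask_r):
        raise StackConstructionError("caudate masks overlap; enlarge the grid")
    if not mask_l.any() or not mask_r.any():
        raise StackConstructionError("grid too small to contain the caudate masks")

    regions = [(mask_l, params_left), (mask_r, params_right),
               (~(mask_l | mask_r), background)]
    m0 = np.zeros(grid_shape)
    offs = [np.zeros(grid_shape) for _ in acq.offsets_hz]
    t1 = np.zeros(grid_shape)
    t2f = np.zeros(grid_shape)
    for mask, p in regions:
        sig = steady_state_signal(p, acq)
        m0[mask] = sig.m0
        for vol, val in zip(offs, sig.values):
            vol[mask] = val
        t1[mask] = p.t1f
        t2f[mask] = p.t2f

    nc = mask_l | mask_r
    reference = float(m0[nc].mean())
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57AC4]))
    m0 = add_rician_noise(m0, snr, rng, reference)
    offs = [add_rician_noise(v, snr, rng, reference) for v in offs]

    return MTImageStack(
        m0_volume=m0,
        offset_volumes=offs,
        affine=np.diag([2.0, 2.0, 4.0, 1.0]),
        masks={"nc_left": mask_l, "nc_right": mask_r},
        t1_map=t1,
        t2f_map=t2f,
    )
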