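"""Synthetic CT tumor-phantom cohort generation.

Builds a cohort of 3-D CT-like volumes (Hounsfield units) with binary tumor
masks, a binary short-term response label, and exponential survival times
whose hazard depends on the label.  The cohort emulates the statistical
structure a radiomics response-prediction study assumes: two outcome classes
that differ in tumor mean attenuation and in the correlation length of the
intra-tumoral texture, tumor diameters spanning roughly 10-155 mm, and
additive Gaussian quantum noise.

Tumors are ellipsoids with a low-order spherical-harmonic boundary jitter so
shape features vary across subjects; intra-tumoral and parenchymal texture
are Gaussian random fields realised by Gaussian-smoothing white noise.
Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import sph_harm_y

from ._utils import logger, subseed

HU_CLIP = (-1024.0, 1400.0)
DIAMETER_RANGE_DEFAULT = (10.40, 153.33)


class SizingError(ValueError):
    """Tumor does not fit inside the requested image grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic tumor phantom.

    Attributes
    ----------
    image_shape : (z, y, x) voxel counts.
    voxel_size_mm : spacing per axis, mm (base 1 mm axial).
    tumor_diameter_mm : maximum tumor diameter, mm.
    hu_background : mean liver-like background attenuation, HU.
    hu_tumor_shift : class-dependent mean HU offset of the tumor interior.
    texture_corr_len : correlation length (voxels) of the Gaussian random
        field inside the tumor.
    texture_amp_hu : standard deviation (HU) of that field.
    noise_sd : SD of additive white Gaussian (quantum) noise, HU.
    axis_ratios : relative ellipsoid semi-axes, each in (0, 1]; the largest
        axis carries ``tumor_diameter_mm``.
    jitter_amp : relative amplitude of the spherical-harmonic boundary
        jitter (0.10 = 10% of the radius).
    seed : RNG seed for this phantom.
    """

    image_shape: tuple[int, int, int] = (64, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_diameter_mm: float = 59.68
    hu_background: float = 60.0
    hu_tumor_shift: float = 45.0
    texture_corr_len: float = 1.5
    texture_amp_hu: float = 15.0
    noise_sd: float = 10.0
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    jitter_amp: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.tumor_diameter_mm <= 0:
            raise ValueError("tumor_diameter_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.axis_ratios) <= 0 or max(self.axis_ratios) > 1:
            raise ValueError("axis_ratios must lie in (0, 1]")
        # full jittered extent must fit with a 2-voxel margin on every axis
        for ax in range(3):
            extent = (self.tumor_diameter_mm * self.axis_ratios[ax]
                      * (1.0 + self.jitter_amp))
            span = self.image_shape[ax] * self.voxel_size_mm[ax]
            if extent + 4.0 * self.voxel_size_mm[ax] > span:
                raise SizingError(
                    f"tumor extent {extent:.1f} mm exceeds image span "
                    f"{span:.1f} mm on axis {ax}")


@dataclass
class Subject:
    subject_id: str
    volume: np.ndarray          # (z, y, x), HU
    mask: np.ndarray            # bool, same grid
    label: int                  # 1 = disease control, 0 = progression
    os_time: float = np.nan     # months
    os_event: int = 0
    spec: PhantomSpec | None = None


@dataclass
class PhantomCohort:
    subjects: list[Subject]
    config: dict
    seed: int

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.subjects], dtype=int)

    def clinical_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.subjects],
            "label": self.labels,
            "os_time": [s.os_time for s in self.subjects],
            "os_event": [s.os_event for s in self.subjects],
        })

    def save(self, out_dir: str | Path) -> None:
        """Write volumes/masks as NIfTI, the clinical table as CSV and the
        generation config as YAML."""
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in self.subjects:
            affine = np.diag(list(s.spec.voxel_size_mm) + [1.0])
            nib.save(nib.Nifti1Image(s.volume.astype(np.float32), affine),
                     out / f"{s.subject_id}_image.nii.gz")
            nib.save(nib.Nifti1Image(s.mask.astype(np.uint8), affine),
                     out / f"{s.subject_id}_mask.nii.gz")
        self.clinical_frame().to_csv(out / "clinical.csv", index=False)
        with open(out / "generation_config.yaml", "w") as fh:
            yaml.safe_dump({"seed": self.seed, **self.config}, fh)


def _real_sph_harm(l: int, m: int, theta: np.ndarray,
                   phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (polar theta, azimuth phi)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real


def _boundary_jitter(theta: np.ndarray, phi: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth random function of direction from harmonics l = 1..3,
    normalised to max |.| = 1."""
    j = np.zeros_like(theta)
    for l in range(1, 4):
        for m in range(-l, l + 1):
            j = j + rng.normal() * _real_sph_harm(l, m, theta, phi)
    peak = np.max(np.abs(j))
    return j / peak if peak > 0 else j


def _gaussian_field(shape: tuple[int, ...], corr_len: float, amp: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with the given pointwise SD, built by
    Gaussian-smoothing white noise (smoothing scale = correlation length)."""
    white = rng.standard_normal(shape)
    if corr_len <= 0 or amp == 0:
        return amp * white
    f = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return amp * f / sd


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (volume, mask) pair.

    The tumor is an ellipsoid (semi-axes ``diameter/2 * axis_ratios``) whose
    radius is modulated by a low-order spherical-harmonic jitter; its
    interior is ``hu_background + hu_tumor_shift`` plus a correlated Gaussian
    texture field, the background is liver-like parenchyma with its own
    short-range texture, and white Gaussian noise is added everywhere.
    HU values are clipped to [-1024, 1400].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    shape = tuple(int(v) for v in spec.image_shape)
    center = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    coords = np.stack([zz, yy, xx], axis=0).astype(float)
    for ax in range(3):
        coords[ax] = (coords[ax] - center[ax]) * spec.voxel_size_mm[ax]

    semi = np.array(spec.axis_ratios) * spec.tumor_diameter_mm / 2.0
    norm = np.sqrt(((coords / semi[:, None, None, None]) ** 2).sum(axis=0))

    r = np.sqrt((coords ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.divide(coords[0], r,
                                            out=np.zeros_like(r),
                                            where=r > 0), -1, 1))
    theta[r == 0] = 0.0
    phi = np.arctan2(coords[1], coords[2])
    jitter = _boundary_jitter(theta, phi, rng)
    mask = norm <= 1.0 + spec.jitter_amp * jitter

    bg_field = _gaussian_field(shape, 1.5, spec.texture_amp_hu * 0.5, rng)
    tumor_field = _gaussian_field(shape, spec.texture_corr_len,
                                  spec.texture_amp_hu, rng)
    volume = spec.hu_background + bg_field
    volume[mask] = spec.hu_background + spec.hu_tumor_shift + tumor_field[mask]
    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, shape)
    volume = np.clip(volume, *HU_CLIP)
    return volume.astype(np.float64), mask


@dataclass(frozen=True)
class CohortConfig:
    """Distributions from which per-subject phantom specs are drawn.

    Defaults emulate the target study population: ~103 subjects with a
    ~70/30 disease-control/progression split, maximum tumor diameters with
    median ~60 mm in [10.40, 153.33] mm, arterial-phase liver attenuation
    around 60 HU and ~10 HU quantum noise.  The two classes differ in tumor
    mean HU shift and texture correlation length; ``effect`` (argument of
    :func:`generate_cohort`) scales that separation, with effect = 0 giving
    label-independent images.
    """

    diameter_median_mm: float = 59.68
    diameter_log_sd: float = 0.55
    diameter_range_mm: tuple[float, float] = DIAMETER_RANGE_DEFAULT
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 8.0
    hu_background: float = 60.0
    hu_shift_control: float = 45.0       # label 1 tumors, arterial enhancement
    hu_shift_effect_mm: float = 12.0     # label 0 = control - effect * this
    corr_len_control: float = 1.5
    corr_len_effect: float = 1.0         # label 0 = control + effect * this
    texture_amp_hu: float = 15.0
    noise_sd: float = 10.0
    subject_jitter_hu: float = 3.0
    subject_jitter_corr: float = 0.15
    # survival defaults
    hazard_ratio: float = 2.49
    median_ctrl_months: float = 18.0
    censor_rate: float = 0.30


def generate_survival(labels: Sequence[int], hr: float = 2.49,
                      median_ctrl: float = 18.0, censor_rate: float = 0.30,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival times with hazard multiplied by ``hr`` for
    label-0 (progression) subjects, under administrative censoring chosen to
    yield approximately the requested censor rate.

    Returns (os_time months, os_event) arrays.
    """
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    lam_ctrl = np.log(2.0) / median_ctrl
    lam = np.where(labels == 1, lam_ctrl, lam_ctrl * hr)
    t_event = rng.exponential(1.0 / lam)

    if censor_rate == 0:
        return t_event, np.ones(len(labels), dtype=int)

    # administrative window C with mean_i exp(-lam_i * C) = censor_rate
    def frac_censored(c: float) -> float:
        return float(np.mean(np.exp(-lam * c)))

    lo, hi = 1e-6, 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    window = 0.5 * (lo + hi) * rng.uniform(0.85, 1.15, size=len(labels))
    event = (t_event <= window).astype(int)
    os_time = np.minimum(t_event, window)
    return np.maximum(os_time, 1e-3), event


def generate_cohort(n: int = 103, control_fraction: float = 72 / 103,
                    effect: float = 1.0, seed: int = 0,
                    config: CohortConfig | None = None,
                    image_shape: tuple[int, int, int] | None = None,
                    ) -> PhantomCohort:
    """Generate a full phantom cohort.

    Exactly ``round(n * control_fraction)`` subjects carry label 1 (disease
    control).  Class 1 and class 0 differ in tumor HU shift and texture
    correlation length by ``effect`` times the config's effect scales.
    Per-subject specs are drawn from the config distributions; the global
    seed is split into per-subject streams by counter offset so regeneration
    is bit-identical.

    ``image_shape`` overrides the per-subject adaptive grid (tumor extent
    plus margin) with a fixed grid; the tumor must still fit.
    """
    if n < 4:
        raise ValueError("n must be >= 4 (cannot stratify folds)")
    if not 0 < control_fraction < 1:
        raise ValueError("control_fraction must be in (0, 1)")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(subseed(seed, "cohort"))

    n1 = int(round(n * control_fraction))
    labels = np.array([1] * n1 + [0] * (n - n1))
    rng.shuffle(labels)

    subjects: list[Subject] = []
    for i, lab in enumerate(labels):
        mu = np.log(cfg.diameter_median_mm)
        d = float(np.exp(rng.normal(mu, cfg.diameter_log_sd)))
        d = float(np.clip(d, *cfg.diameter_range_mm))
        ratios = tuple(sorted(rng.uniform(0.80, 1.0, size=3))[::-1])
        ratios = (1.0, ratios[1], ratios[2])  # largest axis carries d
        shift = (cfg.hu_shift_control
                 - (0 if lab == 1 else effect * cfg.hu_shift_effect_mm)
                 + rng.normal(0.0, cfg.subject_jitter_hu))
        corr = (cfg.corr_len_control
                + (0 if lab == 1 else effect * cfg.corr_len_effect)
                + rng.normal(0.0, cfg.subject_jitter_corr))
        corr = max(corr, 0.5)
        if image_shape is None:
            extent = d * 1.1 + 2 * cfg.margin_mm
            side = int(np.ceil(extent))
            shape = (side, side, side)
        else:
            shape = tuple(image_shape)
        spec = PhantomSpec(
            image_shape=shape, voxel_size_mm=cfg.voxel_size_mm,
            tumor_diameter_mm=d, hu_background=cfg.hu_background,
            hu_tumor_shift=shift, texture_corr_len=corr,
            texture_amp_hu=cfg.texture_amp_hu, noise_sd=cfg.noise_sd,
            axis_ratios=ratios, seed=subseed(seed, f"subject:{i}"))
        volume, mask = generate_phantom(spec)
        subjects.append(Subject(subject_id=f"S{i:03d}", volume=volume,
                                mask=mask, label=int(lab), spec=spec))

    os_time, os_event = generate_survival(
        labels, hr=cfg.hazard_ratio, median_ctrl=cfg.median_ctrl_months,
        censor_rate=cfg.censor_rate, seed=subseed(seed, "survival"))
    for s, t, e in zip(subjects, os_time, os_event):
        s.os_time, s.os_event = float(t), int(e)

    logger.info("generated cohort n=%d (%d control / %d progression)",
                n, n1, n - n1)
    return PhantomCohort(subjects=subjects,
                         config=dataclasses.asdict(cfg) | {"n": n,
                         "control_fraction": control_fraction,
                         "effect": effect},
                         seed=seed)
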