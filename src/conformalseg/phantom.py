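"""Synthetic prostate-phantom cohorts.

Each phantom exam is a deformed-ellipsoid organ on an anisotropic grid,
together with an emulated probabilistic segmenter and an ellipsoid-formula
reference reading:

* **shape** — an ellipsoid with semi-axes drawn per exam, perturbed by a
  low-order (l <= 4) real-spherical-harmonic radial field so the boundary
  deviates from the pure ellipsoid the reference formula assumes;
* **probability map** — a logistic function of the Euclidean signed distance
  to the (optionally bias-shifted) organ surface, plus spatially correlated
  Gaussian noise, clipped to [0, 1].  A positive bias shifts the apparent
  surface outward and makes the emulated segmenter over-segment, the
  behaviour reported for deep-learning prostate models;
* **reference volume** — the PI-RADS ellipsoid formula (pi/6 * W * H * D)
  applied to the phantom's axis extents, each perturbed by multiplicative
  reader noise (manual caliper readings err proportionally).

Calibration and evaluation exams drawn from one :class:`PhantomSpec` are
i.i.d., hence exchangeable — the assumption under which conformal prediction
guarantees coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit, sph_harm_y

from .grids import LabelMask, ProbabilityMap
from .volumetry import ellipsoid_volume

__all__ = ["PhantomSpec", "PhantomExam", "GenerationError", "generate_phantom", "generate_cohort"]


class GenerationError(ValueError):
    """The requested phantom does not fit on the requested grid."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic cohort distribution.

    Defaults give a ~48 mm field of view at clinical prostate-MRI spacing
    with organ volumes of roughly 6-30 mL (a scaled-down prostate), a
    moderately noisy boundary-uncertain segmenter, and a +1 mm surface bias
    (over-segmentation).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    #: per-axis semi-axis ranges in mm (half of width / height / depth)
    semi_axis_x: tuple[float, float] = (12.0, 20.0)
    semi_axis_y: tuple[float, float] = (12.0, 20.0)
    semi_axis_z: tuple[float, float] = (10.0, 16.0)
    #: boundary deformation amplitude, fraction of local radius, in [0, 0.5)
    deformation: float = 0.08
    #: logistic sharpness of the emulated segmenter, 1/mm
    sharpness: float = 2.0
    #: signed boundary offset of the segmenter in mm; > 0 = over-segmentation
    bias_mm: float = 1.0
    #: standard deviation of the additive correlated probability noise
    noise_amplitude: float = 0.15
    #: correlation length of the probability noise in mm
    noise_correlation_mm: float = 4.0
    #: multiplicative reader noise SD on each measured axis (fraction)
    reader_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.deformation < 0.5):
            raise ValueError(f"deformation must lie in [0, 0.5), got {self.deformation}")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be positive")
        for name, (lo, hi) in (
            ("x", self.semi_axis_x),
            ("y", self.semi_axis_y),
            ("z", self.semi_axis_z),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid semi-axis range on axis {name}: ({lo}, {hi})")
        half_extent = [0.5 * n * s for n, s in zip(self.grid_shape, self.spacing)]
        for name, (lo, hi), half in zip(
            "xyz", (self.semi_axis_x, self.semi_axis_y, self.semi_axis_z), half_extent
        ):
            reach = hi * (1.0 + self.deformation) + max(self.bias_mm, 0.0)
            if reach > half:
                raise GenerationError(
                    f"axis {name}: maximal radius {reach:.1f} mm exceeds the grid "
                    f"half-extent {half:.1f} mm"
                )


@dataclass
class PhantomExam:
    """One synthetic exam: ground-truth mask, segmenter output, reference reading."""

    exam_id: str
    mask: LabelMask
    prob: ProbabilityMap
    axes_mm: tuple[float, float, float]  # measured W, H, D incl. reader noise
    pv_ref_ml: float
    seed: int

    def __post_init__(self) -> None:
        if self.mask.voxels.sum() == 0:
            raise GenerationError(f"{self.exam_id}: empty phantom mask")
        if self.pv_ref_ml <= 0:
            raise ValueError(f"{self.exam_id}: PV_ref must be positive")
        self.mask.require_same_grid(self.prob)


# real spherical harmonics used for the boundary deformation
_DEFORM_TERMS = [(l, m) for l in (2, 3, 4) for m in range(-l, l + 1)]


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic Y_lm(theta=polar, phi=azimuth)."""
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    if m < 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.imag
    return y.real


def _fibonacci_sphere(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) of n near-uniform directions on the unit sphere."""
    i = np.arange(n, dtype=np.float64)
    phi = (2.0 * np.pi * i / ((1.0 + np.sqrt(5.0)) / 2.0)) % (2.0 * np.pi)
    theta = np.arccos(1.0 - 2.0 * (i + 0.5) / n)
    return theta, phi


def _radius(a, b, c, theta, phi, coeffs, scale):
    """Surface radius R(theta, phi) of the deformed ellipsoid."""
    st, ct = np.sin(theta), np.cos(theta)
    ux, uy, uz = st * np.cos(phi), st * np.sin(phi), ct
    r0 = 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)
    if scale == 0.0:
        return r0
    f = np.zeros_like(theta)
    for (l, m), cc in zip(_DEFORM_TERMS, coeffs):
        f += cc * _real_sph_harm(l, m, theta, phi)
    return r0 * (1.0 + scale * f)


def generate_phantom(spec: PhantomSpec, exam_seed: int, exam_id: str = "exam") -> PhantomExam:
    """Generate one phantom exam, deterministically from ``(spec, exam_seed)``.

    Random draws, in fixed order: semi-axes, deformation coefficients,
    probability-noise field, reader-noise factors.
    """
    rng = np.random.default_rng(exam_seed)
    a = rng.uniform(*spec.semi_axis_x)
    b = rng.uniform(*spec.semi_axis_y)
    c = rng.uniform(*spec.semi_axis_z)

    if spec.deformation > 0:
        coeffs = rng.standard_normal(len(_DEFORM_TERMS))
        theta_s, phi_s = _fibonacci_sphere(4096)
        f = np.zeros_like(theta_s)
        for (l, m), cc in zip(_DEFORM_TERMS, coeffs):
            f += cc * _real_sph_harm(l, m, theta_s, phi_s)
        # scale so the radial perturbation peaks at the requested amplitude
        scale = spec.deformation / np.abs(f).max()
    else:
        coeffs = np.zeros(len(_DEFORM_TERMS))
        scale = 0.0

    shape, spacing = spec.grid_shape, spec.spacing
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    ix, iy, iz = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    x = ix * spacing[0] - center[0]
    y = iy * spacing[1] - center[1]
    z = iz * spacing[2] - center[2]
    rho = np.sqrt(x * x + y * y + z * z)
    cos_t = np.divide(z, rho, out=np.ones_like(rho), where=rho > 0)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    phi = np.arctan2(y, x)

    surf = _radius(a, b, c, theta, phi, coeffs, scale)
    mask_arr = (rho <= surf).astype(np.uint8)
    mask = LabelMask(mask_arr, spacing)

    # emulated segmenter: logistic of signed distance to the bias-shifted surface
    biased = rho <= surf + spec.bias_mm
    sd = ndimage.distance_transform_edt(biased, sampling=spacing) - ndimage.distance_transform_edt(
        ~biased, sampling=spacing
    )
    p = expit(spec.sharpness * sd)
    if spec.noise_amplitude > 0:
        white = rng.standard_normal(shape)
        sigma = [spec.noise_correlation_mm / s for s in spacing]
        noise = ndimage.gaussian_filter(white, sigma)
        nsd = noise.std()
        if nsd > 0:
            p = p + noise * (spec.noise_amplitude / nsd)
        np.clip(p, 0.0, 1.0, out=p)
    prob = ProbabilityMap(p, spacing)

    # caliper-style axis extents of the continuous (unbiased) surface
    if scale == 0.0:
        extents = np.array([2 * a, 2 * b, 2 * c])
    else:
        theta_f, phi_f = _fibonacci_sphere(8192)
        r_f = _radius(a, b, c, theta_f, phi_f, coeffs, scale)
        st = np.sin(theta_f)
        pts = np.stack(
            [r_f * st * np.cos(phi_f), r_f * st * np.sin(phi_f), r_f * np.cos(theta_f)], axis=1
        )
        extents = pts.max(axis=0) - pts.min(axis=0)

    factors = np.ones(3)
    if spec.reader_noise_sd > 0:
        factors = np.clip(1.0 + rng.normal(0.0, spec.reader_noise_sd, 3), 0.1, None)
    w, h, d = extents * factors
    pv_ref = ellipsoid_volume(w, h, d)

    return PhantomExam(exam_id, mask, prob, (float(w), float(h), float(d)), pv_ref, int(exam_seed))


def generate_cohort(
    spec: PhantomSpec, n_exams: int, master_seed: int
) -> list[PhantomExam]:
    """Generate ``n_exams`` i.i.d. phantom exams; per-exam seeds are spawned
    deterministically from ``master_seed``."""
    if n_exams < 1:
        raise ValueError("n_exams must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n_exams)
    exams = []
    for k, child in enumerate(children):
        seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        exams.append(generate_phantom(spec, seed, exam_id=f"exam_{k:04d}"))
    return exams
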