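"""Multi-center synthetic PET phantom bench.

Generates paired NAC/ASC 2D studies: elliptical "patients" with organs and
focal lesions, a 511-keV attenuation map, and per-center scanner
idiosyncrasies (PSF blur, pseudo-Poisson noise, scatter fraction, matrix
size, slice thickness).  The physics is a desk-scale surrogate, not a
sinogram simulation: attenuation is applied as a per-pixel angular mean of
chord survival factors exp(-integral mu dl), and scatter as a broad Gaussian
convolution of the attenuated (primary) signal rescaled to an exact scatter
fraction.  This captures the two facts the correction task depends on —
attenuation removes counts in a geometry-dependent way, scatter adds a
low-frequency haze — while keeping full datasets generatable in seconds.

Activity is simulated in SUV-like units and stored in the study as
activity-concentration units (kBq/mL) consistent with the SUV conversion in
:mod:`fedpet.preprocessing`, so the preprocessing chain is exercised for real.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import GridSpec, resample

logger = logging.getLogger(__name__)

__all__ = [
    "Ellipse",
    "Organ",
    "Lesion",
    "PhantomSpec",
    "CenterProfile",
    "PairedStudy",
    "FactorMap",
    "CenterDataset",
    "build_phantom",
    "attenuation_factors",
    "simulate_pair",
    "random_phantom_spec",
    "generate_center_dataset",
    "MU_SOFT_TISSUE_MM",
    "MU_LUNG_MM",
]

# linear attenuation coefficients at 511 keV, 1/mm
MU_SOFT_TISSUE_MM = 0.0096
MU_LUNG_MM = 0.0028
MU_BONE_MM = 0.017
_MU_MAX = 0.02


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse; center in mm relative to the grid center."""

    center_mm: tuple
    semi_axes_mm: tuple

    def mask(self, yy_mm: np.ndarray, xx_mm: np.ndarray) -> np.ndarray:
        cy, cx = self.center_mm
        ay, ax = self.semi_axes_mm
        return ((yy_mm - cy) / ay) ** 2 + ((xx_mm - cx) / ax) ** 2 <= 1.0


@dataclass(frozen=True)
class Organ:
    shape: Ellipse
    activity: float  # SUV-like units
    mu_511: float  # 1/mm


@dataclass(frozen=True)
class Lesion:
    center_mm: tuple
    radius_mm: float
    activity: float


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomy of one synthetic patient slice.

    Later structures override earlier ones where they overlap (draw order).
    ``texture_amplitude`` adds seeded smooth multiplicative texture to the
    body activity; 0 keeps the phantom piecewise constant.
    """

    grid_size: int
    pixel_size_mm: float
    body: Ellipse
    body_activity: float = 1.0
    background_mu: float = MU_SOFT_TISSUE_MM
    organs: tuple = ()
    lesions: tuple = ()
    texture_amplitude: float = 0.0

    def validate(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.body_activity < 0 or not 0 <= self.background_mu <= _MU_MAX:
            raise ValueError("body activity must be >= 0 and mu in [0, 0.02] 1/mm")
        for o in self.organs:
            if o.activity < 0 or not 0 <= o.mu_511 <= _MU_MAX:
                raise ValueError("organ activity must be >= 0 and mu in [0, 0.02] 1/mm")
        for l in self.lesions:
            if l.activity < 0 or l.radius_mm <= 0:
                raise ValueError("lesion activity must be >= 0, radius positive")


@dataclass(frozen=True)
class CenterProfile:
    """Scanner idiosyncrasies of one simulated center (non-IID by design)."""

    center_id: str
    psf_fwhm_mm: float = 5.0
    noise_scale: float = 0.02
    scatter_fraction: float = 0.45  # whole-body scans reach 50-60%
    matrix_size: int = 64
    slice_thickness_mm: float = 3.5
    n_studies: int = 50

    def validate(self):
        if self.psf_fwhm_mm < 0 or self.noise_scale < 0:
            raise ValueError("psf_fwhm_mm and noise_scale must be >= 0")
        if not 0 <= self.scatter_fraction < 0.8:
            raise ValueError("scatter_fraction must lie in [0, 0.8)")
        if self.matrix_size < 8 or self.slice_thickness_mm <= 0 or self.n_studies < 1:
            raise ValueError("invalid matrix size / slice thickness / study count")


@dataclass(frozen=True)
class FactorMap:
    """Per-pixel attenuation survival factors, values in (0, 1]."""

    values: np.ndarray
    angles_used: int


@dataclass
class PairedStudy:
    """One patient analogue: NAC input, ASC reference, SUV metadata."""

    study_id: str
    nac_image: np.ndarray  # activity-concentration units (kBq/mL-like)
    asc_image: np.ndarray
    injected_activity_MBq: float
    body_weight_kg: float
    grid: GridSpec
    slice_thickness_mm: float
    center_id: str
    seed: int


@dataclass
class CenterDataset:
    """A silo: one center's profile plus its ordered studies."""

    profile: CenterProfile
    studies: list

    def __len__(self):
        return len(self.studies)


def _coords_mm(grid_size: int, pixel_size_mm: float):
    c = (np.arange(grid_size) + 0.5 - grid_size / 2) * pixel_size_mm
    return np.meshgrid(c, c, indexing="ij")


def build_phantom(spec: PhantomSpec, seed: int = 0):
    """Rasterize a PhantomSpec into (activity_map, attenuation_map).

    Deterministic given (spec, seed); the seed only feeds the optional
    activity texture.  Outside the body both maps are zero.
    """
    spec.validate()
    yy, xx = _coords_mm(spec.grid_size, spec.pixel_size_mm)
    body = spec.body.mask(yy, xx)
    activity = np.where(body, spec.body_activity, 0.0)
    mu = np.where(body, spec.background_mu, 0.0)
    for organ in spec.organs:
        m = organ.shape.mask(yy, xx) & body
        activity[m] = organ.activity
        mu[m] = organ.mu_511
    if spec.texture_amplitude > 0:
        rng = np.random.default_rng(seed)
        tex = ndimage.gaussian_filter(rng.standard_normal(activity.shape), 3.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        activity *= 1.0 + spec.texture_amplitude * tex
        activity = np.clip(activity, 0.0, None)
    for les in spec.lesions:
        cy, cx = les.center_mm
        m = ((yy - cy) ** 2 + (xx - cx) ** 2 <= les.radius_mm**2) & body
        activity[m] = les.activity
    return activity, mu


def attenuation_factors(
    attenuation_map: np.ndarray, pixel_size_mm: float, n_angles: int = 32
) -> FactorMap:
    """Angular-mean survival factor for every pixel.

    For each of ``n_angles`` directions (uniform over half a turn; opposite
    directions share a chord) the line integral of mu along the full chord
    through a pixel is computed by equal-step ray marching with step
    pixel/2 and bilinear sampling.  The integral is constant along a chord,
    so marching is organized per projection line and pixels read their
    chord's value by linear interpolation in the perpendicular coordinate.
    """
    if n_angles < 4:
        raise ValueError("n_angles must be >= 4")
    mu = np.asarray(attenuation_map, dtype=float)
    if mu.ndim != 2 or (mu < 0).any():
        raise ValueError("attenuation_map must be a 2D non-negative array")
    n = mu.shape[0]
    if mu.shape[1] != n:
        raise ValueError("attenuation_map must be square")
    step = pixel_size_mm / 2.0
    half = n * pixel_size_mm / np.sqrt(2.0) + pixel_size_mm  # half-diagonal + margin
    s_lines = np.arange(-half, half + step, step)
    t_march = np.arange(-half, half + step, step)
    yy, xx = _coords_mm(n, pixel_size_mm)
    total = np.zeros_like(mu)
    for a in range(n_angles):
        phi = np.pi * a / n_angles
        d = np.array([np.cos(phi), np.sin(phi)])  # chord direction (y, x)
        p = np.array([-np.sin(phi), np.cos(phi)])  # perpendicular
        # sample points for every (line, step): world mm -> fractional index
        py = s_lines[:, None] * p[0] + t_march[None, :] * d[0]
        px = s_lines[:, None] * p[1] + t_march[None, :] * d[1]
        iy = py / pixel_size_mm + n / 2 - 0.5
        ix = px / pixel_size_mm + n / 2 - 0.5
        samples = ndimage.map_coordinates(
            mu, np.stack([iy.ravel(), ix.ravel()]), order=1, mode="constant", cval=0.0
        ).reshape(py.shape)
        line_integrals = samples.sum(axis=1) * step
        s_pix = yy * p[0] + xx * p[1]
        integ = np.interp(s_pix.ravel(), s_lines, line_integrals).reshape(mu.shape)
        total += integ
    values = np.exp(-total / n_angles)
    return FactorMap(values=values, angles_used=n_angles)


def _fwhm_to_sigma_px(fwhm_mm: float, pixel_size_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pixel_size_mm


def simulate_pair(
    activity_map: np.ndarray,
    attenuation_map: np.ndarray,
    profile: CenterProfile,
    suv_meta: dict,
    seed,
    pixel_size_mm: float,
    n_angles: int = 32,
    study_id: str = "study",
) -> PairedStudy:
    """Corrupt a phantom into a paired (NAC, ASC) study for one center.

    ASC = PSF-blurred activity + noise (the reference the network learns).
    NAC = attenuated primary + scatter + noise, where the primary is the
    blurred activity times the survival factors and scatter is a broad
    Gaussian blur of the primary rescaled so that
    sum(scatter) / (sum(scatter) + sum(primary)) equals the profile's
    scatter fraction exactly.  Both images are resampled to the center's
    matrix size (fixed field of view) and returned in concentration units.
    """
    profile.validate()
    activity = np.asarray(activity_map, dtype=float)
    mu = np.asarray(attenuation_map, dtype=float)
    if activity.shape != mu.shape:
        raise ValueError("activity and attenuation maps must share the grid")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    if profile.psf_fwhm_mm > 0:
        asc_clean = ndimage.gaussian_filter(
            activity, _fwhm_to_sigma_px(profile.psf_fwhm_mm, pixel_size_mm)
        )
    else:
        asc_clean = activity.copy()

    if mu.any():
        factors = attenuation_factors(mu, pixel_size_mm, n_angles).values
    else:
        factors = np.ones_like(mu)
    primary = asc_clean * factors

    sf = profile.scatter_fraction
    if sf > 0 and primary.sum() > 0:
        support = mu > 0 if mu.any() else activity > 0
        area_mm2 = support.sum() * pixel_size_mm**2
        body_diameter_mm = 2.0 * np.sqrt(max(area_mm2, 1.0) / np.pi)
        scatter = ndimage.gaussian_filter(
            primary, _fwhm_to_sigma_px(0.4 * body_diameter_mm, pixel_size_mm)
        )
        scatter *= sf / (1.0 - sf) * primary.sum() / scatter.sum()
    else:
        scatter = np.zeros_like(primary)
    nac_clean = primary + scatter

    def noisy(img):
        if profile.noise_scale == 0:
            return img
        out = img + rng.normal(size=img.shape) * profile.noise_scale * np.sqrt(
            np.clip(img, 0, None)
        )
        n_neg = int((out < 0).sum())
        if n_neg:
            logger.debug("clamped %d negative pixels to 0", n_neg)
        return np.clip(out, 0.0, None)

    asc = noisy(asc_clean)
    nac = noisy(nac_clean)

    injected = float(suv_meta["injected_activity_MBq"])
    weight = float(suv_meta["body_weight_kg"])
    if injected <= 0 or weight <= 0:
        raise ValueError("injected activity and body weight must be positive")
    # SUV-like -> concentration (kBq/mL) so that preprocessing.to_suv inverts it
    conc_factor = injected / weight
    asc *= conc_factor
    nac *= conc_factor

    n_src = activity.shape[0]
    src_grid = GridSpec(spacing_mm=(pixel_size_mm, pixel_size_mm), size=(n_src, n_src))
    m = profile.matrix_size
    if m != n_src:
        fov = n_src * pixel_size_mm
        tgt_grid = GridSpec(spacing_mm=(fov / m, fov / m), size=(m, m))
        asc = resample(asc, src_grid, tgt_grid)
        nac = resample(nac, src_grid, tgt_grid)
        grid = tgt_grid
    else:
        grid = src_grid

    return PairedStudy(
        study_id=study_id,
        nac_image=nac,
        asc_image=asc,
        injected_activity_MBq=injected,
        body_weight_kg=weight,
        grid=grid,
        slice_thickness_mm=profile.slice_thickness_mm,
        center_id=profile.center_id,
        seed=int(ss.entropy) if isinstance(ss.entropy, int) else 0,
    )


def random_phantom_spec(
    rng: np.random.Generator, grid_size: int = 64, pixel_size_mm: float = 3.0
) -> PhantomSpec:
    """Draw one randomized patient slice.

    Bodies are 100-160 mm across with unit-SUV background, one lung-like
    low-attenuation organ pair, one liver-like hot organ, and 0-3 focal hot
    lesions at 2-5x background uptake.
    """
    ay = rng.uniform(50, 80)
    ax = rng.uniform(40, 65)
    cy, cx = rng.uniform(-6, 6, size=2)
    body = Ellipse((cy, cx), (ay, ax))
    body_act = rng.uniform(0.8, 1.2)
    organs = []
    # lung-like pair: low uptake, low mu, in the upper half
    for side in (-1, 1):
        organs.append(
            Organ(
                Ellipse(
                    (cy - 0.45 * ay, cx + side * 0.40 * ax),
                    (0.30 * ay * rng.uniform(0.8, 1.1), 0.25 * ax * rng.uniform(0.8, 1.1)),
                ),
                activity=body_act * rng.uniform(0.2, 0.4),
                mu_511=MU_LUNG_MM,
            )
        )
    # liver-like hot organ in the lower half
    organs.append(
        Organ(
            Ellipse(
                (cy + 0.35 * ay, cx - 0.25 * ax),
                (0.25 * ay * rng.uniform(0.8, 1.2), 0.30 * ax * rng.uniform(0.8, 1.2)),
            ),
            activity=body_act * rng.uniform(1.4, 2.2),
            mu_511=MU_SOFT_TISSUE_MM,
        )
    )
    lesions = []
    for _ in range(rng.integers(0, 4)):
        ly = cy + rng.uniform(-0.6, 0.6) * ay
        lx = cx + rng.uniform(-0.6, 0.6) * ax
        lesions.append(
            Lesion((ly, lx), radius_mm=rng.uniform(6, 15), activity=body_act * rng.uniform(2, 5))
        )
    return PhantomSpec(
        grid_size=grid_size,
        pixel_size_mm=pixel_size_mm,
        body=body,
        body_activity=body_act,
        organs=tuple(organs),
        lesions=tuple(lesions),
        texture_amplitude=0.15,
    )


def generate_center_dataset(
    profile: CenterProfile,
    master_seed: int,
    grid_size: int = 64,
    pixel_size_mm: float = 3.0,
    n_angles: int = 32,
) -> CenterDataset:
    """All studies of one center, bit-for-bit reproducible from master_seed.

    Phantom anatomy for study ``i`` depends only on (master_seed, i), never on
    the profile, so two centers sharing a master seed image the same patients
    through different scanners.
    """
    profile.validate()
    if profile.n_studies < 3:
        raise ValueError("n_studies must be >= 3")
    studies = []
    for i in range(profile.n_studies):
        geom_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master_seed, spawn_key=(i, 0))
        )
        spec = random_phantom_spec(geom_rng, grid_size, pixel_size_mm)
        activity, mu = build_phantom(spec, seed=int(geom_rng.integers(2**31)))
        meta_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=master_seed, spawn_key=(i, 1))
        )
        suv_meta = {
            "injected_activity_MBq": meta_rng.uniform(300, 550),
            "body_weight_kg": meta_rng.uniform(55, 95),
        }
        noise_seed = np.random.SeedSequence(entropy=master_seed, spawn_key=(i, 2))
        studies.append(
            simulate_pair(
                activity,
                mu,
                profile,
                suv_meta,
                noise_seed,
                pixel_size_mm,
                n_angles=n_angles,
                study_id=f"{profile.center_id}-{i:03d}",
            )
        )
    return CenterDataset(profile=profile, studies=studies)
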