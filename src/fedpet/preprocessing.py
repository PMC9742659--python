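"""SUV conversion, grid resampling, and intensity normalization.

The preprocessing contract for every center is identical: convert both NAC
and reference ASC images to standardized uptake values, resample to a common
voxel grid (3 x 3 mm in-plane for 2D slices; 3 x 3 x 4 mm for volumes), then
divide NAC by 3 and ASC by 9 and clip to [0, 5], so all training inputs and
targets across centers share the 0-5 range.

Unit convention for SUV: images are activity concentrations in kBq/mL,
injected activity in MBq, body weight in kg, so

    SUV(v) = image(v) [kBq/mL] * weight [kg] * decay_factor / injected [MBq]

(the kilo/mega prefixes cancel against g/mL tissue density of 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SUVParameters",
    "GridSpec",
    "NormalizationRule",
    "to_suv",
    "resample",
    "normalize",
    "denormalize",
    "DEFAULT_SPACING_MM",
]

DEFAULT_SPACING_MM = (3.0, 3.0, 4.0)


@dataclass(frozen=True)
class SUVParameters:
    injected_activity_MBq: float
    body_weight_kg: float
    decay_correction_factor: float = 1.0

    def validate(self):
        if (
            self.injected_activity_MBq <= 0
            or self.body_weight_kg <= 0
            or self.decay_correction_factor <= 0
        ):
            raise ValueError("SUV parameters must all be positive")


@dataclass(frozen=True)
class GridSpec:
    """Regular sampling grid: per-axis spacing (mm), size, world origin (mm).

    Works for 2D slices and 3D volumes alike (tuple lengths must agree).
    """

    spacing_mm: tuple
    size: tuple
    origin_mm: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "size", tuple(int(n) for n in self.size))
        if self.origin_mm is not None:
            object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        if len(self.spacing_mm) != len(self.size):
            raise ValueError("spacing and size must have the same dimensionality")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("grid spacing must be positive")
        if any(n < 1 for n in self.size):
            raise ValueError("grid size must be positive")
        if self.origin_mm is None:
            object.__setattr__(self, "origin_mm", (0.0,) * len(self.size))
        elif len(self.origin_mm) != len(self.size):
            raise ValueError("origin must match dimensionality")

    @property
    def ndim(self):
        return len(self.size)


@dataclass(frozen=True)
class NormalizationRule:
    """Empirical intensity normalization: divide and clip to [0, 5].

    Divisors are 3 for NAC and 9 for ASC by default; the clip guarantees the
    harmonized 0-5 range (clipped-voxel counts are logged for audit).
    """

    role: str  # "NAC" or "ASC"
    divisor: float = None
    clip_range: tuple = (0.0, 5.0)

    _DEFAULTS = {"NAC": 3.0, "ASC": 9.0}

    def __post_init__(self):
        if self.role not in self._DEFAULTS:
            raise ValueError("role must be 'NAC' or 'ASC'")
        if self.divisor is None:
            object.__setattr__(self, "divisor", self._DEFAULTS[self.role])
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")


def to_suv(image: np.ndarray, params: SUVParameters) -> np.ndarray:
    """Convert an activity-concentration image (kBq/mL) to SUV (linear map)."""
    params.validate()
    scale = (
        params.body_weight_kg
        * params.decay_correction_factor
        / params.injected_activity_MBq
    )
    return np.asarray(image, dtype=float) * scale


def resample(image: np.ndarray, source: GridSpec, target: GridSpec) -> np.ndarray:
    """Linear-interpolation resampling from one grid to another.

    Voxel centers sit at origin + (index + 0.5) * spacing; values requested
    outside the source extent are 0.  A constant image therefore stays
    constant in the interior and may taper in the outermost band.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != source.ndim or source.ndim != target.ndim:
        raise ValueError("image, source and target dimensionalities must agree")
    if tuple(image.shape) != tuple(source.size):
        raise ValueError(f"image shape {image.shape} does not match source grid {source.size}")
    if source == target:
        return image.copy()
    axes_idx = []
    for ax in range(target.ndim):
        world = target.origin_mm[ax] + (np.arange(target.size[ax]) + 0.5) * target.spacing_mm[ax]
        axes_idx.append((world - source.origin_mm[ax]) / source.spacing_mm[ax] - 0.5)
    mesh = np.meshgrid(*axes_idx, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])
    out = ndimage.map_coordinates(image, coords, order=1, mode="constant", cval=0.0)
    return out.reshape(target.size)


def normalize(image: np.ndarray, rule: NormalizationRule) -> np.ndarray:
    """Divide by the rule's divisor and clip to the rule's range."""
    lo, hi = rule.clip_range
    scaled = np.asarray(image, dtype=float) / rule.divisor
    n_clipped = int(((scaled < lo) | (scaled > hi)).sum())
    if n_clipped:
        logger.info(
            "%s normalization clipped %d voxels outside [%g, %g]",
            rule.role, n_clipped, lo, hi,
        )
    return np.clip(scaled, lo, hi)


def denormalize(image: np.ndarray, rule: NormalizationRule) -> np.ndarray:
    """Inverse of :func:`normalize` on the representable (unclipped) range."""
    return np.asarray(image, dtype=float) * rule.divisor
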