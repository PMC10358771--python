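"""Training-time augmentation transforms: random gamma and 3D elastic warp.

Both transforms are deterministic given an explicit seed, apply identically
to image and label volumes where relevant, and are safe on Z-scored
(negative-valued) inputs: the gamma power is taken after rescaling the
image to [0, 1] and undone afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ImageVolume, StructureSet, require_same_geometry

__all__ = ["AugmentConfig", "gamma_transform", "elastic_deform", "make_rng"]


@dataclass
class AugmentConfig:
    """Augmentation parameters.

    gamma_p:
        Probability that a given call applies the gamma transform (0.3
        mimics occasional contrast variation across MR acquisitions).
    gamma_range:
        Uniform range for the gamma exponent (default (0.7, 1.3)).
    elastic_grid_spacing_mm:
        Control-point spacing of the random displacement field. Coarser
        grids give smoother, more organ-scale deformations.
    elastic_max_disp_mm:
        Per-axis amplitude bound of the displacement field, in mm. "Minor"
        relative to abdominal organ size; default 4 mm.
    seed:
        Base seed for the per-call random stream.
    """

    gamma_p: float = 0.3
    gamma_range: tuple[float, float] = (0.7, 1.3)
    elastic_grid_spacing_mm: float = 50.0
    elastic_max_disp_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma_p <= 1.0):
            raise ValueError("gamma_p must be in [0, 1]")
        lo, hi = self.gamma_range
        if not (0 < lo <= hi):
            raise ValueError("gamma_range must satisfy 0 < lo <= hi")
        if self.elastic_max_disp_mm < 0:
            raise ValueError("elastic_max_disp_mm must be >= 0")
        if self.elastic_grid_spacing_mm <= 0:
            raise ValueError("elastic_grid_spacing_mm must be > 0")


def make_rng(config: AugmentConfig, call_index: int = 0) -> np.random.Generator:
    """Independent, reproducible stream for one augmentation call."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, call_index]))


def gamma_transform(vol: ImageVolume, config: AugmentConfig,
                    rng: np.random.Generator | None = None,
                    force_gamma: float | None = None) -> ImageVolume:
    """Random gamma intensity transform.

    With probability ``gamma_p`` the image is rescaled to [0, 1], raised to
    a power gamma ~ Uniform(gamma_range), and mapped back to the original
    [min, max]; otherwise it is returned unchanged. Min and max are exact
    fixed points in both branches and rank order is preserved. A constant
    volume is a documented no-op. ``force_gamma`` bypasses the coin flip
    and applies that exponent deterministically (useful for testing).
    """
    rng = rng if rng is not None else make_rng(config)
    data = np.asarray(vol.data, dtype=np.float64)
    if force_gamma is None:
        if rng.uniform() >= config.gamma_p:
            return vol.with_data(data.copy())
        gamma = rng.uniform(*config.gamma_range)
    else:
        gamma = float(force_gamma)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax == vmin:
        return vol.with_data(data.copy())
    unit = (data - vmin) / (vmax - vmin)
    return vol.with_data(unit**gamma * (vmax - vmin) + vmin)


def _displacement_field(shape, spacing, config: AugmentConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Smooth per-axis displacement field in voxel units, shape (3, *shape).

    Independent uniform draws on a coarse control grid (spacing
    ``elastic_grid_spacing_mm``) are upsampled to voxel resolution with a
    cubic spline and clipped to the amplitude bound, which cubic
    interpolation may otherwise slightly overshoot.
    """
    amp = config.elastic_max_disp_mm
    field = np.empty((3,) + tuple(shape), dtype=np.float64)
    if amp == 0:
        field.fill(0.0)
        return field
    # control-grid shape: at least 4 points per axis for the cubic spline
    n_ctrl = [max(4, int(np.ceil(shape[i] * spacing[i] /
                                 config.elastic_grid_spacing_mm)) + 3)
              for i in range(3)]
    for axis in range(3):
        coarse = rng.uniform(-amp, amp, size=n_ctrl)
        zoom = [shape[i] / n_ctrl[i] for i in range(3)]
        fine = ndimage.zoom(coarse, zoom, order=3, mode="nearest",
                            grid_mode=True)
        np.clip(fine, -amp, amp, out=fine)
        field[axis] = fine / spacing[axis]  # mm -> voxel units
    return field


def elastic_deform(vol: ImageVolume, structures: StructureSet | None,
                   config: AugmentConfig,
                   rng: np.random.Generator | None = None):
    """Warp an image and its labels with one smooth random displacement field.

    The image is resampled with linear interpolation, every mask with
    nearest-neighbour on the *same* field, so labels stay binary and move
    exactly with the image. Geometry is unchanged; out-of-volume samples
    are edge-clamped. Identical rng state reproduces identical output.
    """
    rng = rng if rng is not None else make_rng(config)
    if structures is not None and len(structures):
        first = next(iter(structures.organs.values()))
        require_same_geometry(vol, first)

    field = _displacement_field(vol.shape, vol.spacing, config, rng)
    if not np.any(field):
        warped_vol = vol.with_data(vol.data.copy())
        warped_set = None
        if structures is not None:
            warped_set = StructureSet(
                {n: m.with_data(m.data.copy()) for n, m in structures.items()})
        return warped_vol, warped_set

    grid = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in vol.shape],
                       indexing="ij")
    coords = [grid[a] + field[a] for a in range(3)]
    warped = ndimage.map_coordinates(vol.data, coords, order=1, mode="nearest")
    warped_vol = vol.with_data(warped)

    warped_set = None
    if structures is not None:
        warped_masks = {}
        for name, mask in structures.items():
            w = ndimage.map_coordinates(mask.data.astype(np.uint8), coords,
                                        order=0, mode="nearest")
            warped_masks[name] = mask.with_data(w.astype(bool))
        warped_set = StructureSet(warped_masks)
    return warped_vol, warped_set
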