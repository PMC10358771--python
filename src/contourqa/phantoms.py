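"""Synthetic abdominal phantoms with analytically known metric behaviour.

The study data this toolkit targets — multi-sequence abdominal MRIs with
expert organ contours — are clinical and private, so every computation is
exercised on synthetic phantoms instead: caricature organs (ellipsoids,
tubes, C-loops) laid out at realistic positions and sizes spanning two
orders of magnitude of volume (a few cc for the esophagus up to hundreds
of cc for the liver), MRI-like piecewise-constant intensities modulated by
a smooth multiplicative bias field plus Gaussian noise, and controlled
contour perturbations (translations, erosions, dropped slices, boundary
jitter) whose effect on each accuracy metric is known in closed form or
derivable by brute force.

Everything is reproducible from ``(spec, seed)`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from . import oracle
from .metrics import MetricConfig, evaluate_pair
from .volume import BinaryMask, ImageVolume, StructureSet

__all__ = [
    "OrganRecipe",
    "PhantomSpec",
    "PerturbationSpec",
    "PerturbResult",
    "default_organ_recipes",
    "make_phantom",
    "perturb",
    "BenchmarkCase",
    "make_benchmark_suite",
]


@dataclass
class OrganRecipe:
    """One caricature organ: a simple solid with an intensity level.

    shape:
        ``ellipsoid`` (size = semi-axes mm), ``tube`` (axis-z cylinder,
        size = (radius, z_lo, z_hi) mm), or ``c_loop`` (half torus in an
        axial plane, size = (ring_radius, tube_radius) mm).
    """

    name: str
    shape: str
    size_mm: tuple[float, ...]
    center_mm: tuple[float, float, float]
    intensity_mean: float = 100.0
    intensity_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "tube", "c_loop", "box"):
            raise ValueError(f"unknown organ shape {self.shape!r}")


def default_organ_recipes() -> list[OrganRecipe]:
    """Twelve-organ abdominal layout for the default phantom grid.

    Positions and sizes are chosen to be pairwise disjoint on the default
    ~158 x 158 x 144 mm grid while keeping each organ's volume in a
    realistic (scaled-down) range.
    """
    return [
        OrganRecipe("liver", "ellipsoid", (40, 32, 42), (45, 55, 70), 220),
        OrganRecipe("stomach", "ellipsoid", (22, 18, 26), (105, 45, 80), 140),
        OrganRecipe("spleen", "ellipsoid", (18, 14, 22), (120, 95, 60), 230),
        OrganRecipe("left_kidney", "ellipsoid", (13, 11, 22), (115, 120, 45), 200),
        OrganRecipe("right_kidney", "ellipsoid", (13, 11, 22), (35, 120, 45), 200),
        OrganRecipe("pancreas", "ellipsoid", (28, 9, 8), (78, 95, 75), 180),
        OrganRecipe("small_bowel", "ellipsoid", (24, 20, 12), (78, 60, 120), 110),
        OrganRecipe("aorta", "tube", (7.5, 0.0, 1e9), (78, 125, 0), 260),
        OrganRecipe("spinal_cord", "tube", (4.5, 0.0, 1e9), (78, 145, 0), 120),
        OrganRecipe("esophagus", "tube", (4.0, 90.0, 140.0), (60, 20, 0), 150),
        OrganRecipe("duodenum", "c_loop", (20, 6), (40, 95, 15), 160),
        OrganRecipe("large_bowel", "c_loop", (35, 9), (78, 60, 15), 100),
    ]


@dataclass
class PhantomSpec:
    """Phantom geometry, organ recipes, and intensity-corruption model.

    Default spacing matches the in-plane resolution and 3 mm slices of a
    post-contrast T1 abdominal acquisition; ``t2like`` spacing
    (1.1875, 1.1875, 3.0) is typical of a half-Fourier T2 sequence.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (1.640625, 1.640625, 3.0)
    organs: list[OrganRecipe] = field(default_factory=default_organ_recipes)
    background_intensity: float = 60.0
    bias_amplitude: float = 0.3
    bias_smoothness_mm: float = 120.0
    noise_sd: float = 5.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.bias_amplitude <= 0.5):
            raise ValueError("bias_amplitude must be in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


T2_LIKE_SPACING = (1.1875, 1.1875, 3.0)


def _coordinate_grids(shape, spacing):
    axes = [np.arange(shape[i], dtype=np.float64) * spacing[i] for i in range(3)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize(recipe: OrganRecipe, grids) -> np.ndarray:
    X, Y, Z = grids
    cx, cy, cz = recipe.center_mm
    if recipe.shape == "ellipsoid":
        a, b, c = recipe.size_mm
        return (((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2
                + ((Z - cz) / c) ** 2) < 1.0
    if recipe.shape == "tube":
        radius, z_lo, z_hi = recipe.size_mm
        in_plane = ((X - cx) ** 2 + (Y - cy) ** 2) < radius**2
        return in_plane & (Z >= z_lo) & (Z <= z_hi)
    if recipe.shape == "c_loop":
        ring_r, tube_r = recipe.size_mm
        radial = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
        torus = ((radial - ring_r) ** 2 + (Z - cz) ** 2) < tube_r**2
        return torus & (X >= cx)
    # box: size = half-widths
    hx, hy, hz = recipe.size_mm
    return ((np.abs(X - cx) < hx) & (np.abs(Y - cy) < hy)
            & (np.abs(Z - cz) < hz))


def _bias_field(shape, spacing, amplitude, smoothness_mm,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude].

    A product of low-frequency cosines with seeded phases; wavelength set
    by ``smoothness_mm``.
    """
    if amplitude == 0:
        return np.ones(shape, dtype=np.float64)
    X, Y, Z = _coordinate_grids(shape, spacing)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    k = np.pi / smoothness_mm
    s = (np.cos(k * X + phases[0]) * np.cos(k * Y + phases[1])
         * np.cos(k * Z + phases[2]))
    return 1.0 + amplitude * s


def make_phantom(spec: PhantomSpec | None = None):
    """Generate (intensity volume, clean structure set, ground truth).

    The intensity volume is the per-organ piecewise-constant image times
    the smooth bias field plus Gaussian noise. ``ground_truth`` carries the
    generating bias field, the noiseless unbiased image, and the per-organ
    mean intensities, for use as test oracles.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    grids = _coordinate_grids(spec.grid_shape, spec.spacing)
    extent = [spec.grid_shape[i] * spec.spacing[i] for i in range(3)]

    clean = np.full(spec.grid_shape, float(spec.background_intensity))
    occupancy = np.zeros(spec.grid_shape, dtype=bool)
    organs: dict[str, BinaryMask] = {}
    for recipe in spec.organs:
        m = _rasterize(recipe, grids)
        if not m.any():
            raise ValueError(f"organ recipe {recipe.name!r} rasterizes to an "
                             f"empty mask on grid extent {extent} mm")
        if not spec.allow_overlap and (m & occupancy).any():
            raise ValueError(f"organ recipe {recipe.name!r} overlaps a previous "
                             "organ; set allow_overlap=True if intended")
        occupancy |= m
        organs[recipe.name] = BinaryMask(m, spec.spacing)
        value = recipe.intensity_mean
        if recipe.intensity_sd > 0:
            clean[m] = value + rng.normal(0.0, recipe.intensity_sd,
                                          size=int(m.sum()))
        else:
            clean[m] = value

    bias = _bias_field(spec.grid_shape, spec.spacing, spec.bias_amplitude,
                       spec.bias_smoothness_mm, rng)
    noisy = clean * bias
    if spec.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vol = ImageVolume(noisy, spec.spacing)
    ground_truth = {
        "bias_field": ImageVolume(bias, spec.spacing),
        "noiseless": ImageVolume(clean, spec.spacing),
        "organ_intensities": {r.name: r.intensity_mean for r in spec.organs},
    }
    return vol, StructureSet(organs), ground_truth


# ---------------------------------------------------------------------------
# Controlled perturbations
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """A single contour perturbation with a known geometric effect.

    op:
        ``translate_mm`` (magnitude = mm shift, scalar for x or a 3-tuple;
        quantized to whole voxels, realized shift reported back),
        ``dilate_voxels`` / ``erode_voxels`` (magnitude = iterations of a
        6-connected — or box, see ``structure`` — element),
        ``drop_slices`` (magnitude = number of top occupied axial slices
        emptied), ``boundary_jitter`` (magnitude = flip probability of
        boundary-adjacent voxels).
    """

    op: str
    magnitude: float | tuple[float, float, float] = 0.0
    seed: int = 0
    structure: str = "cross"  # "cross" (6-connected) or "box" (26-connected)

    def __post_init__(self) -> None:
        ops = ("translate_mm", "dilate_voxels", "erode_voxels",
               "drop_slices", "boundary_jitter")
        if self.op not in ops:
            raise ValueError(f"unknown perturbation op {self.op!r}")
        if self.structure not in ("cross", "box"):
            raise ValueError(f"unknown structuring element {self.structure!r}")


@dataclass
class PerturbResult:
    mask: BinaryMask
    realized_shift_mm: Optional[tuple[float, float, float]] = None
    emptied: bool = False


def _integer_shift(data: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(data)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for axis, s in enumerate(shift):
        n = data.shape[axis]
        if abs(s) >= n:
            return out
        if s >= 0:
            src[axis] = slice(0, n - s)
            dst[axis] = slice(s, n)
        else:
            src[axis] = slice(-s, n)
            dst[axis] = slice(0, n + s)
    out[tuple(dst)] = data[tuple(src)]
    return out


def perturb(mask: BinaryMask, pspec: PerturbationSpec) -> PerturbResult:
    """Apply one perturbation; emptying the mask is flagged, not an error."""
    data = mask.data
    if pspec.op == "translate_mm":
        mag = pspec.magnitude
        if np.isscalar(mag):
            mag = (float(mag), 0.0, 0.0)
        voxels = tuple(int(round(mag[i] / mask.spacing[i])) for i in range(3))
        realized = tuple(voxels[i] * mask.spacing[i] for i in range(3))
        out = _integer_shift(data, voxels)
        return PerturbResult(mask.with_data(out), realized_shift_mm=realized,
                             emptied=not out.any())

    if pspec.op in ("dilate_voxels", "erode_voxels"):
        n = int(pspec.magnitude)
        if n == 0:
            return PerturbResult(mask.with_data(data.copy()))
        if pspec.structure == "cross":
            struct = ndimage.generate_binary_structure(3, 1)
        else:
            struct = np.ones((3, 3, 3), dtype=bool)
        fn = (ndimage.binary_dilation if pspec.op == "dilate_voxels"
              else ndimage.binary_erosion)
        out = fn(data, structure=struct, iterations=n)
        return PerturbResult(mask.with_data(out), emptied=not out.any())

    if pspec.op == "drop_slices":
        k = int(pspec.magnitude)
        out = data.copy()
        occupied = [z for z in range(data.shape[2]) if data[:, :, z].any()]
        for z in occupied[len(occupied) - k:] if k > 0 else []:
            out[:, :, z] = False
        return PerturbResult(mask.with_data(out), emptied=not out.any())

    # boundary_jitter
    p = float(pspec.magnitude)
    rng = np.random.default_rng(pspec.seed)
    struct = ndimage.generate_binary_structure(3, 1)
    inner = data & ~ndimage.binary_erosion(data, structure=struct)
    outer = ndimage.binary_dilation(data, structure=struct) & ~data
    boundary = inner | outer
    flips = boundary & (rng.uniform(size=data.shape) < p)
    out = data ^ flips
    return PerturbResult(mask.with_data(out), emptied=not out.any())


# ---------------------------------------------------------------------------
# Benchmark suite: perturbation families with known expected metric values
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkCase:
    """One ref/auto pair plus expected metric values with provenance tags.

    ``expected`` maps metric name to ``(value, tag)`` where tag is
    ``"analytic"`` (closed form) or ``"oracle"`` (brute-force all-pairs).
    """

    name: str
    family: str
    ref: StructureSet
    auto: StructureSet
    expected: dict[str, tuple[float, str]]
    config: MetricConfig = field(default_factory=MetricConfig)

    def evaluate(self):
        return evaluate_pair(self.auto, self.ref, self.config)["organ"]


def _cube_mask(n: int, grid: int = 24, nz: int = 16,
               spacing=(1.0, 1.0, 1.0), z_extent: int | None = None) -> BinaryMask:
    data = np.zeros((grid, grid, nz), dtype=bool)
    lo = (grid - n) // 2
    z_n = z_extent if z_extent is not None else min(n, nz - 4)
    z_lo = (nz - z_n) // 2
    data[lo:lo + n, lo:lo + n, z_lo:z_lo + z_n] = True
    return BinaryMask(data, spacing)


def _single(mask: BinaryMask) -> StructureSet:
    return StructureSet({"organ": mask})


def _oracle_expected(auto: BinaryMask, ref: BinaryMask,
                     config: MetricConfig) -> dict[str, tuple[float, str]]:
    return {
        "mda_mm": (oracle.brute_mda(auto, ref), "oracle"),
        "hd95_mm": (oracle.brute_hd(auto, ref, config.hd_percentile,
                                    config.hd_convention), "oracle"),
        "sdsc": (oracle.brute_sdsc(auto, ref, config.tolerance_mm), "oracle"),
        "apl_mm": (oracle.brute_apl_slice2d(auto, ref, config.tolerance_mm),
                   "oracle"),
    }


def make_benchmark_suite(seed: int = 0) -> list[BenchmarkCase]:
    """A fixed ensemble of perturbation families with expected metric values.

    Families: identical pairs, sub-tolerance translations, supra-tolerance
    translations, box dilations, erosions, dropped slices, and missing
    organs — three magnitudes each. Expected values are closed-form where
    the geometry allows and brute-force otherwise.
    """
    del seed  # the suite is fully deterministic; kept for interface symmetry
    config = MetricConfig()
    cases: list[BenchmarkCase] = []

    # 1. identical pairs
    for n in (6, 8, 10):
        ref = _cube_mask(n)
        expected = {
            "dsc": (1.0, "analytic"), "mda_mm": (0.0, "analytic"),
            "hd95_mm": (0.0, "analytic"), "pvd_pct": (0.0, "analytic"),
            "sdsc": (1.0, "analytic"), "apl_mm": (0.0, "analytic"),
        }
        cases.append(BenchmarkCase(f"identity_n{n}", "identity",
                                   _single(ref), _single(ref), expected, config))

    # 2./3. translations of a 10-voxel cube; the 0.5 mm-spacing case keeps a
    # third sub-tolerance magnitude that is not voxel-aligned with tolerance
    translations = [(1.0, (1.0, 1.0, 1.0)), (2.0, (1.0, 1.0, 1.0)),
                    (1.5, (0.5, 0.5, 1.0)), (3.0, (1.0, 1.0, 1.0)),
                    (4.0, (1.0, 1.0, 1.0)), (5.0, (1.0, 1.0, 1.0))]
    for shift, spacing in translations:
        ref = _cube_mask(10, spacing=spacing)
        auto = perturb(ref, PerturbationSpec("translate_mm", float(shift))).mask
        family = "translate_sub_tol" if shift <= config.tolerance_mm \
            else "translate_supra_tol"
        shift_vox = shift / spacing[0]
        expected: dict[str, tuple[float, str]] = {
            "dsc": ((10 - shift_vox) / 10, "analytic"),
            "pvd_pct": (0.0, "analytic"),
        }
        if shift <= config.tolerance_mm:
            expected["sdsc"] = (1.0, "analytic")
            expected["apl_mm"] = (0.0, "analytic")
            expected["mda_mm"] = (oracle.brute_mda(auto, ref), "oracle")
            expected["hd95_mm"] = (oracle.brute_hd(auto, ref), "oracle")
        else:
            expected.update(_oracle_expected(auto, ref, config))
        cases.append(BenchmarkCase(f"translate_{shift}mm", family,
                                   _single(ref), _single(auto), expected, config))

    # 4. box dilations of an 8-voxel cube (full 26-connected growth keeps
    #    the result an exact cube, so the volume change is closed-form)
    for k in (1, 2, 3):
        ref = _cube_mask(8, z_extent=8)
        auto = perturb(ref, PerturbationSpec("dilate_voxels", k,
                                             structure="box")).mask
        v_ref, v_auto = 8**3, (8 + 2 * k) ** 3
        expected = {
            "dsc": (2 * v_ref / (v_ref + v_auto), "analytic"),
            "pvd_pct": (100.0 * (v_auto - v_ref) / v_ref, "analytic"),
        }
        expected.update(_oracle_expected(auto, ref, config))
        cases.append(BenchmarkCase(f"dilate_{k}", "dilate",
                                   _single(ref), _single(auto), expected, config))

    # 5. erosions of a 12-voxel cube (erosion of a cube is again a cube)
    for k in (1, 2, 3):
        ref = _cube_mask(12, grid=26, nz=18, z_extent=12)
        auto = perturb(ref, PerturbationSpec("erode_voxels", k)).mask
        v_ref, v_auto = 12**3, (12 - 2 * k) ** 3
        expected = {
            "dsc": (2 * v_auto / (v_ref + v_auto), "analytic"),
            "pvd_pct": (100.0 * (v_auto - v_ref) / v_ref, "analytic"),
        }
        expected.update(_oracle_expected(auto, ref, config))
        cases.append(BenchmarkCase(f"erode_{k}", "erode",
                                   _single(ref), _single(auto), expected, config))

    # 6. dropped superior slices of a 10 x 10 x 8 block at 1 mm in-plane
    for k in (1, 2, 3):
        ref = _cube_mask(10, z_extent=8)
        auto = perturb(ref, PerturbationSpec("drop_slices", k)).mask
        v_ref, v_auto = 10 * 10 * 8, 10 * 10 * (8 - k)
        expected = {
            "dsc": (2 * v_auto / (v_ref + v_auto), "analytic"),
            "pvd_pct": (100.0 * (v_auto - v_ref) / v_ref, "analytic"),
            # each dropped slice contributes its full 40 mm perimeter
            "apl_mm": (40.0 * k, "analytic"),
        }
        cases.append(BenchmarkCase(f"drop_slices_{k}", "drop_slices",
                                   _single(ref), _single(auto), expected, config))

    # 7. missing organ (auto empty): APL is the whole reference contour
    for n in (6, 8, 10):
        ref = _cube_mask(n, z_extent=n // 2)
        auto = ref.with_data(np.zeros(ref.shape, dtype=bool))
        expected = {
            "dsc": (0.0, "analytic"),
            "pvd_pct": (-100.0, "analytic"),
            "apl_mm": (4.0 * n * (n // 2), "analytic"),
        }
        cases.append(BenchmarkCase(f"missing_n{n}", "missing_organ",
                                   _single(ref), _single(auto), expected, config))

    return cases
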