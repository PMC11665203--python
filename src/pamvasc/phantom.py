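"""Synthetic PAM/CFM phantoms with exact ground truth.

Vessel scenes are random binary branching trees grown from field-edge roots:
child diameter = parent diameter x branch_decay, centerlines are gently
jittered random walks (smooth at the rendering scale). Tube interiors render
at a constant intensity, the scene is blurred by a Gaussian PSF of known
FWHM and corrupted by additive Gaussian noise. Ground truth records the
unblurred mask, the exact polyline centerlines, per-diameter-bin centerline
lengths, hemorrhage masks, and plaque coordinates.

Geometry and noise derive from independent sub-streams of one master seed,
so the same geometry can be rendered with different blur or noise settings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from pamvasc.bins import DEFAULT_BINS_UM, assign_bin, bin_edges_to_pairs, bin_label
from pamvasc.imgio import IntensityImage

BinPair = Tuple[float, float]


@dataclass
class Centerline:
    """A vessel centerline polyline with per-point diameters, all in micrometres.

    ``points`` is an (N, 2) array of (y_um, x_um) positions.
    """

    points: np.ndarray
    diameters_um: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.diameters_um = np.broadcast_to(
            np.asarray(self.diameters_um, dtype=np.float64), (self.points.shape[0],)
        ).copy()
        if self.points.shape[1] != 2:
            raise ValueError("centerline points must be (N, 2)")
        if np.any(self.diameters_um <= 0):
            raise ValueError("diameters must be > 0")

    @property
    def length_um(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def mean_diameter_um(self) -> float:
        return float(self.diameters_um.mean())


@dataclass
class PhantomSpec:
    """Geometry, optics and noise parameters of a synthetic vessel scene."""

    field_size_um: Tuple[float, float] = (2000.0, 2000.0)
    grid_px: Tuple[int, int] = (512, 512)
    n_trees: int = 4
    root_diameter_um: float = 45.0
    branch_decay: float = 0.6
    capillary_fraction: float = 0.0
    min_diameter_um: float = 5.0
    psf_fwhm_um: float = 8.0
    noise_sigma: float = 4.0
    background_level: float = 20.0
    vessel_intensity: float = 200.0
    n_hemorrhages: int = 0
    hemorrhage_radius_um: float = 200.0
    hemorrhage_intensity: float = 60.0
    noise_model: str = "gaussian"  # "gaussian" | "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        py = self.field_size_um[0] / self.grid_px[0]
        px = self.field_size_um[1] / self.grid_px[1]
        if not math.isclose(py, px, rel_tol=1e-9):
            raise ValueError(
                f"anisotropic pixel pitch ({py:.4f} x {px:.4f} um/px); "
                "field_size_um and grid_px must yield one isotropic pitch"
            )
        if self.psf_fwhm_um < 0:
            raise ValueError("psf_fwhm_um must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_trees < 0 or self.n_hemorrhages < 0:
            raise ValueError("counts must be >= 0")
        if not 0 < self.branch_decay <= 1:
            raise ValueError("branch_decay must lie in (0, 1]")
        if not 0 <= self.capillary_fraction < 1:
            raise ValueError("capillary_fraction must lie in [0, 1)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.n_trees > 0 and self.pixel_pitch_um > self.min_diameter_um:
            raise ValueError(
                f"pixel pitch {self.pixel_pitch_um:.3f} um exceeds the smallest "
                f"requested vessel diameter {self.min_diameter_um:g} um; such "
                "vessels are unrenderable — refine the grid or raise min_diameter_um"
            )

    @property
    def pixel_pitch_um(self) -> float:
        return self.field_size_um[0] / self.grid_px[0]

    @property
    def area_mm2(self) -> float:
        return self.field_size_um[0] * self.field_size_um[1] / 1e6


@dataclass
class PhantomTruth:
    """Exact ground truth for one generated image."""

    mask: np.ndarray
    centerlines: List[Centerline]
    per_bin_length_um: Dict[BinPair, float]
    plaque_xy: List[Tuple[float, float]]
    hemorrhage_mask: np.ndarray
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        total = self.total_length_um
        binned = sum(self.per_bin_length_um.values())
        if total > 0 and not math.isclose(binned, total, rel_tol=1e-6):
            raise ValueError(
                f"per-bin lengths ({binned:.6f}) do not sum to total centerline "
                f"length ({total:.6f})"
            )

    @property
    def total_length_um(self) -> float:
        return float(sum(c.length_um for c in self.centerlines))

    @property
    def area_mm2(self) -> float:
        h, w = self.mask.shape
        return h * w * (self.pixel_pitch_um / 1000.0) ** 2

    def true_vld(self) -> Dict[BinPair, float]:
        """True vessel length density (mm/mm^2) per diameter bin."""
        area = self.area_mm2
        return {b: (l / 1000.0) / area for b, l in self.per_bin_length_um.items()}


@dataclass
class CohortSpec:
    """Design of a simulated two-or-more-group study.

    Each group is (label, per-bin VLD multiplier mapping, plaque density per
    mm^2). Multipliers < 1 randomly thin centerlines in the matching diameter
    bin; multipliers > 1 add jittered duplicates.
    """

    n_per_group: int
    groups: Sequence[Tuple[str, Dict[BinPair, float], float]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for label, mult, dens in self.groups:
            if any(m <= 0 for m in mult.values()):
                raise ValueError(f"group {label!r}: multipliers must be > 0")
            if dens < 0:
                raise ValueError(f"group {label!r}: plaque density must be >= 0")


def bin_lengths(
    centerlines: Sequence[Centerline], edges: Sequence[float] = DEFAULT_BINS_UM
) -> Dict[BinPair, float]:
    """Exact centerline length per diameter bin (binned by polyline mean diameter)."""
    out: Dict[BinPair, float] = {pair: 0.0 for pair in bin_edges_to_pairs(edges)}
    for c in centerlines:
        out[assign_bin(c.mean_diameter_um, edges)] += c.length_um
    return out


# ---------------------------------------------------------------------------
# geometry growth
# ---------------------------------------------------------------------------

_STEP_UM = 8.0
_BRANCH_LEN_UM = (180.0, 420.0)
_MAX_DEPTH = 8


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    angle: float,
    length_um: float,
    field: Tuple[float, float],
) -> Tuple[np.ndarray, float, bool]:
    """Random-walk polyline; returns (points, final angle, still inside field)."""
    pts = [start.copy()]
    pos = start.copy()
    n_steps = max(2, int(round(length_um / _STEP_UM)))
    inside = True
    for _ in range(n_steps):
        angle += rng.normal(0.0, 0.07)
        pos = pos + _STEP_UM * np.array([math.sin(angle), math.cos(angle)])
        if not (0 <= pos[0] < field[0] and 0 <= pos[1] < field[1]):
            pos = np.clip(pos, [0.0, 0.0], [field[0] - 1e-6, field[1] - 1e-6])
            pts.append(pos)
            inside = False
            break
        pts.append(pos)
    return np.array(pts), angle, inside


def _grow_tree(rng: np.random.Generator, spec: PhantomSpec) -> List[Centerline]:
    field = spec.field_size_um
    side = int(rng.integers(4))
    t = rng.uniform(0.1, 0.9)
    if side == 0:  # top edge, heading down
        start, base = np.array([0.0, t * field[1]]), math.pi / 2
    elif side == 1:  # bottom edge
        start, base = np.array([field[0] - 1e-6, t * field[1]]), -math.pi / 2
    elif side == 2:  # left edge, heading right
        start, base = np.array([t * field[0], 0.0]), 0.0
    else:  # right edge
        start, base = np.array([t * field[0], field[1] - 1e-6]), math.pi

    # angle convention: dy = sin, dx = cos
    angle0 = base + rng.uniform(-0.5, 0.5)
    stack = [(start, angle0, spec.root_diameter_um, 0)]
    polylines: List[Centerline] = []
    while stack:
        pos, angle, diam, depth = stack.pop()
        length = rng.uniform(*_BRANCH_LEN_UM)
        pts, angle, inside = _walk(rng, pos, angle, length, field)
        if len(pts) >= 2:
            polylines.append(Centerline(pts, np.full(len(pts), diam)))
        child_diam = diam * spec.branch_decay
        if inside and child_diam >= spec.min_diameter_um and depth < _MAX_DEPTH:
            spread = rng.uniform(0.35, 0.8)
            stack.append((pts[-1], angle - spread, child_diam, depth + 1))
            stack.append((pts[-1], angle + spread, child_diam, depth + 1))
    return polylines


def _add_capillary_sprouts(
    rng: np.random.Generator, polylines: List[Centerline], spec: PhantomSpec
) -> None:
    """Sprout short sub-10 um branches until the capillary length fraction is met."""
    if spec.capillary_fraction <= 0 or not polylines:
        return
    for _ in range(500):
        total = sum(c.length_um for c in polylines)
        cap = sum(c.length_um for c in polylines if c.mean_diameter_um < 10.0)
        if total == 0 or cap / total >= spec.capillary_fraction:
            return
        host = polylines[int(rng.integers(len(polylines)))]
        i = int(rng.integers(len(host.points)))
        diam = rng.uniform(spec.min_diameter_um, min(9.5, 10.0))
        pts, _, _ = _walk(
            rng,
            host.points[i].copy(),
            rng.uniform(0, 2 * math.pi),
            rng.uniform(80.0, 200.0),
            spec.field_size_um,
        )
        if len(pts) >= 2:
            polylines.append(Centerline(pts, np.full(len(pts), diam)))


def grow_geometry(spec: PhantomSpec, rng: Optional[np.random.Generator] = None) -> List[Centerline]:
    """Grow the vessel centerline set for a spec (no rendering)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    polylines: List[Centerline] = []
    for _ in range(spec.n_trees):
        polylines.extend(_grow_tree(rng, spec))
    _add_capillary_sprouts(rng, polylines, spec)
    return polylines


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def rasterize_centerlines(
    centerlines: Sequence[Centerline], grid_px: Tuple[int, int], pixel_pitch_um: float
) -> np.ndarray:
    """Boolean tube mask: pixel centers within diameter/2 of a centerline."""
    h, w = grid_px
    mask = np.zeros((h, w), dtype=bool)
    for c in centerlines:
        pts_px = c.points / pixel_pitch_um
        radii_px = c.diameters_um / (2.0 * pixel_pitch_um)
        for i in range(len(pts_px) - 1):
            p0, p1 = pts_px[i], pts_px[i + 1]
            r = max(radii_px[i], radii_px[i + 1])
            r = max(r, 0.5)  # guarantee at least 1-px-wide rendering
            lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
            hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int)
            lo = np.maximum(lo, 0)
            hi = np.minimum(hi, [h - 1, w - 1])
            if np.any(hi < lo):
                continue
            yy, xx = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
            d = p1 - p0
            seg_len2 = float(d @ d)
            if seg_len2 == 0:
                dist2 = (yy - p0[0]) ** 2 + (xx - p0[1]) ** 2
            else:
                t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / seg_len2
                t = np.clip(t, 0.0, 1.0)
                dist2 = (yy - (p0[0] + t * d[0])) ** 2 + (xx - (p0[1] + t * d[1])) ** 2
            mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1] |= dist2 <= r * r
    return mask


def _render_scene(
    spec: PhantomSpec,
    centerlines: Sequence[Centerline],
    noise_rng: np.random.Generator,
    geom_rng: Optional[np.random.Generator] = None,
) -> Tuple[IntensityImage, np.ndarray, np.ndarray]:
    pitch = spec.pixel_pitch_um
    mask = rasterize_centerlines(centerlines, spec.grid_px, pitch)
    hem_mask = np.zeros(spec.grid_px, dtype=bool)
    if spec.n_hemorrhages > 0:
        rng = geom_rng if geom_rng is not None else noise_rng
        r_px = spec.hemorrhage_radius_um / pitch
        h, w = spec.grid_px
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(spec.n_hemorrhages):
            cy = rng.uniform(r_px, h - 1 - r_px) if h - 1 > 2 * r_px else (h - 1) / 2
            cx = rng.uniform(r_px, w - 1 - r_px) if w - 1 > 2 * r_px else (w - 1) / 2
            hem_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2

    scene = np.maximum(
        mask.astype(np.float64) * spec.vessel_intensity,
        hem_mask.astype(np.float64) * spec.hemorrhage_intensity,
    )
    if spec.psf_fwhm_um > 0:
        sigma_px = spec.psf_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0))) / pitch
        scene = gaussian_filter(scene, sigma_px, mode="reflect")
    img = spec.background_level + scene
    if spec.noise_model == "poisson" and spec.noise_sigma > 0:
        img = noise_rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    elif spec.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)
    image = IntensityImage(img, pitch, modality="PAM", provenance=f"phantom(seed={spec.seed})")
    return image, mask, hem_mask


def phantom_from_centerlines(
    spec: PhantomSpec, centerlines: Sequence[Centerline]
) -> Tuple[IntensityImage, PhantomTruth]:
    """Render a phantom from explicitly constructed centerline geometry."""
    ss = np.random.SeedSequence(spec.seed)
    _, noise_seed = ss.spawn(2)
    noise_rng = np.random.default_rng(noise_seed)
    image, mask, hem_mask = _render_scene(spec, centerlines, noise_rng)
    truth = PhantomTruth(
        mask=mask,
        centerlines=list(centerlines),
        per_bin_length_um=bin_lengths(centerlines),
        plaque_xy=[],
        hemorrhage_mask=hem_mask,
        pixel_pitch_um=spec.pixel_pitch_um,
    )
    return image, truth


def generate_vessel_phantom(spec: PhantomSpec) -> Tuple[IntensityImage, PhantomTruth]:
    """Generate a synthetic angiogram and its exact ground truth.

    Deterministic for a fixed ``spec.seed``; the geometry stream is
    independent of the noise stream, so changing blur or noise settings
    leaves the true centerlines untouched.
    """
    ss = np.random.SeedSequence(spec.seed)
    geom_seed, noise_seed = ss.spawn(2)
    geom_rng = np.random.default_rng(geom_seed)
    noise_rng = np.random.default_rng(noise_seed)
    centerlines = grow_geometry(spec, geom_rng)
    image, mask, hem_mask = _render_scene(spec, centerlines, noise_rng, geom_rng)
    truth = PhantomTruth(
        mask=mask,
        centerlines=centerlines,
        per_bin_length_um=bin_lengths(centerlines),
        plaque_xy=[],
        hemorrhage_mask=hem_mask,
        pixel_pitch_um=spec.pixel_pitch_um,
    )
    return image, truth


# ---------------------------------------------------------------------------
# plaque phantoms
# ---------------------------------------------------------------------------


def generate_plaque_phantom(
    n_plaques: int,
    spot_fwhm_um: float = 15.0,
    background_model: str = "flat",
    seed: int = 0,
    field_size_um: Tuple[float, float] = (2000.0, 2000.0),
    grid_px: Tuple[int, int] = (512, 512),
) -> Tuple[IntensityImage, PhantomTruth]:
    """Synthetic fluorescence frame: bright Gaussian spots over a background.

    Spots are placed uniformly at random with pairwise separation of at
    least three spot FWHM; placement fails with an error if that separation
    is geometrically infeasible for the requested count.
    """
    if n_plaques < 0:
        raise ValueError("n_plaques must be >= 0")
    if not spot_fwhm_um > 0:
        raise ValueError("spot_fwhm_um must be > 0")
    if background_model not in ("flat", "vessel_bleed"):
        raise ValueError("background_model must be 'flat' or 'vessel_bleed'")

    pitch = field_size_um[0] / grid_px[0]
    min_sep = 3.0 * spot_fwhm_um
    margin = spot_fwhm_um
    usable = (field_size_um[0] - 2 * margin) * (field_size_um[1] - 2 * margin)
    if n_plaques > 0 and usable / (min_sep**2) < n_plaques:
        raise ValueError(
            f"cannot place {n_plaques} spots with pairwise separation "
            f">= {min_sep:g} um in a {field_size_um[0]:g} x {field_size_um[1]:g} um field"
        )
    ss = np.random.SeedSequence(seed)
    geom_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    coords: List[Tuple[float, float]] = []  # (x_um, y_um)
    attempts = 0
    while len(coords) < n_plaques:
        attempts += 1
        if attempts > 2000 * max(n_plaques, 1):
            raise ValueError(
                f"failed to place {n_plaques} spots with separation >= {min_sep:g} um"
            )
        x = geom_rng.uniform(margin, field_size_um[1] - margin)
        y = geom_rng.uniform(margin, field_size_um[0] - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in coords):
            coords.append((x, y))

    h, w = grid_px
    if background_model == "flat":
        img = np.full((h, w), 30.0)
    else:
        vspec = PhantomSpec(
            field_size_um=field_size_um,
            grid_px=grid_px,
            n_trees=3,
            root_diameter_um=35.0,
            psf_fwhm_um=8.0,
            noise_sigma=0.0,
            background_level=0.0,
            vessel_intensity=45.0,
            seed=int(geom_rng.integers(2**31)),
        )
        vimg, _ = generate_vessel_phantom(vspec)
        diffuse = gaussian_filter(geom_rng.standard_normal((h, w)), 25.0, mode="reflect")
        diffuse = 30.0 * (diffuse - diffuse.min()) / max(np.ptp(diffuse), 1e-12)
        img = 30.0 + diffuse + vimg.pixels

    sigma_px = spot_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0))) / pitch
    half = int(math.ceil(4 * sigma_px))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    kernel = np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    for x_um, y_um in coords:
        amp = geom_rng.uniform(160.0, 240.0)
        r, c = int(round(y_um / pitch)), int(round(x_um / pitch))
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        img[r0:r1, c0:c1] += amp * kernel[
            r0 - (r - half) : r1 - (r - half), c0 - (c - half) : c1 - (c - half)
        ]
    img = img + noise_rng.normal(0.0, 3.0, size=img.shape)
    img = np.clip(img, 0.0, None)
    image = IntensityImage(img, pitch, modality="CFM", provenance=f"plaque phantom(seed={seed})")
    truth = PhantomTruth(
        mask=np.zeros((h, w), dtype=bool),
        centerlines=[],
        per_bin_length_um={pair: 0.0 for pair in bin_edges_to_pairs(DEFAULT_BINS_UM)},
        plaque_xy=coords,
        hemorrhage_mask=np.zeros((h, w), dtype=bool),
        pixel_pitch_um=pitch,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def _apply_multipliers(
    rng: np.random.Generator,
    centerlines: List[Centerline],
    multipliers: Dict[BinPair, float],
    field: Tuple[float, float],
) -> List[Centerline]:
    out: List[Centerline] = []
    for c in centerlines:
        m = multipliers.get(assign_bin(c.mean_diameter_um), 1.0)
        if m <= 1.0:
            if rng.uniform() < m:
                out.append(c)
        else:
            out.append(c)
            extra = int(m - 1.0) + (1 if rng.uniform() < (m - 1.0) % 1.0 else 0)
            for _ in range(extra):
                shift = rng.uniform(-60.0, 60.0, size=2)
                pts = np.clip(c.points + shift, [0, 0], [field[0] - 1e-6, field[1] - 1e-6])
                out.append(Centerline(pts, c.diameters_um.copy()))
    return out


def simulate_cohort(
    cohort: CohortSpec,
    base: PhantomSpec,
    render: bool = True,
) -> List[Tuple[str, Optional[IntensityImage], PhantomTruth]]:
    """Generate per-subject phantoms for a multi-group study design.

    Per-bin multipliers thin (or duplicate) centerlines so that the true
    per-bin lengths scale by the multiplier in expectation. With
    ``render=False`` only geometry and truth are produced (fast path for
    statistical calibration studies); the image slot is then ``None``.
    """
    ss = np.random.SeedSequence(cohort.seed)
    subjects: List[Tuple[str, Optional[IntensityImage], PhantomTruth]] = []
    for g_idx, (label, multipliers, plaque_density) in enumerate(cohort.groups):
        for s_idx in range(cohort.n_per_group):
            sub_ss = np.random.SeedSequence(entropy=cohort.seed, spawn_key=(g_idx, s_idx))
            geom_rng, noise_rng, effect_rng = (
                np.random.default_rng(s) for s in sub_ss.spawn(3)
            )
            spec = replace(base, seed=int(sub_ss.generate_state(1)[0] % (2**31)))
            centerlines = grow_geometry(spec, geom_rng)
            centerlines = _apply_multipliers(
                effect_rng, centerlines, multipliers, spec.field_size_um
            )
            n_plq = int(effect_rng.poisson(plaque_density * spec.area_mm2))
            plaque_xy = [
                (
                    float(effect_rng.uniform(0, spec.field_size_um[1])),
                    float(effect_rng.uniform(0, spec.field_size_um[0])),
                )
                for _ in range(n_plq)
            ]
            if render:
                image, mask, hem_mask = _render_scene(spec, centerlines, noise_rng, geom_rng)
            else:
                image = None
                mask = np.zeros(spec.grid_px, dtype=bool)
                hem_mask = np.zeros(spec.grid_px, dtype=bool)
            truth = PhantomTruth(
                mask=mask,
                centerlines=centerlines,
                per_bin_length_um=bin_lengths(centerlines),
                plaque_xy=plaque_xy,
                hemorrhage_mask=hem_mask,
                pixel_pitch_um=spec.pixel_pitch_um,
            )
            subjects.append((label, image, truth))
    return subjects


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_phantom(
    out_dir: Union[str, Path],
    name: str,
    image: IntensityImage,
    truth: PhantomTruth,
) -> Dict[str, str]:
    """Write image + mask as 16-bit/8-bit TIFF and truth as a JSON sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{name}.tif"
    mask_path = out / f"{name}_mask.tif"
    json_path = out / f"{name}_truth.json"
    tifffile.imwrite(str(img_path), np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16))
    tifffile.imwrite(str(mask_path), truth.mask.astype(np.uint8) * 255)
    payload = {
        "pixel_pitch_um": truth.pixel_pitch_um,
        "per_bin_length_um": {bin_label(k): v for k, v in truth.per_bin_length_um.items()},
        "plaque_xy_um": [list(p) for p in truth.plaque_xy],
        "centerlines": [
            {"points_um": c.points.tolist(), "diameters_um": c.diameters_um.tolist()}
            for c in truth.centerlines
        ],
    }
    json_path.write_text(json.dumps(payload))
    return {"image": str(img_path), "mask": str(mask_path), "truth": str(json_path)}
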