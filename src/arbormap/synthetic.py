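"""Synthetic two-channel confocal phantoms with known ground truth.

Real dual-channel stacks pair a volume-filling morphology channel (eGFP or
mCherry throughout the neuron) with an immunosignal channel showing punctate
ion-channel clusters. This module renders both from analytic descriptions —
tubes with known midlines and radii, Gaussian puncta at known arc positions —
plus a configurable shot/read-noise model, so every downstream stage
(filtering, segmentation, skeletonization, profiling) can be tested against
exact ground truth.

Default geometries mirror typical high-resolution confocal acquisition: a
fine 0.08×0.08×0.084 μm voxel (2048-format imaging at Nyquist sampling) and
a coarse 0.16×0.16×0.17 μm variant (1024 format) that keeps larger fixtures
at desk scale. Signal intensity tiers follow what punctate immunostains show
in practice: baseline 0–40 gray levels, faint clusters 40–120, prominent
clusters 120–255.

Noise-free renders involve no RNG and are exactly reproducible; noisy
renders are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .image_io import ImageStack, VoxelGeometry
from .skeletonize import SeedPoint

__all__ = [
    "TubeSpec",
    "PunctumSpec",
    "NoiseModel",
    "GroundTruth",
    "Fixture",
    "fine_geometry",
    "coarse_geometry",
    "render_morphology",
    "render_signal",
    "standard_fixtures",
]

FINE_SPACING = (0.08, 0.08, 0.084)    # x, y, z in um (2048-format analog)
COARSE_SPACING = (0.16, 0.16, 0.17)   # 1024-format analog


def fine_geometry(extent_um: tuple[float, float, float]) -> VoxelGeometry:
    """Fine-sampling geometry covering the requested physical extent."""
    dx, dy, dz = FINE_SPACING
    return VoxelGeometry(dx, dy, dz, int(np.ceil(extent_um[0] / dx)),
                         int(np.ceil(extent_um[1] / dy)),
                         int(np.ceil(extent_um[2] / dz)))


def coarse_geometry(extent_um: tuple[float, float, float]) -> VoxelGeometry:
    dx, dy, dz = COARSE_SPACING
    return VoxelGeometry(dx, dy, dz, int(np.ceil(extent_um[0] / dx)),
                         int(np.ceil(extent_um[1] / dy)),
                         int(np.ceil(extent_um[2] / dz)))


@dataclass(frozen=True)
class TubeSpec:
    """A tubular neurite segment.

    ``control_points`` is an (N, 3) polyline in μm (x, y, z); ``radius`` is
    either a constant or a ``(start, end)`` pair for a linear taper along
    arc length. Terminal ends are cut flat by default so the rendered
    structure's physical length equals the centerline length; ``round_caps``
    extends each terminal end by a hemispherical cap instead.
    """

    name: str
    control_points: tuple
    radius: float | tuple[float, float] = 0.5
    intensity: float = 200.0
    round_caps: bool = False

    def points(self) -> np.ndarray:
        return np.asarray(self.control_points, dtype=float)

    def radii_at(self, t: np.ndarray) -> np.ndarray:
        """Radius at normalized arc position t in [0, 1]."""
        if np.isscalar(self.radius):
            return np.full_like(t, float(self.radius))
        r0, r1 = self.radius
        return r0 + (r1 - r0) * t


@dataclass(frozen=True)
class PunctumSpec:
    """A fluorescent punctum placed along a named tube.

    ``arc_position`` is the distance (μm) along the tube's midline;
    ``radial_offset`` displaces the punctum perpendicular to the local axis.
    ``amplitude`` is the peak gray level of the 3D Gaussian of width
    ``sigma`` (μm).
    """

    tube: str
    arc_position: float
    amplitude: float = 180.0
    sigma: float = 0.3
    radial_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude > 255:
            raise ValueError("amplitude must be <= 255")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: Poisson resampling of the signal plus additive
    Gaussian read noise of the given standard deviation (gray levels)."""

    gaussian_sigma: float = 0.0
    poisson: bool = False
    background: float = 0.0


@dataclass
class GroundTruth:
    """Analytic truth accompanying a rendered stack.

    ``midlines`` maps tube name → dict with dense ``points`` (M, 3) μm,
    ``arcs`` (M,) μm and ``radii`` (M,) μm. Topology counts describe the
    arbor after ideal reconstruction; ``puncta`` records the specs used for
    the signal channel.
    """

    midlines: dict = field(default_factory=dict)
    n_endpoints: int = 0
    n_bifurcations: int = 0
    n_root_edges: int = 0
    puncta: list = field(default_factory=list)

    def midline_points(self, names=None) -> np.ndarray:
        names = names or list(self.midlines)
        return np.concatenate([self.midlines[n]["points"] for n in names])

    def point_on_tube(self, name: str, arc: float) -> np.ndarray:
        m = self.midlines[name]
        return np.array([np.interp(arc, m["arcs"], m["points"][:, k])
                         for k in range(3)])


@dataclass
class Fixture:
    """A named phantom: rendered stack(s), truth, geometry and soma seed."""

    name: str
    morphology: ImageStack
    truth: GroundTruth
    seed_point: SeedPoint
    signal: ImageStack | None = None


def _resample_polyline(pts: np.ndarray, step: float):
    """Dense samples along a polyline: points, cumulative arcs, unit tangents."""
    segs = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(segs, axis=1)
    arcs = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arcs[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, arcs, pts[:, k])
    tang = np.gradient(out, t, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    return out, t, tang


def _voxel_centers(geometry: VoxelGeometry, sl: tuple[slice, slice, slice]):
    """Physical (z, y, x order -> returned as x,y,z) centers of a subvolume."""
    zz, yy, xx = np.mgrid[sl]
    pts = np.stack([xx * geometry.dx, yy * geometry.dy, zz * geometry.dz],
                   axis=-1)
    return pts, (zz, yy, xx)


def _apply_noise(img: np.ndarray, noise: NoiseModel | None, seed: int,
                 max_gray: float) -> np.ndarray:
    if noise is None:
        return np.clip(np.rint(img), 0, max_gray)
    out = img + noise.background
    if noise.poisson or noise.gaussian_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise.poisson:
            out = rng.poisson(np.maximum(out, 0)).astype(float)
        if noise.gaussian_sigma > 0:
            out = out + rng.normal(0.0, noise.gaussian_sigma, out.shape)
    return np.clip(np.rint(out), 0, max_gray)


def render_morphology(specs: list[TubeSpec], geometry: VoxelGeometry,
                      noise: NoiseModel | None = None, seed: int = 0,
                      psf_sigma_um: float = 0.0,
                      truth: GroundTruth | None = None,
                      ) -> tuple[ImageStack, GroundTruth]:
    """Rasterize tubes into the morphology channel and record ground truth.

    A voxel's tube intensity fades linearly from full to zero across one
    voxel at the surface (anti-aliased edge); overlapping tubes take the
    maximum. Optional Gaussian PSF blur and noise are applied afterwards.
    Deterministic for a fixed seed; noise-free renders touch no RNG.
    """
    truth = truth or GroundTruth()
    img = np.zeros(geometry.shape_zyx, dtype=float)
    spacing = np.array(geometry.spacing_xyz)
    extent = np.array(geometry.extent_um)
    edge = float(min(spacing))
    step = edge / 3.0
    for spec in specs:
        pts = spec.points()
        samples, arcs, tangents = _resample_polyline(pts, step)
        total = arcs[-1]
        radii = spec.radii_at(arcs / total if total > 0 else arcs)
        rmax = float(radii.max())
        if ((samples - rmax < -1e-9).any()
                or (samples + rmax > extent + 1e-9).any()):
            raise ValueError(f"tube {spec.name!r} extends outside the stack "
                             f"(extent {tuple(extent)} um)")
        lo = np.maximum(samples.min(axis=0) - rmax - 2 * edge, 0.0)
        hi = np.minimum(samples.max(axis=0) + rmax + 2 * edge, extent)
        sl = tuple(slice(int(lo[k] / spacing[k]),
                         int(np.ceil(hi[k] / spacing[k])) + 1)
                   for k in (2, 1, 0))
        centers, (zz, yy, xx) = _voxel_centers(geometry, sl)
        flat = centers.reshape(-1, 3)
        tree = cKDTree(samples)
        dist, nearest = tree.query(flat, workers=-1)
        r_local = radii[nearest]
        frac = np.clip((r_local - dist) / edge + 0.5, 0.0, 1.0)
        if not spec.round_caps:
            # cut terminal ends flat: blank voxels past the end planes
            for end_i, sign in ((0, -1.0), (len(samples) - 1, 1.0)):
                axial = (flat - samples[end_i]) @ (sign * tangents[end_i])
                frac[axial > 0.0] = 0.0
        vals = spec.intensity * frac
        region = img[sl]
        np.maximum(region, vals.reshape(region.shape), out=region)
        truth.midlines[spec.name] = {"points": samples, "arcs": arcs,
                                     "radii": radii}
    if psf_sigma_um > 0:
        img = gaussian_filter(img, [psf_sigma_um / s
                                    for s in geometry.spacing_zyx])
    out = _apply_noise(img, noise, seed, 255)
    stack = ImageStack(out.astype(np.uint8), geometry, 8, "morphology")
    return stack, truth


def render_signal(puncta: list[PunctumSpec], truth: GroundTruth,
                  geometry: VoxelGeometry, baseline: float = 0.0,
                  noise: NoiseModel | None = None, seed: int = 0,
                  ) -> ImageStack:
    """Render the punctate signal channel for an existing morphology truth.

    The image is a sum of 3D Gaussians at the puncta positions (placed by
    arc position along their named tube, optionally offset radially), plus a
    uniform baseline, plus noise, clipped to 8 bits.
    """
    img = np.full(geometry.shape_zyx, float(baseline))
    spacing = np.array(geometry.spacing_xyz)
    extent = np.array(geometry.extent_um)
    for p in puncta:
        if p.tube not in truth.midlines:
            raise ValueError(f"punctum references unknown tube {p.tube!r}")
        m = truth.midlines[p.tube]
        center = truth.point_on_tube(p.tube, p.arc_position)
        if p.radial_offset:
            k = int(np.searchsorted(m["arcs"], p.arc_position))
            k = min(max(k, 1), len(m["arcs"]) - 1)
            tang = m["points"][k] - m["points"][k - 1]
            tang = tang / max(np.linalg.norm(tang), 1e-12)
            ref = np.array([0.0, 0.0, 1.0])
            if abs(tang @ ref) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            normal = np.cross(tang, ref)
            normal /= np.linalg.norm(normal)
            center = center + p.radial_offset * normal
        reach = 4.0 * p.sigma
        lo = np.maximum(center - reach, 0.0)
        hi = np.minimum(center + reach, extent)
        sl = tuple(slice(int(lo[k] / spacing[k]),
                         int(np.ceil(hi[k] / spacing[k])) + 1)
                   for k in (2, 1, 0))
        centers, _ = _voxel_centers(geometry, sl)
        d2 = ((centers - center) ** 2).sum(axis=-1)
        img[sl] += p.amplitude * np.exp(-d2 / (2.0 * p.sigma ** 2))
    # baseline is part of the deterministic image; NoiseModel.background adds
    # on top of it when a noise model is supplied
    out = _apply_noise(img, noise, seed, 255)
    stack = ImageStack(out.astype(np.uint8), geometry, 8, "signal")
    truth.puncta = list(puncta)
    return stack


def _tube(name, pts, radius=0.5, intensity=200.0, **kw) -> TubeSpec:
    return TubeSpec(name, tuple(map(tuple, pts)), radius, intensity, **kw)


def standard_fixtures(names: list[str] | None = None,
                      seed: int = 12345) -> dict[str, Fixture]:
    """Deterministic suite of named phantoms used throughout the test suite.

    Members: ``straight_tube``, ``curved_tube``, ``tapering_cone``,
    ``y_tree``, ``tree_with_spur`` (3 μm spur), ``gap_tube`` (2-voxel axial
    gap), ``stellate`` (5 primary dendrites), ``crowded_field`` (distractor
    tubes from other cells). Regeneration with the same seed is
    byte-identical.
    """
    builders = {
        "straight_tube": _fx_straight,
        "curved_tube": _fx_curved,
        "tapering_cone": _fx_cone,
        "y_tree": _fx_ytree,
        "tree_with_spur": _fx_spur,
        "gap_tube": _fx_gap,
        "stellate": _fx_stellate,
        "crowded_field": _fx_crowded,
    }
    names = names or list(builders)
    return {n: builders[n](seed) for n in names}


def _fx_straight(seed: int) -> Fixture:
    geom = fine_geometry((22.0, 4.0, 4.0))
    tube = _tube("trunk", [(1.0, 2.0, 2.0), (21.0, 2.0, 2.0)], radius=0.5)
    stack, truth = render_morphology([tube], geom)
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 2, 0, 1
    return Fixture("straight_tube", stack, truth,
                   SeedPoint(1.0 / geom.dx, 2.0 / geom.dy, 2.0 / geom.dz))


def _fx_curved(seed: int) -> Fixture:
    geom = fine_geometry((20.0, 10.0, 4.0))
    t = np.linspace(0, 1, 40)
    pts = np.stack([1.0 + 18.0 * t, 5.0 + 3.5 * np.sin(np.pi * t),
                    2.0 + 0.0 * t], axis=1)
    stack, truth = render_morphology([_tube("arc", pts, radius=0.5)], geom)
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 2, 0, 1
    return Fixture("curved_tube", stack, truth,
                   SeedPoint(1.0 / geom.dx, 5.0 / geom.dy, 2.0 / geom.dz))


def _fx_cone(seed: int) -> Fixture:
    geom = fine_geometry((23.0, 5.6, 5.6))
    tube = _tube("cone", [(1.5, 2.8, 2.8), (21.5, 2.8, 2.8)],
                 radius=(1.2, 0.35))
    stack, truth = render_morphology([tube], geom)
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 2, 0, 1
    return Fixture("tapering_cone", stack, truth,
                   SeedPoint(1.5 / geom.dx, 2.8 / geom.dy, 2.8 / geom.dz))


def _ytree_specs():
    soma = (2.0, 10.0, 2.5)
    fork = (14.0, 10.0, 2.5)
    return [
        _tube("stem", [soma, fork], radius=0.6),
        _tube("upper", [fork, (23.5, 16.0, 2.5)], radius=0.5),
        _tube("lower", [fork, (22.0, 4.5, 2.5)], radius=0.5),
    ]


def _fx_ytree(seed: int) -> Fixture:
    geom = fine_geometry((25.0, 20.0, 5.0))
    stack, truth = render_morphology(_ytree_specs(), geom)
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 3, 1, 1
    return Fixture("y_tree", stack, truth,
                   SeedPoint(2.0 / geom.dx, 10.0 / geom.dy, 2.5 / geom.dz))


def _fx_spur(seed: int) -> Fixture:
    geom = fine_geometry((25.0, 20.0, 5.0))
    specs = _ytree_specs() + [
        _tube("spur", [(8.0, 10.0, 2.5), (8.0, 13.0, 2.5)], radius=0.4)]
    stack, truth = render_morphology(specs, geom)
    # after 5 um pruning the 3 um spur disappears: same topology as y_tree
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 3, 1, 1
    return Fixture("tree_with_spur", stack, truth,
                   SeedPoint(2.0 / geom.dx, 10.0 / geom.dy, 2.5 / geom.dz))


def _fx_gap(seed: int) -> Fixture:
    geom = fine_geometry((22.0, 4.0, 4.0))
    gap = 2 * geom.dx  # 2-voxel axial gap at the midpoint
    mid = 11.0
    specs = [
        _tube("left", [(1.0, 2.0, 2.0), (mid - gap / 2, 2.0, 2.0)], radius=0.4),
        _tube("right", [(mid + gap / 2, 2.0, 2.0), (21.0, 2.0, 2.0)], radius=0.4),
    ]
    noise = NoiseModel(gaussian_sigma=6.0, poisson=True, background=12.0)
    stack, truth = render_morphology(specs, geom, noise=noise, seed=seed)
    # analysis-side truth: the intended midline spans the gap
    full = _resample_polyline(np.array([(1.0, 2.0, 2.0), (21.0, 2.0, 2.0)]),
                              geom.dx / 3)
    truth.midlines["full"] = {"points": full[0], "arcs": full[1],
                              "radii": np.full(len(full[1]), 0.4)}
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 2, 0, 1
    return Fixture("gap_tube", stack, truth,
                   SeedPoint(1.0 / geom.dx, 2.0 / geom.dy, 2.0 / geom.dz))


def _fx_stellate(seed: int) -> Fixture:
    geom = coarse_geometry((40.0, 40.0, 6.0))
    center = np.array([20.0, 20.0, 3.0])
    specs = []
    for i, ang in enumerate(np.deg2rad([0, 72, 144, 216, 288])):
        tip = center + 16.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        specs.append(_tube(f"ray{i}", [center, tip], radius=0.5))
    stack, truth = render_morphology(specs, geom)
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 5, 0, 5
    return Fixture("stellate", stack, truth,
                   SeedPoint(20.0 / geom.dx, 20.0 / geom.dy, 3.0 / geom.dz))


def _fx_crowded(seed: int) -> Fixture:
    geom = coarse_geometry((40.0, 40.0, 8.0))
    center = np.array([20.0, 20.0, 4.0])
    specs = []
    for i, ang in enumerate(np.deg2rad([20, 140, 260])):
        tip = center + 15.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        specs.append(_tube(f"ray{i}", [center, tip], radius=0.5))
    rng = np.random.default_rng(seed + 1)
    for i in range(6):  # distractor processes from other cells
        a = rng.uniform(0, 2 * np.pi)
        p0 = np.array([rng.uniform(5, 35), rng.uniform(5, 35),
                       rng.uniform(1.5, 6.5)])
        p1 = p0 + rng.uniform(6, 12) * np.array([np.cos(a), np.sin(a), 0.0])
        p1 = np.clip(p1, [1, 1, 1], [39, 39, 7])
        specs.append(_tube(f"distractor{i}", [p0, p1], radius=0.3,
                           intensity=140.0))
    noise = NoiseModel(gaussian_sigma=5.0, poisson=True, background=10.0)
    stack, truth = render_morphology(specs, geom, noise=noise, seed=seed)
    truth.n_endpoints, truth.n_bifurcations, truth.n_root_edges = 3, 0, 3
    return Fixture("crowded_field", stack, truth,
                   SeedPoint(20.0 / geom.dx, 20.0 / geom.dy, 4.0 / geom.dz))
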