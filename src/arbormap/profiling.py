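"""Fluorescence intensity profiling along the dendritic skeleton.

The skeleton reconstructed from the morphology channel supplies 3D sample
positions (compartments); because both channels come from the same imaging
session, each compartment addresses the same topographical location in the
signal stack. For every compartment four datasets are computed:

1. *point value* — the signal gray level at the compartment voxel;
2. *mean value* — the mean over a spherical volumetric window (default
   diameter 6 μm) centered on the compartment, with the sphere scaled by the
   actual voxel dimensions;
3. *max value* — the maximum over the same window;
4. *radius* — the dendrite radius carried over from the morphology channel.

Profiles for a chosen walk of dendritic segments are written as tab-separated
text (one file per dendrite, directly importable as Igor-style waves) and the
whole arbor with its per-compartment values as an ASCII AmiraMesh
SpatialGraph for 3D visualization. Profiles can be normalized against the
identically profiled raw morphology channel to correct depth or shadowing
effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageStack, VoxelGeometry
from .skeletonize import Compartment, SkeletonEdge, SkeletonGraph

__all__ = [
    "SphereWindow",
    "ProfileRecord",
    "DendritePath",
    "profile_graph",
    "select_path",
    "normalize_profile",
    "write_profile_txt",
    "read_profile_txt",
    "write_spatial_graph",
    "read_spatial_graph",
]

log = logging.getLogger(__name__)

_DATASETS = ("point", "mean", "max", "norm_point", "norm_mean")


@dataclass(frozen=True)
class SphereWindow:
    """Spherical averaging window, scaled by the actual voxel dimensions.

    A voxel belongs to the window iff the physical distance between its
    center and the compartment's voxel center is at most ``diameter / 2``.
    """

    diameter: float = 6.0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    def offsets(self, geometry: VoxelGeometry) -> np.ndarray:
        """Integer (z, y, x) voxel offsets inside the sphere."""
        r = self.diameter / 2.0
        nz = int(np.floor(r / geometry.dz))
        ny = int(np.floor(r / geometry.dy))
        nx = int(np.floor(r / geometry.dx))
        oz, oy, ox = np.mgrid[-nz:nz + 1, -ny:ny + 1, -nx:nx + 1]
        d2 = ((oz * geometry.dz) ** 2 + (oy * geometry.dy) ** 2
              + (ox * geometry.dx) ** 2)
        keep = d2 <= r * r
        return np.stack([oz[keep], oy[keep], ox[keep]], axis=1)


@dataclass
class ProfileRecord:
    """Per-compartment measurement row.

    Invariants: ``point_value <= max_value`` and ``mean_value <= max_value``
    (the compartment's own voxel is inside its window). ``flagged`` marks
    records whose normalization denominator fell at or below epsilon.
    """

    arc_length: float
    point_value: float
    mean_value: float
    max_value: float
    radius: float
    normalized_point: float | None = None
    normalized_mean: float | None = None
    flagged: bool = False


@dataclass
class DendritePath:
    """An ordered walk of dendritic segments with concatenated records."""

    edge_names: list[str]
    compartments: list[Compartment] = field(default_factory=list)
    records: list[ProfileRecord] = field(default_factory=list)


def _compartment_voxel(comp: Compartment, geometry: VoxelGeometry,
                       ) -> tuple[int, int, int]:
    """Voxel (z, y, x) of a compartment, from index or physical position."""
    if comp.voxel_index is not None:
        x, y, z = comp.voxel_index
    else:
        x = int(round(comp.position[0] / geometry.dx))
        y = int(round(comp.position[1] / geometry.dy))
        z = int(round(comp.position[2] / geometry.dz))
    return (z, y, x)


def profile_graph(graph: SkeletonGraph, signal: ImageStack,
                  window: SphereWindow | None = None,
                  ) -> dict[str, list[ProfileRecord]]:
    """Measure point / mean-in-sphere / max-in-sphere for every compartment.

    Scans the graph one dendritic segment at a time and registers the signal
    stack at each compartment position. The window is clipped at image
    borders — only in-bounds voxels enter the mean. Returns one record list
    per edge name, aligned with that edge's compartments.
    """
    window = window or SphereWindow()
    geom = signal.geometry
    if graph.geometry is not None and graph.geometry != geom:
        raise ValueError(
            f"skeleton was built on geometry {graph.geometry} but the signal "
            f"stack has {geom}; both channels must come from the same "
            f"imaging session")
    offsets = window.offsets(geom)
    data = signal.voxels
    shape = np.array(data.shape)
    out: dict[str, list[ProfileRecord]] = {}
    for edge in graph.edges:
        records = []
        for comp in edge.compartments:
            center = np.array(_compartment_voxel(comp, geom))
            if (center < 0).any() or (center >= shape).any():
                raise ValueError(f"compartment voxel {tuple(center[::-1])} "
                                 f"outside the signal stack")
            vox = center + offsets
            lo_ok = (center - np.abs(offsets).max(axis=0) >= 0).all()
            hi_ok = (center + np.abs(offsets).max(axis=0) < shape).all()
            if not (lo_ok and hi_ok):
                inb = ((vox >= 0) & (vox < shape)).all(axis=1)
                vox = vox[inb]
            vals = data[vox[:, 0], vox[:, 1], vox[:, 2]]
            records.append(ProfileRecord(
                arc_length=comp.arc_length,
                point_value=float(data[tuple(center)]),
                mean_value=float(vals.mean()),
                max_value=float(vals.max()),
                radius=comp.radius,
            ))
        out[edge.name] = records
    return out


def select_path(graph: SkeletonGraph, edge_sequence: list[str],
                records: dict[str, list[ProfileRecord]] | None = None,
                soma_exclusion_radius: float = 0.0) -> DendritePath:
    """Concatenate a sequence of adjacent dendritic segments into one path.

    Consecutive edges must share a graph node; arc length is cumulative from
    the path start and continuous across joins (the shared junction
    compartment is kept once). Records with arc length below
    ``soma_exclusion_radius`` are dropped — the first few μm of a
    soma-seeded dendrite actually sample the cell body and should be
    excluded from analysis.
    """
    emap = graph.edge_map()
    for name in edge_sequence:
        if name not in emap:
            raise KeyError(f"unknown edge {name!r}; valid edges: "
                           f"{sorted(emap)}")
    if not edge_sequence:
        raise ValueError("edge_sequence is empty")
    for a, b in zip(edge_sequence, edge_sequence[1:]):
        ea, eb = emap[a], emap[b]
        if not ({ea.proximal, ea.distal} & {eb.proximal, eb.distal}):
            raise ValueError(f"edges {a!r} and {b!r} are not adjacent in the "
                             f"graph (no shared node)")

    comps: list[Compartment] = []
    recs: list[ProfileRecord] = []
    for i, name in enumerate(edge_sequence):
        edge = emap[name]
        er = records.get(name) if records is not None else None
        if er is not None and len(er) != len(edge.compartments):
            raise ValueError(f"records for {name!r} do not match its "
                             f"compartment count")
        chain = list(zip(edge.compartments,
                         er if er is not None else [None] * len(edge.compartments)))
        if i > 0 and comps:
            # orient so the shared junction comes first, then drop it
            prev_pos = comps[-1].position
            d_first = np.linalg.norm(chain[0][0].position - prev_pos)
            d_last = np.linalg.norm(chain[-1][0].position - prev_pos)
            if d_last < d_first:
                chain = chain[::-1]
            chain = chain[1:]
        for comp, rec in chain:
            comps.append(comp)
            recs.append(rec)

    # cumulative arc length along the walk
    arc = 0.0
    path_records: list[ProfileRecord] = []
    prev = None
    for comp, rec in zip(comps, recs):
        if prev is not None:
            arc += float(np.linalg.norm(comp.position - prev.position))
        if rec is not None:
            r = ProfileRecord(arc, rec.point_value, rec.mean_value,
                              rec.max_value, rec.radius,
                              rec.normalized_point, rec.normalized_mean,
                              rec.flagged)
        else:
            r = ProfileRecord(arc, np.nan, np.nan, np.nan, comp.radius)
        path_records.append(r)
        prev = comp
    keep = [i for i, r in enumerate(path_records)
            if r.arc_length >= soma_exclusion_radius]
    return DendritePath(list(edge_sequence),
                        [comps[i] for i in keep],
                        [path_records[i] for i in keep])


def normalize_profile(signal_records: list[ProfileRecord],
                      morphology_records: list[ProfileRecord],
                      epsilon: float = 1.0) -> list[ProfileRecord]:
    """Divide signal records by identically profiled morphology records.

    ``normalized_point = point_sig / max(point_morph, epsilon)`` and likewise
    for the mean; records where the morphology value is at or below epsilon
    are flagged (the denominator is clamped, not dropped). Both lists must
    come from the same path, compartment for compartment.
    """
    if len(signal_records) != len(morphology_records):
        raise ValueError(
            f"record lists differ in length ({len(signal_records)} vs "
            f"{len(morphology_records)}); both channels must be profiled on "
            f"the same path")
    out = []
    for s, m in zip(signal_records, morphology_records):
        if abs(s.arc_length - m.arc_length) > 1e-6:
            raise ValueError("record lists are not compartment-aligned "
                             f"(arc {s.arc_length} vs {m.arc_length})")
        flag = m.point_value <= epsilon or m.mean_value <= epsilon
        out.append(ProfileRecord(
            s.arc_length, s.point_value, s.mean_value, s.max_value, s.radius,
            normalized_point=s.point_value / max(m.point_value, epsilon),
            normalized_mean=s.mean_value / max(m.mean_value, epsilon),
            flagged=flag,
        ))
    return out


def write_profile_txt(path_data: DendritePath, path) -> None:
    """Write one dendrite path as a tab-separated text file.

    One header line, one row per compartment; columns ``arc_um point mean
    max radius_um`` plus ``norm_point norm_mean`` when normalization was
    applied. The format loads directly as delimited waves in Igor-style
    analysis software.
    """
    if not path_data.records:
        raise ValueError("path has no records to write")
    normalized = all(r.normalized_point is not None for r in path_data.records)
    cols = ["arc_um", "point", "mean", "max", "radius_um"]
    if normalized:
        cols += ["norm_point", "norm_mean"]
    lines = ["\t".join(cols)]
    for r in path_data.records:
        row = [f"{r.arc_length:.6g}", f"{r.point_value:.6g}",
               f"{r.mean_value:.9g}", f"{r.max_value:.6g}", f"{r.radius:.6g}"]
        if normalized:
            row += [f"{r.normalized_point:.9g}", f"{r.normalized_mean:.9g}"]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_profile_txt(path) -> DendritePath:
    """Re-read a profile text file written by :func:`write_profile_txt`."""
    with open(path) as fh:
        header = fh.readline().split()
        rows = [list(map(float, line.split())) for line in fh if line.strip()]
    normalized = "norm_point" in header
    records = []
    for row in rows:
        rec = ProfileRecord(row[0], row[1], row[2], row[3], row[4])
        if normalized:
            rec.normalized_point, rec.normalized_mean = row[5], row[6]
        records.append(rec)
    return DendritePath([], [], records)


def write_spatial_graph(graph: SkeletonGraph,
                        records: dict[str, list[ProfileRecord]],
                        path, mode: str = "morphology",
                        dataset: str = "point") -> None:
    """Write the arbor and its measured values as an ASCII AmiraMesh
    SpatialGraph.

    ``mode='morphology'`` stores the true per-compartment radius in the
    thickness field (a morphologically realistic skeleton); ``'filament'``
    stores a constant half-voxel thickness (a wire-frame that makes the
    intensity color map easier to read). ``dataset`` selects which measured
    quantity fills the intensity field (point by default, or mean / max /
    norm_point / norm_mean).
    """
    if mode not in ("morphology", "filament"):
        raise ValueError(f"unknown mode {mode!r}")
    if dataset not in _DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}; choose from {_DATASETS}")
    for edge in graph.edges:
        if edge.name not in records:
            raise ValueError(f"no records for edge {edge.name!r}")
        if len(records[edge.name]) != len(edge.compartments):
            raise ValueError(f"records for {edge.name!r} do not cover its "
                             f"compartments")

    node_ids = sorted(graph.nodes)
    node_row = {nid: i for i, nid in enumerate(node_ids)}
    if graph.geometry is not None:
        half_voxel = 0.5 * min(graph.geometry.spacing_xyz)
    else:
        half_voxel = 0.5

    def value(rec: ProfileRecord) -> float:
        v = {"point": rec.point_value, "mean": rec.mean_value,
             "max": rec.max_value, "norm_point": rec.normalized_point,
             "norm_mean": rec.normalized_mean}[dataset]
        if v is None:
            raise ValueError(f"dataset {dataset!r} requested but records are "
                             f"not normalized")
        return v

    points, thickness, intensity, edge_rows, n_points = [], [], [], [], []
    for edge in graph.edges:
        edge_rows.append((node_row[edge.proximal], node_row[edge.distal]))
        n_points.append(len(edge.compartments))
        for comp, rec in zip(edge.compartments, records[edge.name]):
            points.append(comp.position)
            thickness.append(comp.radius if mode == "morphology" else half_voxel)
            intensity.append(value(rec))

    lines = ["# AmiraMesh 3D ASCII 2.0",
             "",
             f"define VERTEX {len(node_ids)}",
             f"define EDGE {len(graph.edges)}",
             f"define POINT {len(points)}",
             "",
             "Parameters {",
             '    ContentType "HxSpatialGraph"',
             "}",
             "",
             "VERTEX { float[3] VertexCoordinates } @1",
             "EDGE { int[2] EdgeConnectivity } @2",
             "EDGE { int NumEdgePoints } @3",
             "POINT { float[3] EdgePointCoordinates } @4",
             "POINT { float thickness } @5",
             "POINT { float intensity } @6",
             "",
             "@1"]
    for nid in node_ids:
        p = graph.nodes[nid].position
        lines.append(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}")
    lines += ["", "@2"]
    lines += [f"{a} {b}" for a, b in edge_rows]
    lines += ["", "@3"]
    lines += [str(n) for n in n_points]
    lines += ["", "@4"]
    lines += [f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}" for p in points]
    lines += ["", "@5"]
    lines += [f"{t:.6g}" for t in thickness]
    lines += ["", "@6"]
    lines += [f"{v:.6g}" for v in intensity]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_spatial_graph(path) -> dict:
    """Parse an ASCII AmiraMesh SpatialGraph written by
    :func:`write_spatial_graph`.

    Returns a dict with ``vertices`` (V, 3), ``edges`` (E, 2),
    ``n_edge_points`` (E,), ``points`` (P, 3), ``thickness`` (P,), and
    ``intensity`` (P,) arrays.
    """
    blocks: dict[str, list[list[float]]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("@") and len(line) <= 3:
                current = line
                blocks[current] = []
            elif current and line and not line.startswith(("#", "define",
                                                           "Parameters", "}",
                                                           '"')):
                try:
                    blocks[current].append([float(v) for v in line.split()])
                except ValueError:
                    current = None
    return {
        "vertices": np.array(blocks["@1"], dtype=float),
        "edges": np.array(blocks["@2"], dtype=int),
        "n_edge_points": np.array(blocks["@3"], dtype=int).ravel(),
        "points": np.array(blocks["@4"], dtype=float),
        "thickness": np.array(blocks["@5"], dtype=float).ravel(),
        "intensity": np.array(blocks["@6"], dtype=float).ravel(),
    }
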