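"""High-level orchestration: reconstruct and profile runs with a manifest.

These functions chain the library stages the way an analysis session does —
filter → segment (× rounds) → skeletonize → hoc for the morphology channel,
then hoc + signal stack → per-compartment profiles → text/SpatialGraph
files — writing every intermediate for inspection and a machine-readable
manifest of all parameters so runs across experimental conditions stay
comparable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .filtering import DiffusionParams, filter_segment_rounds
from .image_io import ImageStack, VoxelGeometry, read_stack, write_stack
from .profiling import (DendritePath, ProfileRecord, SphereWindow,
                        normalize_profile, profile_graph, select_path,
                        write_profile_txt, write_spatial_graph)
from .segmentation import SegmentationMask, SegmentationParams, segment, \
    remove_small_components
from .skeletonize import (SeedPoint, SkeletonGraph, build_graph,
                          estimate_radius, extract_midline, read_hoc,
                          write_hoc)

__all__ = ["PipelineConfig", "run_reconstruct", "run_profile"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All parameters of a reconstruction/profiling run.

    Units: voxel spacings and every length in μm; seed coordinates in
    0-based pixels; intensities in gray levels.
    """

    morphology_path: str | None = None
    signal_path: str | None = None
    geometry: VoxelGeometry | None = None
    seed_point: SeedPoint | None = None
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    window: SphereWindow = field(default_factory=SphereWindow)
    rounds: int = 2
    min_branch_length: float = 5.0
    snap_radius_um: float = 10.0
    soma_exclusion_radius: float = 0.0
    output_dir: str = "."
    rng_seed: int = 0

    def manifest(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: enc(getattr(v, f.name))
                        for f in dataclasses.fields(v)}
            return v
        d = enc(self)
        d["version"] = __version__
        return d


def _write_manifest(config: PipelineConfig, out_dir: Path, stage: str,
                    extra: dict) -> None:
    manifest = config.manifest()
    manifest["stage"] = stage
    manifest.update(extra)
    with open(out_dir / f"{stage}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_reconstruct(config: PipelineConfig,
                    morphology: ImageStack | None = None,
                    ) -> tuple[SkeletonGraph, Path]:
    """Morphology stack → filtered/segmented mask → skeleton → hoc file.

    Returns the radius-annotated graph and the hoc path. Intermediate
    filtered stacks and masks are written to the output directory.
    """
    if config.geometry is None or config.seed_point is None:
        raise ValueError("reconstruction needs a voxel geometry and a soma "
                         "seed point")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if morphology is None:
        if config.morphology_path is None:
            raise ValueError("no morphology stack given")
        morphology = read_stack(config.morphology_path, config.geometry,
                                "morphology")
    t0 = time.perf_counter()
    intermediates: list = []
    mask = filter_segment_rounds(morphology, config.diffusion,
                                 config.segmentation, config.rounds,
                                 intermediates)
    for i, (filt, m) in enumerate(intermediates, start=1):
        write_stack(filt, out_dir / f"round{i}_filtered.tif")
        write_stack(filt.with_voxels(m.voxels.astype(np.uint8) * 255),
                    out_dir / f"round{i}_mask.tif")
    mask = remove_small_components(mask, config.segmentation)
    log.info("filter+segment x%d: %.1f s, %d components kept", config.rounds,
             time.perf_counter() - t0, mask.n_components)

    t1 = time.perf_counter()
    midline = extract_midline(mask)
    graph = build_graph(midline, config.seed_point, config.geometry,
                        config.min_branch_length, config.snap_radius_um,
                        mask=mask)
    graph = estimate_radius(graph, mask)
    log.info("skeletonization: %.1f s, %d edges, %d endpoints, %d bifurcations",
             time.perf_counter() - t1, len(graph.edges), graph.n_endpoints,
             graph.n_bifurcations)
    hoc_path = out_dir / "skeleton.hoc"
    write_hoc(graph, hoc_path)
    _write_manifest(config, out_dir, "reconstruct", {
        "n_edges": len(graph.edges),
        "n_endpoints": graph.n_endpoints,
        "n_bifurcations": graph.n_bifurcations,
        "n_components_after_cleanup": mask.n_components,
    })
    return graph, hoc_path


def run_profile(config: PipelineConfig, hoc_path=None,
                signal: ImageStack | None = None,
                path_edges: list[str] | None = None,
                normalize_against: ImageStack | None = None,
                dataset: str = "point") -> dict:
    """hoc + signal stack → per-compartment profiles → txt + SpatialGraph.

    Profiles every dendritic segment; if ``path_edges`` is given, writes one
    txt file for that walk, otherwise one per root-to-tip segment name.
    ``normalize_against`` (the raw, unfiltered morphology stack) adds
    normalized columns. Returns the record dict keyed by edge name.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if hoc_path is None:
        hoc_path = out_dir / "skeleton.hoc"
    graph = read_hoc(hoc_path)
    graph.geometry = config.geometry
    if signal is None:
        if config.signal_path is None or config.geometry is None:
            raise ValueError("profiling needs a signal stack and geometry")
        signal = read_stack(config.signal_path, config.geometry, "signal")
    records = profile_graph(graph, signal, config.window)
    morph_records = None
    if normalize_against is not None:
        morph_records = profile_graph(graph, normalize_against, config.window)

    def finish(names: list[str], stem: str) -> DendritePath:
        path = select_path(graph, names, records,
                           config.soma_exclusion_radius)
        if morph_records is not None:
            mpath = select_path(graph, names, morph_records,
                                config.soma_exclusion_radius)
            path.records = normalize_profile(path.records, mpath.records)
        write_profile_txt(path, out_dir / f"{stem}.txt")
        return path

    if path_edges:
        finish(path_edges, "path_" + "_".join(
            n.replace("[", "").replace("]", "") for n in path_edges))
    else:
        for edge in graph.edges:
            finish([edge.name], edge.name.replace("[", "").replace("]", ""))
    if morph_records is not None:
        for name in records:
            records[name] = normalize_profile(records[name],
                                              morph_records[name])
    for mode in ("morphology", "filament"):
        write_spatial_graph(graph, records,
                            out_dir / f"spatialgraph_{mode}.am", mode,
                            dataset)
    _write_manifest(config, out_dir, "profile", {
        "n_edges": len(graph.edges),
        "dataset": dataset,
        "normalized": morph_records is not None,
    })
    return records
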