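"""End-to-end orchestration: ingest -> segment -> track -> time series
-> deformation metrics -> spatial graph, with reproducible outputs.

``run_all`` is the library entry point the command-line interface wraps.
All stochastic steps (synthetic noise, GP fitting, random sampling)
consume the single configured seed, so a rerun with the same config and
seed reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import frames_io, mechanics, segment, spatial_analysis, track, tseries
from .frames_io import FrameStack

logger = logging.getLogger("sarcokinetics")

__all__ = ["RunConfig", "PipelineResult", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults match the recommended values for
    fluorescence movies of z-disc--labeled cardiomyocytes."""

    folder_name: str
    gaussian_filter_size: float = 1.0
    tp_depth: float = 4.0
    memory: int = 5
    keep_thresh: float = 0.75
    min_presence: float = 0.10
    rng_seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.gaussian_filter_size <= 0:
            raise ValueError("gaussian_filter_size must be > 0")
        if not 0 < self.keep_thresh <= 1:
            raise ValueError("keep_thresh must be in (0, 1]")
        if not 0 <= self.min_presence < 1:
            raise ValueError("min_presence must be in [0, 1)")


@dataclass
class PipelineResult:
    """In-memory results of a full pipeline run."""

    stack: FrameStack
    zdiscs: list
    sarcomeres: list
    zdisc_tracks: list
    sarc_tracks: list
    series: list
    metrics: dict = field(default_factory=dict)
    deformation: list = field(default_factory=list)
    graph: object = None


def run_all(config: RunConfig, stack: FrameStack | None = None) -> PipelineResult:
    """Run the whole pipeline and write tables, metrics, and a manifest.

    ``stack`` may be passed directly (e.g. from the synthetic generator);
    otherwise ``config.folder_name`` is loaded as a movie. Partial
    outputs are preserved if a later stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if stack is None:
        logger.info("stage ingest: %s", config.folder_name)
        stack = frames_io.load_movie(config.folder_name)

    logger.info("stage segment: %d frames", stack.frame_count)
    zdiscs, sarcs = segment.segment_movie(
        stack.frames, config.gaussian_filter_size
    )
    _write_detections(out, zdiscs, sarcs)

    logger.info("stage track")
    params = track.TrackingParams(tp_depth=config.tp_depth, memory=config.memory)
    zdisc_tracks = track.track_movie(zdiscs, params, config.min_presence)
    sarc_tracks = track.track_movie(sarcs, params, config.min_presence)
    _write_tracks(out / "zdisc_tracks.csv", zdisc_tracks)
    _write_tracks(out / "sarcomere_tracks.csv", sarc_tracks)

    logger.info("stage timeseries")
    series = tseries.build_timeseries(
        sarc_tracks,
        sarcs,
        tseries.TimeSeriesParams(keep_thresh=config.keep_thresh),
        seed=config.rng_seed,
    )
    _write_series(out, series)

    result = PipelineResult(
        stack=stack,
        zdiscs=zdiscs,
        sarcomeres=sarcs,
        zdisc_tracks=zdisc_tracks,
        sarc_tracks=sarc_tracks,
        series=series,
    )

    if len(series) >= 3:
        logger.info("stage mechanics")
        positions = np.stack([s.position for s in series], axis=1)
        y_series = np.asarray([s.y for s in series])
        angles = np.asarray([s.angle for s in series]).T  # (n_frames, m)
        orientations = np.stack([np.cos(angles), np.sin(angles)], axis=2)
        result.metrics = mechanics.compute_metrics(positions, y_series, orientations)
        ref = result.metrics["reference_frame"]
        result.deformation = mechanics.compute_F_series(positions, ref)
        _write_deformation(out / "deformation.csv", result.deformation)
        (out / "metrics.json").write_text(json.dumps(result.metrics, indent=2))
    else:
        logger.warning("fewer than 3 reconstructed series; skipping mechanics")

    logger.info("stage spatial graph")
    result.graph = spatial_analysis.build_spatial_graph(
        zdisc_tracks, sarc_tracks, zdiscs, sarcs
    )
    _write_graph(out, result.graph)

    manifest = {
        "config": asdict(config),
        "n_frames": stack.frame_count,
        "n_zdisc_tracks": len(zdisc_tracks),
        "n_sarc_tracks": len(sarc_tracks),
        "n_series": len(series),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def _write_detections(out: Path, zdiscs, sarcs) -> None:
    with open(out / "zdiscs.csv", "w") as fh:
        fh.write("frame,id,x,y,length\n")
        for frame in zdiscs:
            for d in frame:
                fh.write(
                    f"{d.frame_index},{d.local_id},{d.center[0]:.4f},"
                    f"{d.center[1]:.4f},{d.length:.4f}\n"
                )
    with open(out / "sarcomeres.csv", "w") as fh:
        fh.write("frame,id,disc_a,disc_b,length,width,angle\n")
        for frame in sarcs:
            for s in frame:
                fh.write(
                    f"{s.frame_index},{s.local_id},{s.zdisc_ids[0]},"
                    f"{s.zdisc_ids[1]},{s.length:.4f},{s.width:.4f},{s.angle:.6f}\n"
                )


def _write_tracks(path: Path, tracks) -> None:
    with open(path, "w") as fh:
        fh.write("global_id,frame,x,y,local_id\n")
        for tr in tracks:
            for f in sorted(tr.detections):
                p = tr.positions[f]
                fh.write(f"{tr.global_id},{f},{p[0]:.4f},{p[1]:.4f},{tr.detections[f]}\n")


def _write_series(out: Path, series) -> None:
    # one file per quantity; rows = tracked sarcomeres, columns = frames
    if not series:
        return
    quantities = {
        "length": lambda s: s.length,
        "normalized_length": lambda s: s.y,
        "width": lambda s: s.width,
        "angle": lambda s: s.angle,
        "position_x": lambda s: s.position[:, 0],
        "position_y": lambda s: s.position[:, 1],
    }
    for name, get in quantities.items():
        arr = np.asarray([get(s) for s in series])
        ids = np.asarray([s.global_id for s in series])[:, None]
        np.savetxt(
            out / f"timeseries_{name}.csv",
            np.hstack([ids, arr]),
            delimiter=",",
            header="global_id," + ",".join(str(t) for t in range(arr.shape[1])),
            comments="",
        )


def _write_deformation(path: Path, states) -> None:
    with open(path, "w") as fh:
        fh.write("frame,F00,F01,F10,F11,lambda1,lambda2,J\n")
        for t, st in enumerate(states):
            F = st.F
            fh.write(
                f"{t},{F[0,0]:.8f},{F[0,1]:.8f},{F[1,0]:.8f},{F[1,1]:.8f},"
                f"{st.lambdas[0]:.8f},{st.lambdas[1]:.8f},{st.J:.8f}\n"
            )


def _write_graph(out: Path, graph) -> None:
    import networkx as nx

    g = graph.copy()
    for _, data in g.nodes(data=True):
        pos = data.pop("position")
        data["x"], data["y"] = float(pos[0]), float(pos[1])
    for _, _, data in g.edges(data=True):
        data["sarc_ids"] = ",".join(str(i) for i in sorted(data["sarc_ids"]))
    nx.write_graphml(g, out / "spatial_graph.graphml")
    with open(out / "spatial_graph_edges.csv", "w") as fh:
        fh.write("node_a,node_b,weight,mean_angle,sarc_ids\n")
        for a, b, data in g.edges(data=True):
            fh.write(
                f"{a},{b},{data['weight']},{data['mean_angle']:.6f},"
                f"\"{data['sarc_ids']}\"\n"
            )
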