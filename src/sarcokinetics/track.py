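"""Cross-frame identity assignment for z-discs and sarcomeres.

Frame-to-frame linking follows the Crocker–Grier philosophy: between
consecutive frames the assignment minimizing total squared displacement
is solved (Hungarian algorithm) over the candidate pairs whose
displacement does not exceed ``tp_depth`` pixels. A track that goes
unmatched may be reacquired for up to ``memory`` frames; during a gap
the admissible radius scales with the number of elapsed frames, keeping
the per-frame displacement bound consistent.

Detections are anything exposing a 2D ``center``; z-discs and
sarcomeres are tracked independently. After linking, tracks present in
more than ``min_presence`` (default 10%) of the movie receive stable
global IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["TrackingParams", "Track", "link_frames", "filter_tracks", "track_movie"]


@dataclass(frozen=True)
class TrackingParams:
    """``tp_depth``: max displacement (pixels) per frame step (default 4);
    ``memory``: frames a lost particle may be reacquired."""

    tp_depth: float = 4.0
    memory: int = 5

    def __post_init__(self) -> None:
        if self.tp_depth <= 0:
            raise ValueError("tp_depth must be > 0")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


@dataclass
class Track:
    """One tracked particle: a per-frame map to local detection ids."""

    global_id: int = -1
    detections: dict[int, int] = field(default_factory=dict)  # frame -> local id
    positions: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def first_frame(self) -> int:
        return min(self.detections)

    @property
    def last_frame(self) -> int:
        return max(self.detections)

    def presence_fraction(self, n_frames: int) -> float:
        return len(self.detections) / n_frames


def link_frames(
    detections_per_frame: list[list], params: TrackingParams | None = None
) -> list[Track]:
    """Link per-frame detections into tracks.

    ``detections_per_frame[t]`` is a list of objects with a ``center``
    attribute (or (x, y) arrays). Empty frames are tolerated; tracks
    persist through them within the memory window.
    """
    params = params or TrackingParams()
    n_frames = len(detections_per_frame)
    open_tracks: list[Track] = []  # candidates for continuation
    closed_tracks: list[Track] = []

    for t in range(n_frames):
        dets = detections_per_frame[t]
        centers = np.asarray(
            [getattr(d, "center", d) for d in dets], dtype=float
        ).reshape(-1, 2)

        # retire tracks whose gap exceeded the memory window
        still_open = []
        for tr in open_tracks:
            if t - tr.last_frame > params.memory + 1:
                closed_tracks.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        matched_det = set()
        if open_tracks and len(dets):
            last_pos = np.asarray([tr.positions[tr.last_frame] for tr in open_tracks])
            gaps = np.asarray([t - tr.last_frame for tr in open_tracks], dtype=float)
            radii = params.tp_depth * gaps  # radius scales with elapsed frames
            diff = last_pos[:, None, :] - centers[None, :, :]
            cost = np.einsum("ijk,ijk->ij", diff, diff)
            feasible = cost <= (radii[:, None] ** 2) + 1e-12
            big = 1e12
            padded = np.where(feasible, cost, big)
            rows, cols_ = linear_sum_assignment(padded)
            for i, j in zip(rows, cols_):
                if not feasible[i, j]:
                    continue
                tr = open_tracks[i]
                tr.detections[t] = getattr(dets[j], "local_id", j)
                tr.positions[t] = centers[j]
                matched_det.add(j)

        for j in range(len(dets)):
            if j in matched_det:
                continue
            tr = Track()
            tr.detections[t] = getattr(dets[j], "local_id", j)
            tr.positions[t] = centers[j]
            open_tracks.append(tr)

        # deterministic ordering of the open pool (first frame, then position)
        open_tracks.sort(
            key=lambda tr: (tr.first_frame, tuple(tr.positions[tr.first_frame]))
        )

    return closed_tracks + open_tracks


def filter_tracks(
    tracks: list[Track], n_frames: int, min_presence: float = 0.10
) -> list[Track]:
    """Keep tracks present in strictly more than ``min_presence`` of the
    movie and assign deterministic global IDs (first frame, position)."""
    kept = [t for t in tracks if t.presence_fraction(n_frames) > min_presence]
    kept.sort(key=lambda tr: (tr.first_frame, tuple(tr.positions[tr.first_frame])))
    for gid, tr in enumerate(kept):
        tr.global_id = gid
    return kept


def track_movie(
    detections_per_frame: list[list],
    params: TrackingParams | None = None,
    min_presence: float = 0.10,
) -> list[Track]:
    """Link then filter, returning globally identified tracks."""
    tracks = link_frames(detections_per_frame, params)
    return filter_tracks(tracks, len(detections_per_frame), min_presence)
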