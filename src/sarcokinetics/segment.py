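"""Per-frame z-disc detection and procedural sarcomere linking.

z-discs appear as bright elongated blobs. Detection computes the
Laplacian of the frame (negated, so bright-blob interiors give a
positive response), smooths it with a Gaussian filter, and extracts
closed iso-contours at a global threshold from Otsu's method. Because
the threshold acts on the Laplacian rather than the raw image, a single
global level suffices even under uneven background.

Sarcomeres are then linked with the ghost-point algorithm:

1. nearest-neighbor center distance for every disc;
2. ``median_neigh`` = median of those distances;
3. each disc gets two "ghost points" at ``median_neigh / 2`` along the
   perpendicular to its endpoint axis, one on each side;
4. each ghost point finds its nearest ghost point belonging to a
   different disc;
5. mutual (two-way) nearest ghost pairs become sarcomeres.

Each disc can therefore join at most two sarcomeres, one per side.
Coordinates are x = column, y = row, origin top-left, sub-pixel allowed;
angles are direction-invariant in [0, pi). Lengths are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, laplace
from scipy.spatial.distance import pdist, squareform
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "ZDisc",
    "SarcomereDetection",
    "segment_zdiscs",
    "ghost_points",
    "link_sarcomeres",
    "segment_movie",
    "visualize_segmentation",
]


@dataclass
class ZDisc:
    """One segmented z-disc contour in one frame."""

    frame_index: int
    local_id: int
    contour: np.ndarray  # (k, 2) as (x, y), closed
    center: np.ndarray  # (x, y), mean of contour points
    endpoints: np.ndarray  # (2, 2), the max-distance contour point pair
    length: float  # that maximum pairwise distance


@dataclass
class SarcomereDetection:
    """One sarcomere: a linked pair of z-discs in one frame."""

    frame_index: int
    local_id: int
    zdisc_ids: tuple[int, int]
    center: np.ndarray  # midpoint of the two disc centers
    length: float  # distance between disc centers
    width: float  # mean of the two disc lengths
    angle: float  # of the center-connecting vector, in [0, pi)


def segment_zdiscs(
    frame: np.ndarray,
    gaussian_filter_size: float = 1.0,
    frame_index: int = 0,
    min_contour_points: int = 4,
) -> list[ZDisc]:
    """Detect z-discs in one frame.

    The response is the Gaussian-smoothed negated Laplacian; contours are
    taken at the Otsu threshold of the response. Open contours (clipped
    at the border) and contours with fewer than ``min_contour_points``
    points are discarded. A constant frame yields no discs.
    """
    frame = np.asarray(frame, dtype=float)
    response = gaussian_filter(-laplace(frame), gaussian_filter_size)
    if np.ptp(response) < 1e-12:
        return []
    level = threshold_otsu(response)
    contours = measure.find_contours(response, level)
    discs: list[ZDisc] = []
    for rc in contours:
        if len(rc) < min_contour_points:
            continue
        if not np.allclose(rc[0], rc[-1]):
            continue  # open contour touching the image border
        xy = rc[:, ::-1]  # (row, col) -> (x, y)
        center = xy.mean(axis=0)
        i, j, length = _max_pairwise(xy)
        discs.append(
            ZDisc(
                frame_index=frame_index,
                local_id=len(discs),
                contour=xy,
                center=center,
                endpoints=np.asarray([xy[i], xy[j]]),
                length=float(length),
            )
        )
    return discs


def _max_pairwise(points: np.ndarray) -> tuple[int, int, float]:
    """Exact max-distance point pair; first occurrence wins ties."""
    d = squareform(pdist(points))
    flat = np.argmax(d)
    i, j = np.unravel_index(flat, d.shape)
    if i > j:
        i, j = j, i
    return int(i), int(j), float(d[i, j])


def ghost_points(discs: list[ZDisc]) -> tuple[np.ndarray, float]:
    """Two ghost points per disc at median_neigh/2 along the disc's
    perpendicular. Returns ((n_discs, 2, 2) array, median_neigh)."""
    centers = np.asarray([d.center for d in discs])
    dist = squareform(pdist(centers))
    np.fill_diagonal(dist, np.inf)
    median_neigh = float(np.median(dist.min(axis=1)))
    out = np.empty((len(discs), 2, 2))
    for i, d in enumerate(discs):
        axis = d.endpoints[1] - d.endpoints[0]
        n = np.linalg.norm(axis)
        if n < 1e-12:
            perp = np.array([1.0, 0.0])
        else:
            axis = axis / n
            perp = np.array([-axis[1], axis[0]])
        out[i, 0] = d.center + 0.5 * median_neigh * perp
        out[i, 1] = d.center - 0.5 * median_neigh * perp
    return out, median_neigh


def link_sarcomeres(discs: list[ZDisc]) -> list[SarcomereDetection]:
    """Ghost-point mutual-nearest linking of z-discs into sarcomeres.

    Nearest-neighbor ties break by smaller distance then lower disc
    local_id (index order), so the result is deterministic and invariant
    under permutations of disc ordering up to relabeling.
    """
    if len(discs) < 2:
        return []
    gp, _ = ghost_points(discs)
    flat = gp.reshape(-1, 2)  # ghost g of disc i is row 2*i + side
    owner = np.repeat(np.arange(len(discs)), 2)
    d = squareform(pdist(flat))
    # a ghost point may not match ghosts of its own disc
    same = owner[:, None] == owner[None, :]
    d[same] = np.inf
    nearest = np.argmin(d, axis=1)  # argmin takes the lowest index on ties

    pairs: set[tuple[int, int]] = set()
    for g in range(len(flat)):
        h = nearest[g]
        if nearest[h] == g:  # two-way nearest neighbor match
            a, b = int(owner[g]), int(owner[h])
            pairs.add((min(a, b), max(a, b)))

    sarcs: list[SarcomereDetection] = []
    for a, b in sorted(pairs):
        ca, cb = discs[a].center, discs[b].center
        v = cb - ca
        angle = float(np.mod(np.arctan2(v[1], v[0]), np.pi))
        sarcs.append(
            SarcomereDetection(
                frame_index=discs[a].frame_index,
                local_id=len(sarcs),
                zdisc_ids=(a, b),
                center=0.5 * (ca + cb),
                length=float(np.linalg.norm(v)),
                width=0.5 * (discs[a].length + discs[b].length),
                angle=angle,
            )
        )
    return sarcs


def segment_movie(
    frames: np.ndarray,
    gaussian_filter_size: float = 1.0,
) -> tuple[list[list[ZDisc]], list[list[SarcomereDetection]]]:
    """Run z-disc detection and sarcomere linking on every frame."""
    discs_per_frame: list[list[ZDisc]] = []
    sarcs_per_frame: list[list[SarcomereDetection]] = []
    for t, frame in enumerate(frames):
        discs = segment_zdiscs(frame, gaussian_filter_size, frame_index=t)
        discs_per_frame.append(discs)
        sarcs_per_frame.append(link_sarcomeres(discs))
    return discs_per_frame, sarcs_per_frame


def visualize_segmentation(
    frame: np.ndarray,
    zdiscs: list[ZDisc],
    sarcomeres: list[SarcomereDetection],
    out_path=None,
):
    """Overlay disc contours and sarcomere segments on a frame.

    Returns the matplotlib figure; saves a PNG when ``out_path`` given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8 * frame.shape[0] / max(frame.shape[1], 1)))
    ax.imshow(frame, cmap="gray", vmin=0, vmax=1)
    for d in zdiscs:
        ax.plot(d.contour[:, 0], d.contour[:, 1], lw=0.8, color="tab:red")
    for s in sarcomeres:
        a = zdiscs[s.zdisc_ids[0]].center
        b = zdiscs[s.zdisc_ids[1]].center
        ax.plot([a[0], b[0]], [a[1], b[1]], lw=1.0, color="tab:cyan")
    ax.set_axis_off()
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
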