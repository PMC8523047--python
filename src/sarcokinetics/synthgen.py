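"""Ground-truthed synthetic movies of contracting sarcomere chains.

A scene is a set of chains of z-discs in 3D. Each z-disc is an oriented
cylinder whose axis lies in the image plane, perpendicular to the local
chain tangent, so that after projection it appears as the familiar bright
elongated blob. Sarcomeres are the segments between consecutive discs;
each carries a prescribed fractional length change g_k(t) (0 at rest,
negative while shortening). Rendering follows a voxelize / slice /
max-project / blur / normalize pipeline, with optional multi-octave
Perlin background noise added to the 2D image.

Because the geometry is prescribed, every movie ships with its ground
truth: per-frame disc centers, per-sarcomere lengths, orientations, and
the scalar contraction metrics computed from the prescribed (not
rendered) geometry with the same formulas the analysis pipeline uses.
All lengths are in pixels and all times in frames.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

__all__ = [
    "ChainSpec",
    "ContractionProgram",
    "RenderParams",
    "SkeletonFrame",
    "GroundTruth",
    "Scene",
    "baseline_scene",
    "build_skeleton",
    "render_frame",
    "perlin_field",
    "add_perlin_noise",
    "generate_movie",
    "write_movie",
]


@dataclass(frozen=True)
class ChainSpec:
    """Geometry of one sarcomere chain.

    The chain follows a guide curve: the polyline through ``control_points``
    displaced in-plane by a sinusoid of the given ``amplitude`` and
    ``period`` (measured along the polyline) and lifted out of the focal
    plane with slope ``tilt_z`` (dz per unit arc length). Discs are placed
    sequentially along the guide curve so that consecutive disc-center
    distances equal the per-sarcomere lengths exactly.
    """

    control_points: tuple[tuple[float, float, float], ...]
    n_sarcomeres: int
    rest_length: float = 10.0
    disc_radius: float = 1.3
    disc_height: float = 5.0
    tilt_z: float = 0.0
    amplitude: float = 0.0
    period: float = 100.0

    def __post_init__(self) -> None:
        if self.n_sarcomeres < 1:
            raise ValueError("n_sarcomeres must be >= 1")
        if self.disc_radius <= 0:
            raise ValueError("disc_radius must be > 0")
        if self.rest_length <= 0:
            raise ValueError("sarcomere rest length must be > 0")
        if len(self.control_points) < 2:
            raise ValueError("need at least 2 control points")

    def guide_point(self, u: float | np.ndarray) -> np.ndarray:
        """Evaluate the guide curve at arc-length parameter ``u``.

        ``u`` is measured along the control polyline; the polyline is
        extrapolated past its last point so chains never run out of curve.
        """
        pts = np.asarray(self.control_points, dtype=float)
        seg = np.diff(pts, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        u_arr = np.atleast_1d(np.asarray(u, dtype=float))
        # piecewise-linear interpolation with linear extrapolation at the end
        idx = np.clip(np.searchsorted(cum, u_arr, side="right") - 1, 0, len(seg) - 1)
        t = (u_arr - cum[idx]) / seglen[idx]
        base = pts[idx] + t[:, None] * seg[idx]
        direction = seg[idx] / seglen[idx][:, None]
        # in-plane normal of the local polyline direction
        horiz = np.hypot(direction[:, 0], direction[:, 1])
        horiz = np.where(horiz < 1e-12, 1.0, horiz)
        normal = np.stack(
            [-direction[:, 1] / horiz, direction[:, 0] / horiz, np.zeros_like(horiz)],
            axis=1,
        )
        wave = self.amplitude * np.sin(2.0 * np.pi * u_arr / self.period)
        out = base + wave[:, None] * normal
        out[:, 2] += self.tilt_z * u_arr
        return out[0] if np.isscalar(u) else out


class ContractionProgram:
    """Per-sarcomere fractional length change g_k(t).

    Stored as an (n_frames, n_sarcomeres) array; g = 0 means rest length,
    g = -0.15 means 15% shortening. Values must stay above -1 (a sarcomere
    cannot collapse through zero length).
    """

    def __init__(self, g: np.ndarray):
        g = np.asarray(g, dtype=float)
        if g.ndim != 2:
            raise ValueError("program must be 2D: (n_frames, n_sarcomeres)")
        if np.any(g <= -1.0):
            raise ValueError("fractional length change must be > -1")
        self.g = g

    @property
    def n_frames(self) -> int:
        return self.g.shape[0]

    @property
    def n_sarcomeres(self) -> int:
        return self.g.shape[1]

    @property
    def is_homogeneous(self) -> bool:
        return bool(np.allclose(self.g, self.g[:, :1]))

    @classmethod
    def static(cls, n_frames: int, n_sarcomeres: int) -> "ContractionProgram":
        return cls(np.zeros((n_frames, n_sarcomeres)))

    @classmethod
    def beating(
        cls,
        n_frames: int,
        n_sarcomeres: int,
        peak_shortening: float = 0.15,
        period: int = 40,
        beat_frames: int = 24,
        phase_lag: float = 0.0,
    ) -> "ContractionProgram":
        """Periodic beats: a smooth sin^2 contraction pulse of
        ``beat_frames`` duration every ``period`` frames, reaching exactly
        ``-peak_shortening`` at mid-beat, with a flat rest in between.
        ``phase_lag`` (frames per sarcomere index) desynchronizes the
        chain; 0 gives a homogeneous synchronous program.
        """
        t = np.arange(n_frames, dtype=float)[:, None]
        k = np.arange(n_sarcomeres, dtype=float)[None, :]
        tau = np.mod(t - phase_lag * k, period)
        pulse = np.where(
            tau < beat_frames,
            np.sin(np.pi * tau / beat_frames) ** 2,
            0.0,
        )
        return cls(-peak_shortening * pulse)

    @classmethod
    def from_function(
        cls,
        fn: Callable[[np.ndarray, int], np.ndarray],
        n_frames: int,
        n_sarcomeres: int,
    ) -> "ContractionProgram":
        """Arbitrary user program: ``fn(frames, k)`` returns g_k(t)."""
        t = np.arange(n_frames, dtype=float)
        g = np.stack([np.asarray(fn(t, k), dtype=float) for k in range(n_sarcomeres)], axis=1)
        return cls(g)


@dataclass(frozen=True)
class RenderParams:
    """Rendering controls for the voxelize/project pipeline.

    ``xy_resolution`` is the number of voxels per pixel in x and y;
    ``z_resolution`` voxels per pixel unit in z (coarser, i.e. smaller).
    The focal slab is centered at ``focal_center`` (z, pixel units) with
    half-width ``slab_half_width`` (pixel units). ``perlin_magnitude`` is
    the noise amplitude as a fraction of peak image intensity.
    """

    shape: tuple[int, int] = (96, 256)
    xy_resolution: int = 2
    z_resolution: int = 1
    focal_center: float = 0.0
    slab_half_width: float = 3.0
    blur_sigma: float = 1.0
    perlin_magnitude: float = 0.05
    perlin_octaves: int = 2
    perlin_period: float = 32.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.slab_half_width * self.z_resolution < 0.5:
            raise ValueError("focal slab must span at least one voxel")
        if self.perlin_magnitude < 0:
            raise ValueError("perlin_magnitude must be >= 0")


@dataclass
class SkeletonFrame:
    """Prescribed 3D geometry of one frame.

    ``disc_centers``: (n_discs, 3); ``disc_axes``: unit cylinder axes,
    in-plane and perpendicular to the chain tangent; ``disc_chain``:
    chain index per disc; ``sarc_pairs``: (n_sarc, 2) disc indices of
    each sarcomere.
    """

    disc_centers: np.ndarray
    disc_axes: np.ndarray
    disc_radius: np.ndarray
    disc_height: np.ndarray
    disc_chain: np.ndarray
    sarc_pairs: np.ndarray

    @property
    def sarc_lengths(self) -> np.ndarray:
        a = self.disc_centers[self.sarc_pairs[:, 0]]
        b = self.disc_centers[self.sarc_pairs[:, 1]]
        return np.linalg.norm(b - a, axis=1)

    @property
    def sarc_centers_2d(self) -> np.ndarray:
        a = self.disc_centers[self.sarc_pairs[:, 0], :2]
        b = self.disc_centers[self.sarc_pairs[:, 1], :2]
        return 0.5 * (a + b)

    @property
    def sarc_orientations_2d(self) -> np.ndarray:
        """Unit in-plane orientation of each sarcomere (sign-free use)."""
        a = self.disc_centers[self.sarc_pairs[:, 0], :2]
        b = self.disc_centers[self.sarc_pairs[:, 1], :2]
        v = b - a
        n = np.linalg.norm(v, axis=1, keepdims=True)
        return v / np.where(n == 0, 1.0, n)


def build_skeleton(
    chain_specs: Sequence[ChainSpec],
    program: ContractionProgram,
    n_frames: int,
) -> list[SkeletonFrame]:
    """Place z-discs along each chain's guide curve for every frame.

    Discs are stepped sequentially so that the chord distance between
    consecutive disc centers is exactly ``rest_length * (1 + g_k(t))``.
    Disc cylinder axes are the in-plane perpendicular of the local chain
    tangent (mean of adjacent segment directions for interior discs).
    """
    total_sarc = sum(c.n_sarcomeres for c in chain_specs)
    if program.n_sarcomeres != total_sarc:
        raise ValueError(
            f"program covers {program.n_sarcomeres} sarcomeres, scene has {total_sarc}"
        )
    if program.n_frames < n_frames:
        raise ValueError("program does not cover n_frames")

    frames: list[SkeletonFrame] = []
    for t in range(n_frames):
        centers, axes, radii, heights, chain_idx, pairs = [], [], [], [], [], []
        col0 = 0
        disc0 = 0
        for ci, spec in enumerate(chain_specs):
            lengths = spec.rest_length * (
                1.0 + program.g[t, col0 : col0 + spec.n_sarcomeres]
            )
            pts = _place_discs(spec, lengths)
            tangents = _chain_tangents(pts)
            for j in range(len(pts)):
                centers.append(pts[j])
                axes.append(_inplane_perpendicular(tangents[j]))
                radii.append(spec.disc_radius)
                heights.append(spec.disc_height)
                chain_idx.append(ci)
            for k in range(spec.n_sarcomeres):
                pairs.append((disc0 + k, disc0 + k + 1))
            col0 += spec.n_sarcomeres
            disc0 += spec.n_sarcomeres + 1
        frames.append(
            SkeletonFrame(
                disc_centers=np.asarray(centers, dtype=float),
                disc_axes=np.asarray(axes, dtype=float),
                disc_radius=np.asarray(radii, dtype=float),
                disc_height=np.asarray(heights, dtype=float),
                disc_chain=np.asarray(chain_idx, dtype=int),
                sarc_pairs=np.asarray(pairs, dtype=int),
            )
        )
    return frames


def _place_discs(spec: ChainSpec, lengths: np.ndarray) -> np.ndarray:
    """Sequential chord stepping: each disc sits on the guide curve at the
    exact prescribed distance from its neighbor.

    The chain is anchored at its central disc (a free chain shortens
    toward its middle, not toward one end), so both halves step outward
    from a fixed arc-length parameter on the guide curve.
    """
    n = len(lengths)
    mid = n // 2
    u_mid = float(spec.rest_length) * mid  # rest arc position of the anchor disc
    anchor = np.asarray(spec.guide_point(u_mid), dtype=float)

    def step(u: float, prev: np.ndarray, L: float, direction: int) -> tuple[float, np.ndarray]:
        def dist(uu: float) -> float:
            return float(np.linalg.norm(spec.guide_point(uu) - prev)) - L

        if direction > 0:
            lo, hi = u + 1e-9, u + 2.0 * L
            while dist(hi) < 0:  # widen if the curve is locally very curved
                hi += L
        else:
            hi, lo = u - 1e-9, u - 2.0 * L
            while dist(lo) < 0:
                lo -= L
        u_next = brentq(dist, lo, hi, xtol=1e-10)
        return u_next, np.asarray(spec.guide_point(u_next), dtype=float)

    forward: list[np.ndarray] = []
    u, prev = u_mid, anchor
    for L in lengths[mid:]:
        u, prev = step(u, prev, float(L), +1)
        forward.append(prev)
    backward: list[np.ndarray] = []
    u, prev = u_mid, anchor
    for L in lengths[:mid][::-1]:
        u, prev = step(u, prev, float(L), -1)
        backward.append(prev)
    return np.asarray(backward[::-1] + [anchor] + forward)


def _chain_tangents(pts: np.ndarray) -> np.ndarray:
    segs = np.diff(pts, axis=0)
    segs = segs / np.linalg.norm(segs, axis=1, keepdims=True)
    tangents = np.empty_like(pts)
    tangents[0] = segs[0]
    tangents[-1] = segs[-1]
    if len(pts) > 2:
        mid = segs[:-1] + segs[1:]
        tangents[1:-1] = mid / np.linalg.norm(mid, axis=1, keepdims=True)
    return tangents


def _inplane_perpendicular(tangent: np.ndarray) -> np.ndarray:
    ax = np.array([-tangent[1], tangent[0], 0.0])
    n = np.linalg.norm(ax)
    if n < 1e-12:  # chain pointing straight out of plane; arbitrary in-plane axis
        return np.array([1.0, 0.0, 0.0])
    return ax / n


def render_frame(skeleton_frame: SkeletonFrame, params: RenderParams) -> np.ndarray:
    """Render one frame: voxelize each disc cylinder at sub-pixel xy
    resolution, slice to the focal slab, max-project along z, block-average
    down to the pixel grid, Gaussian-blur, and normalize to [0, 1].

    A frame whose slab contains no disc voxels renders all-zero (valid).
    """
    rows, cols = params.shape
    sub = params.xy_resolution
    canvas = np.zeros((rows * sub, cols * sub), dtype=np.float32)

    z_step = 1.0 / params.z_resolution
    z_lo = params.focal_center - params.slab_half_width
    z_hi = params.focal_center + params.slab_half_width
    n_z = max(1, int(round((z_hi - z_lo) / z_step)))
    z_centers = z_lo + (np.arange(n_z) + 0.5) * (z_hi - z_lo) / n_z

    for c, ax, r, h in zip(
        skeleton_frame.disc_centers,
        skeleton_frame.disc_axes,
        skeleton_frame.disc_radius,
        skeleton_frame.disc_height,
    ):
        extent = h / 2.0 + r + 1.0
        x0 = max(0, int(np.floor((c[0] - extent) * sub)))
        x1 = min(cols * sub, int(np.ceil((c[0] + extent) * sub)) + 1)
        y0 = max(0, int(np.floor((c[1] - extent) * sub)))
        y1 = min(rows * sub, int(np.ceil((c[1] + extent) * sub)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        # sub-pixel voxel centers in pixel units
        xs = (np.arange(x0, x1) + 0.5) / sub
        ys = (np.arange(y0, y1) + 0.5) / sub
        X, Y = np.meshgrid(xs, ys)
        dx = X - c[0]
        dy = Y - c[1]
        hit = np.zeros(X.shape, dtype=bool)
        for z in z_centers:
            dz = z - c[2]
            along = dx * ax[0] + dy * ax[1] + dz * ax[2]
            rad2 = dx * dx + dy * dy + dz * dz - along * along
            hit |= (np.abs(along) <= h / 2.0) & (rad2 <= r * r)
        canvas[y0:y1, x0:x1] = np.maximum(canvas[y0:y1, x0:x1], hit.astype(np.float32))

    # block-average down to the pixel grid (anti-aliasing)
    image = canvas.reshape(rows, sub, cols, sub).mean(axis=(1, 3))
    if params.blur_sigma > 0:
        image = gaussian_filter(image, params.blur_sigma)
    peak = image.max()
    if peak > 0:
        image = image / peak
    return image.astype(np.float64)


def perlin_field(
    shape: tuple[int, int],
    octaves: int,
    seed: int,
    base_period: float = 32.0,
) -> np.ndarray:
    """Classic multi-octave 2D gradient (Perlin) noise.

    Octave i has lattice period ``base_period / 2**i`` and weight 0.5**i
    (persistence 0.5). The summed field is rescaled to peak amplitude 1
    and is deterministic given ``seed``.
    """
    rows, cols = shape
    total = np.zeros((rows, cols), dtype=float)
    for i in range(octaves):
        period = base_period / (2.0**i)
        total += 0.5**i * _perlin_octave(shape, period, seed + 1000003 * i)
    peak = np.abs(total).max()
    if peak > 0:
        total = total / peak
    return total


def _perlin_octave(shape: tuple[int, int], period: float, seed: int) -> np.ndarray:
    rows, cols = shape
    y = np.arange(rows)[:, None] / period
    x = np.arange(cols)[None, :] / period
    yi = np.floor(y).astype(int)
    xi = np.floor(x).astype(int)
    yf = y - yi
    xf = x - xi

    rng = np.random.default_rng(seed)
    n_gy = int(rows / period) + 2
    n_gx = int(cols / period) + 2
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(n_gy, n_gx))
    gy = np.sin(angles)
    gx = np.cos(angles)

    def dot_corner(oy: int, ox: int) -> np.ndarray:
        iy = yi + oy
        ix = xi + ox
        return gx[iy, ix] * (xf - ox) + gy[iy, ix] * (yf - oy)

    def fade(t: np.ndarray) -> np.ndarray:
        return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)

    u, v = fade(xf), fade(yf)
    top = dot_corner(0, 0) * (1 - u) + dot_corner(0, 1) * u
    bot = dot_corner(1, 0) * (1 - u) + dot_corner(1, 1) * u
    return top * (1 - v) + bot * v


def add_perlin_noise(
    image: np.ndarray,
    magnitude: float,
    octaves: int,
    seed: int,
    base_period: float = 32.0,
) -> np.ndarray:
    """Add zero-mean multi-octave Perlin noise and clip back to [0, 1]."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0 or octaves == 0:
        return image.copy()
    noise = perlin_field(image.shape, octaves, seed, base_period)
    return np.clip(image + magnitude * noise, 0.0, 1.0)


@dataclass
class GroundTruth:
    """Prescribed geometry and the scalar metrics it implies.

    All arrays are indexed (frame, sarcomere) or (frame, disc). Metrics
    are computed from the prescribed geometry with the same formulas the
    analysis pipeline applies to recovered data: per-sarcomere shortening
    s from the normalized length series, median shortening, shortening of
    the mean series, OOP at the most contracted frame, and the deformation
    metrics C_iso / C_parallel from the best-fit deformation gradient of
    the marker (sarcomere-center) motion.
    """

    disc_centers_2d: np.ndarray  # (n_frames, n_discs, 2)
    sarc_lengths: np.ndarray  # (n_frames, n_sarc), 3D lengths
    sarc_centers_2d: np.ndarray  # (n_frames, n_sarc, 2)
    sarc_orientations_2d: np.ndarray  # (n_frames, n_sarc, 2), unit vectors
    metrics: dict = field(default_factory=dict)


@dataclass
class Scene:
    """A complete synthetic experiment: geometry, program, rendering."""

    chains: tuple[ChainSpec, ...]
    program: ContractionProgram
    render: RenderParams = field(default_factory=RenderParams)
    n_frames: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames is None:
            self.n_frames = self.program.n_frames


def baseline_scene(
    seed: int = 0,
    n_frames: int = 80,
    peak_shortening: float = 0.15,
    perlin_magnitude: float = 0.05,
    perlin_octaves: int = 2,
    tilt_z: float = 0.0,
    amplitude: float = 10.0,
    period: float = 220.0,
    n_sarcomeres: int = 20,
) -> Scene:
    """The reference validation scene: a single sinusoidal chain of 20
    sarcomeres (rest length 10 px) beating homogeneously with 15% peak
    shortening, no out-of-plane tilt, and low-magnitude Perlin noise.
    """
    chain = ChainSpec(
        control_points=((22.0, 38.0, 0.0), (242.0, 38.0, 0.0)),
        n_sarcomeres=n_sarcomeres,
        rest_length=10.0,
        tilt_z=tilt_z,
        amplitude=amplitude,
        period=period,
    )
    program = ContractionProgram.beating(
        n_frames, n_sarcomeres, peak_shortening=peak_shortening
    )
    render = RenderParams(
        shape=(96, 256),
        perlin_magnitude=perlin_magnitude,
        perlin_octaves=perlin_octaves,
        rng_seed=seed,
    )
    return Scene(chains=(chain,), program=program, render=render)


def generate_movie(scene: Scene) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene into a (n_frames, rows, cols) float stack in [0, 1]
    with its GroundTruth. Per-frame Perlin noise uses a distinct seed
    derived from the scene seed; identical scenes are bit-identical.
    """
    n_frames = int(scene.n_frames)
    skeleton = build_skeleton(scene.chains, scene.program, n_frames)
    frames = []
    for t, sk in enumerate(skeleton):
        img = render_frame(sk, scene.render)
        img = add_perlin_noise(
            img,
            scene.render.perlin_magnitude,
            scene.render.perlin_octaves,
            seed=scene.render.rng_seed * 100003 + t,
            base_period=scene.render.perlin_period,
        )
        frames.append(img)
    stack = np.asarray(frames)

    gt = GroundTruth(
        disc_centers_2d=np.asarray([sk.disc_centers[:, :2] for sk in skeleton]),
        sarc_lengths=np.asarray([sk.sarc_lengths for sk in skeleton]),
        sarc_centers_2d=np.asarray([sk.sarc_centers_2d for sk in skeleton]),
        sarc_orientations_2d=np.asarray(
            [sk.sarc_orientations_2d for sk in skeleton]
        ),
    )
    gt.metrics = ground_truth_metrics(gt)
    return stack, gt


def ground_truth_metrics(gt: GroundTruth) -> dict:
    """Scalar contraction metrics from prescribed geometry, using the
    mechanics formulas on the noiseless marker positions."""
    from . import mechanics

    L = gt.sarc_lengths  # (T, n)
    Lbar = L.mean(axis=0, keepdims=True)
    y = (L - Lbar) / Lbar
    s = np.array([mechanics.shortening(y[:, k]) for k in range(y.shape[1])])
    s_med = float(np.median(s))
    s_avg = float(mechanics.shortening(y.mean(axis=1)))

    positions = np.transpose(gt.sarc_centers_2d, (0, 1, 2))  # (T, n, 2)
    ref, contracted = mechanics.select_frames(positions)
    F = mechanics.estimate_F(
        mechanics.pair_vectors(positions[ref]),
        mechanics.pair_vectors(positions[contracted]),
    )
    T_tensor, oop, v_max = mechanics.structural_tensor_oop(
        gt.sarc_orientations_2d[contracted]
    )
    c_iso = mechanics.c_iso(F)
    c_par = mechanics.c_parallel(F, v_max)
    return {
        "s_median": s_med,
        "s_avg": s_avg,
        "OOP": float(oop),
        "C_iso": float(c_iso),
        "C_parallel": float(c_par),
        "reference_frame": int(ref),
        "contracted_frame": int(contracted),
    }


def write_movie(out_dir: str | Path, stack: np.ndarray, gt: GroundTruth, scene: Scene | None = None) -> Path:
    """Write the movie as a multi-page float32 TIFF plus ground-truth
    sidecars (JSON scene/metrics, CSV per-frame per-sarcomere data)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "movie.tif", stack.astype(np.float32))

    sidecar: dict = {"metrics": gt.metrics}
    if scene is not None:
        sidecar["render"] = dataclasses.asdict(scene.render)
        sidecar["chains"] = [dataclasses.asdict(c) for c in scene.chains]
        sidecar["n_frames"] = int(scene.n_frames)
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))

    n_frames, n_sarc = gt.sarc_lengths.shape
    rows = []
    for t in range(n_frames):
        for k in range(n_sarc):
            rows.append(
                (
                    t,
                    k,
                    gt.sarc_lengths[t, k],
                    gt.sarc_centers_2d[t, k, 0],
                    gt.sarc_centers_2d[t, k, 1],
                    gt.sarc_orientations_2d[t, k, 0],
                    gt.sarc_orientations_2d[t, k, 1],
                )
            )
    header = "frame,sarcomere,length_px,center_x,center_y,orient_x,orient_y"
    np.savetxt(
        out / "ground_truth_sarcomeres.csv",
        np.asarray(rows),
        delimiter=",",
        header=header,
        comments="",
        fmt=["%d", "%d", "%.8f", "%.8f", "%.8f", "%.8f", "%.8f"],
    )
    return out
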