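# Methods

This note records the models, algorithms, parameter choices, and known
limits of the package in one place. Lengths are in pixels and times in
frames throughout.

## Synthetic movie generation

A scene is a set of sarcomere chains in 3D. Each chain follows a guide
curve: a control polyline displaced in-plane by a sinusoid (`amplitude`,
`period`, measured along the polyline) and lifted out of the focal
plane with slope `tilt_z`. z-discs are placed on the guide curve by
sequential chord stepping so that the distance between consecutive disc
centers equals exactly `rest_length · (1 + g_k(t))`, where g_k(t) is
the prescribed per-sarcomere fractional length change (g > −1; 0 at
rest). The chain is anchored at its central disc: a free chain shortens
toward its middle, and this also keeps per-frame disc displacement
symmetric across the chain. Disc cylinder axes are the in-plane
perpendicular of the local chain tangent, so rendered discs appear as
elongated blobs perpendicular to the chain, as in real z-disc labels.

Rendering voxelizes each disc cylinder on a sub-pixel grid
(`xy_resolution` = 2 voxels per pixel in x/y, `z_resolution` = 1 per
pixel unit in z, deliberately coarser), restricts to a focal slab
(half-width 3 px), max-projects along z (preserves blob brightness for
thin slabs), block-averages to the pixel grid (anti-aliasing), applies
a Gaussian blur (σ = 1 px), and normalizes to [0, 1]. Background noise
is classic 2D gradient (Perlin) noise: octave i has lattice period
32/2^i px and weight 0.5^i (persistence 0.5); the summed field is
rescaled to unit peak amplitude so the noise magnitude parameter is a
fraction of peak image intensity, then added and clipped to [0, 1].
All randomness derives from the scene seed; identical scenes render
bit-identically.

The default contraction program is a periodic sin² pulse: a 24-frame
beat every 40 frames reaching exactly the prescribed peak shortening at
mid-beat, with a flat rest between beats; an optional per-sarcomere
phase lag desynchronizes the chain, and arbitrary per-sarcomere
programs can be supplied as arrays or callables. The baseline
validation scene is a single sinusoidal chain of 20 sarcomeres (rest
length 10 px — about the visual scale of real recordings and coarse
enough that sub-pixel effects are realistic), amplitude 10 px over
period 220 px, no tilt, 80 frames (two beats) at 15% peak shortening,
Perlin magnitude 0.05 with 2 octaves.

Every movie carries its ground truth: per-frame projected disc centers
and per-sarcomere lengths, centers, and orientations, plus the scalar
metrics obtained by running the mechanics formulas of this package on
the prescribed (noiseless) geometry. Ground truth is therefore
self-consistent with the analysis code by construction.

What the generator does **not** emulate: photophysics (bleaching, shot
noise), camera models, non-sarcomeric fluorescent structures, and cell
motion other than the prescribed chain deformation. Passing the
round-trip tests therefore shows the pipeline recovers prescribed
geometry under structured background noise and blur — not that it is
robust to every artifact of real microscopy.

## Movie ingestion

Movies are multi-page TIFFs or lexicographically ordered frame
directories. Color input is converted with ITU-R BT.601 luma weights.
Integer pixel data is rescaled to [0, 1] by the global (not per-frame)
min/max over the stack, so intensity dynamics across the beat are
preserved; float data already inside [0, 1] is left untouched, which
makes a written float32 stack reload bit-exactly.

## Segmentation

The detection response is the Gaussian-smoothed (σ =
`gaussian_filter_size`, default 1; consider 2 for movies with strong
fluctuating background) negated Laplacian of the frame — negated so
bright-blob interiors score positive. Contours are extracted at the
global Otsu threshold of the response; because thresholding acts on the
Laplacian rather than the raw image, one global level suffices and the
result is invariant to constant intensity offsets. Open contours
(clipped at the border) and contours with fewer than 4 points (an
exposed configuration choice) are discarded. Disc center = mean of
contour points; disc length = exact maximum pairwise contour distance
(O(k²), contours are small; ties broken by contour order).

Sarcomere linking uses ghost points: per disc, two points at half the
median nearest-neighbor distance along the perpendicular to the disc's
endpoint axis; a mutual nearest-neighbor match between ghost points of
two different discs links the discs into a sarcomere, so each disc
joins at most two sarcomeres, one per side. Nearest-neighbor ties break
by smaller distance then lower disc index, making the result
deterministic. No "approximately parallel" test is enforced beyond
mutual matching. Sarcomere length = distance between disc centers,
width = mean of the two disc lengths, angle = direction of the
center-connecting vector in [0, π). Coordinates are x = column,
y = row, origin top-left, sub-pixel.

## Tracking

Frame-to-frame linking solves the assignment minimizing total squared
displacement (Hungarian algorithm) over candidate pairs within
`tp_depth` (default 4 px, reduce to 3 for low-resolution movies). A
track unmatched for up to `memory` frames (default 5) may be
reacquired, with the admissible radius scaling with the gap length so
the per-frame displacement bound stays consistent. z-discs and
sarcomeres are tracked independently. Tracks present in more than 10%
of the movie receive global IDs, assigned in (first frame, position)
order for reproducibility.

## Time-series reconstruction

Sarcomere tracks present in at least `keep_thresh` (default 0.75) of
the movie are densified by Gaussian-process regression per quantity
(length, width, angle, x, y): kernel = amplitude × RBF (length-scale
initialized at 10 frames, bounds [1, 100]) + white noise (initial
1e-2, bounds [1e-6, 1]), hyperparameters by marginal-likelihood
maximization, observations standardized before fitting (the kernel
family is fixed; standardization is this package's choice). The
posterior mean both interpolates across lost frames and smooths
pixel-quantization jitter. Angles are unwrapped with period π before
fitting. Normalized length y = (L − L̄)/L̄ uses the mean of the dense
reconstructed series as L̄ (gap-robust), so y is zero-mean by
construction. At least 3 observations are required per series.

## Deformation and functional metrics

All unordered pairs of tracked sarcomere centers define the pair-vector
matrices Λ₀ (reference) and Λ (current); ordered pairs would add only
antipodal duplicates that cancel in the normal equations. F_avg solves
the normal equation via a stable 2×2 solve with a condition-number
guard at 1e8; collinear marker sets are rejected. Polar decomposition
uses SVD (robust near singularity); principal stretches are sorted
λ₁ ≤ λ₂ and eigenvectors take a first-nonzero-positive sign
convention. Reference and contracted frames are chosen by the two-pass
rule: with frame 0 as reference, the frame maximizing det F (most
relaxed) becomes the reference; with that reference, the frame
minimizing det F is the most contracted. Ties break to the earliest
frame within a 1e-10 tolerance on det F. OOP, C_iso, and C_∥ are
evaluated at the most contracted frame; `dim` is fixed at 2.
Sarcomeres are not weighted by width in T or F; a weighting hook would
be straightforward but is deliberately absent.

## Spatial analysis

The spatial graph has tracked z-discs as nodes and sarcomeres as
edges; each frame in which a tracked sarcomere joins two tracked discs
increments the edge weight. Network distance between two sarcomeres is
the minimum node shortest-path length between their endpoint discs
plus one, so adjacent sarcomeres are 1 apart and a sarcomere is 0 from
itself; for path-shaped chains this coincides with line-graph distance.
The "normalized cross-correlation score" between series is zero-lag
Pearson correlation (bounded, scale-invariant); constant series are
excluded. Clustering uses average-linkage agglomeration on either
Euclidean distance or classic unconstrained dynamic time warping with
squared local cost (reported as the square root of the optimal
cumulative cost, so DTW ≤ Euclidean for equal-length series).

Timing parameters are this package's own definitions — the quantities
are standard but no canonical algorithm exists: contraction events are
local minima of y with prominence ≥ 25% of the series range;
contraction (relaxation) time runs from the preceding (to the next)
local extremum found by walking while the series strictly decreases
(increases); period is the median inter-minimum spacing; flat time is
period minus mean contraction and relaxation times; offset is the
frame of the first minimum. The same conventions summarize the
Jacobian series J(t).

## Numerical and testing notes

Validation scenes in the test suite use 30–80 frames and 6–20
sarcomeres per chain; these sizes give sub-second renders while leaving
segmentation, tracking, and GP reconstruction operating in the same
regime as full-scale movies. Determinism is enforced end to end: one
seed drives synthetic noise, GP fitting, and any random sampling.

Known limits: with a 10 px rest length, a 5% peak shortening is a
0.5 px signal, and the extremes of individual reconstructed series
carry a few-thousandths upward bias from sub-pixel rendering and
segmentation jitter; the median shortening s̃ inherits that bias while
the mean-series s_avg averages it out, so their agreement degrades as
the prescribed amplitude approaches the pixel scale. Large inter-frame
motion (beyond `tp_depth` per frame) splits tracks by design. Nearly
collinear marker sets leave the transverse components of F_avg weakly
constrained — single-chain scenes determine C_iso less sharply than
multi-chain ones. All metrics are kinematic; no forces are estimated.
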