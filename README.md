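# sarcokinetics

Segmentation, tracking, and contractile analysis of sarcomeres in
fluorescence movies of beating cardiomyocytes, plus a ground-truthed
synthetic movie generator for validating every stage of the pipeline.

## The problem

Human induced pluripotent stem cell-derived cardiomyocytes (hiPSC-CMs)
are immature, structurally disordered beating heart cells. In movies of
cells with fluorescently labeled z-discs, each sarcomere — the ≈2 µm
contractile unit — appears as the gap between two bright elongated
blobs. Quantifying contraction requires finding those blobs in every
frame, pairing them into sarcomeres, following each sarcomere through
the beat, and condensing hundreds of per-sarcomere length series into a
few functional numbers. Because no experimental ground truth exists at
this scale, the package also simulates such movies from prescribed
geometry so recovery can be checked exactly.

## What it computes

**Detection.** z-discs are closed iso-contours of the Gaussian-smoothed
negated Laplacian of each frame at a global Otsu threshold. Sarcomeres
are linked procedurally: each disc projects two "ghost points" half the
median nearest-neighbor distance along its perpendicular; a mutual
nearest-neighbor match between ghost points of two discs links them
into a sarcomere. Tracking solves, per frame pair, the assignment
minimizing total squared displacement within a radius `tp_depth`
(default 4 px), with short gaps bridged. Tracked series are completed
and smoothed by Gaussian-process regression (RBF + white-noise kernel).

**Functional metrics.** With sarcomere centers as fiducial markers and
Λ₀, Λ the 2×n matrices of all pairwise marker vectors in a reference
and current frame, the average deformation gradient is the least-squares
solution

    F_avg = Λ Λ₀ᵀ (Λ₀ Λ₀ᵀ)⁻¹,

decomposed as F = R U into a rotation and a symmetric positive-definite
stretch with principal stretches λ₁ ≤ λ₂ and Jacobian J = det F. From
the normalized length y = (L − L̄)/L̄ of each sarcomere, shortening is
s = (y_max − y_min)/(y_max + 1) ≡ (L_max − L_min)/L_max; s̃ is the
population median and s_avg the value on the mean series (they coincide
only under synchronous beating). Orientational order is the largest
eigenvalue of the structural tensor T = ⟨2 r rᵀ − I⟩ of unit sarcomere
orientations (OOP = 0 random, 1 aligned), and the deformation-based
contraction scalars are C_iso = 1 − det(F)^(1/2) and C_∥, the
fractional shortening along the dominant orientation v_max via
v₀ = F⁻¹ v_max. The cell is also represented as a spatial graph
(z-discs as nodes, sarcomeres as edges) on which network distance —
the number of connecting sarcomeres between a pair — supports
correlation-versus-distance and clustering analyses.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/03_metrics_pipeline.py` renders the baseline
validation scene (a sinusoidal chain of 20 sarcomeres beating
homogeneously at 15% peak shortening with low Perlin background noise),
runs the full pipeline on the rendered pixels, and prints:

```
20 reconstructed sarcomere time series
          metric  recovered  ground truth
        s_median     0.1542        0.1500
           s_avg     0.1528        0.1500
             OOP     0.9467        0.9478
           C_iso     0.2172        0.2086
      C_parallel     0.1479        0.1469
```

The recovered median and mean-series shortening land within half a
percent of the prescribed 15% and nearly coincide, as they must for
synchronous contraction; OOP and the deformation scalars match the
ground truth computed from the prescribed geometry. The residual gaps
reflect the sub-pixel limit of measuring ~1 px length changes in
rendered images.

The same pipeline is scriptable from the shell:

```sh
sarcokinetics synth --seed 1 --out scene/
sarcokinetics all --folder scene/ --seed 1 --out results/
```

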