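"""Average deformation gradient from fiducial markers and scalar
functional metrics of cardiomyocyte contraction.

Tracked sarcomere centers are treated as fiducial markers. The vectors
connecting every unordered marker pair in a reference frame (columns of
Lambda0) and in the current frame (columns of Lambda) define an
over-determined linear system F Lambda0 = Lambda whose least-squares
solution via the normal equation,

    F_avg = Lambda Lambda0^T (Lambda0 Lambda0^T)^{-1},

is the best-fit average deformation gradient of the tracked domain.
Polar decomposition F = R U splits it into a rotation and a symmetric
positive-definite stretch whose eigenvalues lambda1 <= lambda2 are the
principal stretches; J = det F is the area-change factor (< 1 under
contraction).

Scalar metrics:

* ``s`` — per-sarcomere shortening (y_max - y_min)/(y_max + 1) of the
  normalized length series, identical to (L_max - L_min)/L_max;
  ``s_median`` is its population median (robust to outliers), ``s_avg``
  its value on the pointwise-mean series (sensitive to asynchrony).
* ``OOP`` — largest eigenvalue of the structural tensor
  T = <2 r r^T - I> of unit sarcomere orientations; 0 = random,
  1 = perfect alignment; v_max is the dominant orientation.
* ``C_iso`` = 1 - det(F)^(1/dim) — equivalent isotropic line shortening.
* ``C_parallel`` — fractional line shortening along v_max, from
  v0 = F^{-1} v_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import polar

__all__ = [
    "DeformationState",
    "pair_vectors",
    "estimate_F",
    "polar_and_stretches",
    "compute_F_series",
    "select_frames",
    "shortening",
    "shortening_summary",
    "structural_tensor_oop",
    "c_iso",
    "c_parallel",
    "analyze_J",
    "compute_metrics",
]

_COND_LIMIT = 1e8


@dataclass(frozen=True)
class DeformationState:
    """Polar-decomposed average deformation gradient for one frame."""

    F: np.ndarray
    R: np.ndarray
    U: np.ndarray
    lambdas: tuple[float, float]  # principal stretches, lambda1 <= lambda2
    eigvecs: np.ndarray  # columns aligned with lambdas
    J: float


def pair_vectors(markers: np.ndarray) -> np.ndarray:
    """All vectors connecting unordered marker pairs, as a 2 x n matrix.

    ``markers`` is (m, 2) with m >= 3; n = m(m-1)/2 columns in fixed
    lexicographic pair order (0,1), (0,2), ..., (m-2, m-1).
    """
    markers = np.asarray(markers, dtype=float)
    m = markers.shape[0]
    if m < 3:
        raise ValueError("need at least 3 markers (system underdetermined)")
    i, j = np.triu_indices(m, k=1)
    return (markers[j] - markers[i]).T.copy()


def estimate_F(lambda0: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Best-fit deformation gradient via the normal equation.

    Minimizes sum_i ||F v0_i - v_i||^2 over 2x2 matrices F. Raises if
    the reference pair vectors are rank deficient (collinear markers).
    """
    lambda0 = np.asarray(lambda0, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if lambda0.shape != lam.shape or lambda0.shape[0] != 2:
        raise ValueError("Lambda0 and Lambda must both be 2 x n, column-aligned")
    A = lambda0 @ lambda0.T
    if np.linalg.cond(A) > _COND_LIMIT:
        raise ValueError(
            "reference marker pair vectors are (near-)collinear: "
            "normal matrix is rank deficient"
        )
    # F A = Lambda Lambda0^T  ->  solve A^T F^T = (Lambda Lambda0^T)^T
    B = lam @ lambda0.T
    return np.linalg.solve(A.T, B.T).T


def polar_and_stretches(F: np.ndarray) -> DeformationState:
    """Polar decomposition F = R U with principal stretches of U.

    Uses SVD-based polar decomposition (robust near-singular F).
    Eigenvector sign convention: first nonzero component positive.
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError("det F <= 0: non-physical frame flip")
    R, U = polar(F, side="right")
    w, V = np.linalg.eigh(U)
    order = np.argsort(w)
    w = w[order]
    V = V[:, order]
    for k in range(V.shape[1]):
        V[:, k] = _canonical_sign(V[:, k])
    return DeformationState(
        F=F, R=R, U=U, lambdas=(float(w[0]), float(w[1])), eigvecs=V, J=J
    )


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    for comp in v:
        if abs(comp) > 1e-12:
            return v if comp > 0 else -v
    return v


def compute_F_series(
    positions: np.ndarray, reference_frame: int = 0
) -> list[DeformationState]:
    """Average deformation gradient at every frame.

    ``positions`` is (n_frames, m, 2) reconstructed marker positions.
    F at the reference frame is the identity exactly.
    """
    positions = np.asarray(positions, dtype=float)
    lambda0 = pair_vectors(positions[reference_frame])
    states = []
    for t in range(positions.shape[0]):
        if t == reference_frame:
            F = np.eye(2)
        else:
            F = estimate_F(lambda0, pair_vectors(positions[t]))
        states.append(polar_and_stretches(F))
    return states


def select_frames(positions: np.ndarray) -> tuple[int, int]:
    """Two-pass reference/contracted frame selection.

    Pass 1: with frame 0 as reference, the frame maximizing det(F_avg)
    (most relaxed) becomes the reference. Pass 2: with that reference,
    the frame minimizing det(F_avg) is the most contracted. Ties break
    to the earliest frame.
    """
    states = compute_F_series(positions, reference_frame=0)
    J = np.array([s.J for s in states])
    reference = _first_extremum(J, np.max)
    states = compute_F_series(positions, reference_frame=reference)
    J = np.array([s.J for s in states])
    contracted = _first_extremum(J, np.min)
    return reference, contracted


def _first_extremum(J: np.ndarray, extremum, tol: float = 1e-10) -> int:
    """Earliest frame within ``tol`` of the extremal det(F) (tie-break)."""
    target = extremum(J)
    return int(np.flatnonzero(np.abs(J - target) <= tol)[0])


def shortening(y: np.ndarray) -> float:
    """Sarcomere shortening s = (y_max - y_min) / (y_max + 1).

    ``y`` is the normalized length series (L - Lbar)/Lbar; the result is
    identical to (L_max - L_min)/L_max.
    """
    y = np.asarray(y, dtype=float)
    return float((y.max() - y.min()) / (y.max() + 1.0))


def shortening_summary(y_series: np.ndarray) -> tuple[float, float]:
    """(s_median, s_avg) over a population of normalized-length series.

    ``y_series`` is (n_series, n_frames). s_median is the median of
    per-series s; s_avg is s of the pointwise-mean series. They coincide
    for identical synchronous series and diverge under asynchrony
    (s_avg drops).
    """
    y_series = np.atleast_2d(np.asarray(y_series, dtype=float))
    s = np.array([shortening(y) for y in y_series])
    return float(np.median(s)), shortening(y_series.mean(axis=0))


def structural_tensor_oop(
    orientations: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Structural tensor T = <2 r r^T - I>, OOP, and dominant direction.

    ``orientations`` is (n, 2) unit vectors; the tensor is invariant
    under r -> -r. Returns (T, OOP = largest eigenvalue, v_max with
    first-nonzero-positive sign).
    """
    r = np.asarray(orientations, dtype=float)
    if r.ndim != 2 or r.shape[1] != 2 or r.shape[0] < 1:
        raise ValueError("orientations must be (n, 2) with n >= 1")
    outer = 2.0 * np.einsum("ni,nj->nij", r, r) - np.eye(2)
    T = outer.mean(axis=0)
    w, V = np.linalg.eigh(T)
    v_max = _canonical_sign(V[:, -1])
    return T, float(w[-1]), v_max


def c_iso(F: np.ndarray, dim: int = 2) -> float:
    """Equivalent isotropic line shortening C_iso = 1 - det(F)^(1/dim)."""
    J = float(np.linalg.det(np.asarray(F, dtype=float)))
    if J <= 0:
        raise ValueError("det F <= 0")
    return 1.0 - J ** (1.0 / dim)


def c_parallel(F: np.ndarray, v_max: np.ndarray) -> float:
    """Fractional shortening along the dominant orientation v_max.

    With v0 = F^{-1} v_max the reference-frame preimage of the unit
    dominant direction, C_parallel = (|v0| - |v_max|)/|v0|.
    """
    F = np.asarray(F, dtype=float)
    v_max = np.asarray(v_max, dtype=float)
    v0 = np.linalg.solve(F, v_max)
    n0 = float(np.linalg.norm(v0))
    return (n0 - float(np.linalg.norm(v_max))) / n0


def analyze_J(J: np.ndarray, prominence_frac: float = 0.25) -> dict:
    """Timing summary of the Jacobian series J(t) = det F_avg(t).

    Contraction events are the prominent local minima of J; the summary
    reuses the peak-timing conventions of
    ``spatial_analysis.timeseries_parameters``.
    """
    from .spatial_analysis import timeseries_parameters

    return timeseries_parameters(np.asarray(J, dtype=float), prominence_frac)


def compute_metrics(
    positions: np.ndarray,
    y_series: np.ndarray,
    orientations: np.ndarray,
) -> dict:
    """Full scalar metric bundle from reconstructed sarcomere data.

    ``positions``: (n_frames, m, 2) marker positions; ``y_series``:
    (m, n_frames) normalized lengths; ``orientations``: (n_frames, m, 2)
    unit orientation vectors. Frames are selected by the two-pass
    det(F) rule, then OOP / C_iso / C_parallel are evaluated at the most
    contracted frame.
    """
    reference, contracted = select_frames(positions)
    lambda0 = pair_vectors(positions[reference])
    F = estimate_F(lambda0, pair_vectors(positions[contracted]))
    s_med, s_avg = shortening_summary(y_series)
    _, oop, v_max = structural_tensor_oop(orientations[contracted])
    return {
        "s_median": s_med,
        "s_avg": s_avg,
        "OOP": oop,
        "C_iso": c_iso(F),
        "C_parallel": c_parallel(F, v_max),
        "reference_frame": reference,
        "contracted_frame": contracted,
    }
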