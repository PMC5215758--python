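"""Generalized Procrustes Analysis and bending-energy sliding of semilandmarks.

GPA removes location, scale, and orientation from a sample of landmark
configurations: each configuration is translated to a common origin, scaled to
unit centroid size, and rotated to minimize the summed squared distance to the
evolving sample mean.  The resulting Procrustes shape coordinates are the
shape representation used throughout the analysis.

Semilandmarks — points digitized on homologous curves whose position *along*
the curve is arbitrary — are relaxed by the sliding-landmark algorithm: each
is allowed to move along the local curve tangent so as to minimize the
thin-plate-spline bending energy between the specimen and the sample average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from morphoface.io import SemilandmarkScheme
from morphoface.warping import tps_kernel


@dataclass
class ProcrustesResult:
    """Mean shape and Procrustes shape coordinates after GPA."""

    mean_shape: np.ndarray  # (k, 2), centered, centroid size 1
    aligned: np.ndarray  # (n, k, 2)
    n_iterations: int
    converged: bool


@dataclass
class BendingEnergyMatrix:
    """The k x k bending-energy matrix of a reference configuration.

    Symmetric and positive semidefinite; its quadratic form on a displacement
    field is the thin-plate-spline bending energy per coordinate, and it
    vanishes exactly on affine displacement fields.
    """

    matrix: np.ndarray  # (k, k)
    reference: np.ndarray  # (k, 2)

    def energy(self, displacement: np.ndarray) -> float:
        """Total bending energy of a (k, 2) displacement field."""
        d = np.asarray(displacement, dtype=float)
        return float(d[:, 0] @ self.matrix @ d[:, 0] + d[:, 1] @ self.matrix @ d[:, 1])


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of points from their centroid."""
    pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("config must be a (k>=2, 2) array")
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return cs


def align_pair(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Optimal proper rotation R (2x2, det +1) minimizing ||A @ R - B||_F.

    Both configurations must already be centered.  Reflections are never
    returned: faces have handedness.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 2:
        raise ValueError("A and B must be (k, 2) arrays of equal shape")
    H = A.T @ B
    if np.linalg.matrix_rank(H) < 2:
        raise ValueError("degenerate (collinear) shapes: rotation is not unique")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, d]) @ Vt
    return R


def _center_scale(config: np.ndarray) -> np.ndarray:
    centered = config - config.mean(axis=0)
    return centered / centroid_size(config)


def gpa(
    configs: np.ndarray | list,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes Analysis of n configurations (n, k, 2).

    Iterates: center all, scale each to centroid size 1, rotate each to the
    current mean, recompute and renormalize the mean — until the mean shape
    moves by less than ``tol`` (RMS per coordinate).  Non-convergence within
    ``max_iter`` is flagged, not fatal.
    """
    X = np.asarray(configs, dtype=float)
    if X.ndim != 3 or X.shape[2] != 2 or X.shape[0] < 2:
        raise ValueError("configs must be an (n>=2, k, 2) array")
    n = X.shape[0]
    aligned = np.stack([_center_scale(X[i]) for i in range(n)])
    mean = aligned[0].copy()
    n_it = 0
    converged = False
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            R = align_pair(aligned[i], mean)
            aligned[i] = aligned[i] @ R
        new_mean = aligned.mean(axis=0)
        new_mean = _center_scale(new_mean)
        shift = float(np.sqrt(((new_mean - mean) ** 2).mean()))
        mean = new_mean
        if shift < tol:
            converged = True
            break
    # final rotation pass so every configuration is optimally posed on the mean
    for i in range(n):
        aligned[i] = aligned[i] @ align_pair(aligned[i], mean)
    return ProcrustesResult(mean_shape=mean, aligned=aligned, n_iterations=n_it, converged=converged)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate difference between two aligned shapes.

    This is the small-variation (tangent-space) approximation to the
    Procrustes distance, valid for shapes from a common GPA.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape dimension mismatch")
    return float(np.linalg.norm(a - b))


def bending_energy_matrix(reference: np.ndarray) -> BendingEnergyMatrix:
    """Bending-energy matrix of a reference configuration.

    Builds the bordered thin-plate-spline system with kernel
    U(r) = r^2 log r^2 and returns the upper-left k x k block of its inverse:
    the quadratic form whose value on a displacement field is the TPS bending
    energy.  It annihilates affine displacement fields exactly.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 4:
        raise ValueError("reference must be a (k>=4, 2) array")
    k = ref.shape[0]
    r2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    if np.any(r2[~np.eye(k, dtype=bool)] == 0.0):
        raise ValueError("coincident landmarks in reference: singular kernel")
    K = tps_kernel(np.sqrt(r2))
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular TPS system (collinear reference?)") from e
    M = Linv[:k, :k]
    M = 0.5 * (M + M.T)
    return BendingEnergyMatrix(matrix=M, reference=ref)


def _curve_tangents(points: np.ndarray, scheme: SemilandmarkScheme) -> dict[int, np.ndarray]:
    """Unit tangents at sliding semilandmarks, from the current point positions.

    Central differences of the neighboring curve points; the (fixed) curve
    endpoints get no tangent.  Raises on coincident neighbors (zero tangent).
    """
    tangents: dict[int, np.ndarray] = {}
    sliding = set(scheme.sliding_indices)
    for curve in scheme.curves:
        for pos in range(1, len(curve) - 1):
            idx = curve[pos]
            if idx not in sliding:
                continue
            t = points[curve[pos + 1]] - points[curve[pos - 1]]
            norm = np.linalg.norm(t)
            if norm == 0.0:
                raise ValueError(f"zero-length tangent at landmark {idx} (coincident neighbors)")
            tangents[idx] = t / norm
    return tangents


def _slide_one(
    points: np.ndarray,
    mean: np.ndarray,
    M: np.ndarray,
    scheme: SemilandmarkScheme,
    specimen_id: str = "?",
) -> np.ndarray:
    """Closed-form generalized least-squares sliding step for one specimen.

    Displacements of sliding points are constrained to their tangent
    directions; the tangent offsets minimizing the bending energy of the
    residual against the mean solve a small symmetric linear system.
    """
    try:
        tangents = _curve_tangents(points, scheme)
    except ValueError as e:
        raise ValueError(f"specimen {specimen_id}: {e}") from None
    idx = sorted(tangents)
    if not idx:
        return points.copy()
    s = len(idx)
    k = points.shape[0]
    Tx = np.zeros((k, s))
    Ty = np.zeros((k, s))
    for col, j in enumerate(idx):
        Tx[j, col] = tangents[j][0]
        Ty[j, col] = tangents[j][1]
    d = points - mean
    A = Tx.T @ M @ Tx + Ty.T @ M @ Ty
    b = Tx.T @ M @ d[:, 0] + Ty.T @ M @ d[:, 1]
    try:
        lam = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError:
        lam = np.linalg.lstsq(A, -b, rcond=None)[0]
    out = points.copy()
    for col, j in enumerate(idx):
        out[j] = out[j] + lam[col] * tangents[j]
    return out


def slide_semilandmarks(
    configs: np.ndarray | list,
    scheme: SemilandmarkScheme,
    tol: float = 1e-8,
    max_outer_iter: int = 3,
    specimen_ids: list[str] | None = None,
    regpa_each_iter: bool = False,
    final_gpa: bool = True,
    energy_trace: list[float] | None = None,
) -> tuple[np.ndarray, ProcrustesResult]:
    """Relax semilandmarks along their curve tangents to minimize bending energy.

    An initial GPA fixes the alignment, the sample mean, and the
    bending-energy matrix of the mean; the relaxation then alternates sliding
    (each specimen's tangent offsets solved in closed form against the mean)
    with recomputation of the mean.  Both steps are exact minimizers of the
    total bending energy, so the energy trace is non-increasing by
    construction.  A final GPA re-superimposes the slid configurations.

    With ``regpa_each_iter`` the superimposition, mean, and bending-energy
    matrix are instead refreshed every outer iteration (the classical
    alternation, monotone only to numerical tolerance).  With
    ``final_gpa=False`` the closing superimposition is skipped, leaving the
    configurations in the initial GPA's frame (anatomical landmarks then keep
    their exact pre-sliding coordinates).  If ``energy_trace`` is a list, the
    total bending energy after the initial GPA and after each outer iteration
    is appended to it.

    Returns the slid configurations (in the alignment frame) and the final
    :class:`ProcrustesResult`.
    """
    X = np.asarray(configs, dtype=float)
    if X.ndim != 3 or X.shape[1] != scheme.n_points:
        raise ValueError("configs inconsistent with scheme point count")
    ids = specimen_ids if specimen_ids is not None else [str(i) for i in range(X.shape[0])]
    if not scheme.sliding_indices:
        res = gpa(X)
        return res.aligned.copy(), res
    res = gpa(X)
    aligned = res.aligned.copy()
    mean = res.mean_shape
    bem = bending_energy_matrix(mean)
    prev_energy = float(sum(bem.energy(aligned[i] - mean) for i in range(X.shape[0])))
    if energy_trace is not None:
        energy_trace.append(prev_energy)
    for _ in range(max_outer_iter):
        for i in range(aligned.shape[0]):
            aligned[i] = _slide_one(aligned[i], mean, bem.matrix, scheme, ids[i])
        mean = aligned.mean(axis=0)
        if regpa_each_iter:
            res = gpa(aligned)
            aligned = res.aligned.copy()
            mean = res.mean_shape
            bem = bending_energy_matrix(mean)
        energy = float(sum(bem.energy(aligned[i] - mean) for i in range(aligned.shape[0])))
        if energy_trace is not None:
            energy_trace.append(energy)
        if prev_energy - energy < tol * max(prev_energy, 1.0):
            break
        prev_energy = energy
    if not final_gpa:
        return aligned, ProcrustesResult(mean_shape=_center_scale(mean), aligned=aligned,
                                         n_iterations=res.n_iterations, converged=res.converged)
    final = gpa(aligned)
    return final.aligned.copy(), final
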