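"""Point-set registration of centroid datasets to a reference cloud.

Pipeline (per dataset): an anchor-based rotation brings the source cloud into
approximate orientation with the reference; affine coherent point drift (CPD)
then refines the alignment; finally each transformed source cell is matched
to its Euclidean-nearest reference cell and its marker labels are transferred.

CPD models the source set as a Gaussian mixture (one isotropic component of
variance sigma^2 per source point, plus an optional uniform outlier component
of weight ``w``) and treats the reference set as observations drawn from it.
EM alternates Gaussian posteriors (E-step) with closed-form updates of the
affine matrix ``B``, translation ``t`` and ``sigma^2`` (M-step), maximizing
the likelihood of the observed cloud.  The fit is deterministic given its
inputs; all stochasticity lives in the synthetic-data generators.

Numerical conventions: both clouds are centered and jointly scaled by the
reference RMS radius before EM (sigma^2 initialization is then stable across
unit choices), and the recovered transform is composed back to micrometres.
Convergence is declared when the absolute change of the negative
log-likelihood falls below ``tolerance`` (default 1e-3, with the default
iteration cap of 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from ciona_visuomotor.centroid_io import CentroidDataset
from ciona_visuomotor.circuit_model import (
    CircuitFixture,
    fixture_anchors,
    fixture_points,
)

__all__ = [
    "RigidInit",
    "AffineTransform",
    "RegistrationResult",
    "RegistrationParams",
    "LabeledAssignment",
    "ConfigurationError",
    "DegenerateGeometryError",
    "anchor_rotation",
    "cpd_affine_register",
    "map_nearest",
    "register_dataset",
]


class ConfigurationError(ValueError):
    """Inputs are structurally unusable (e.g. no shared anchor)."""


class DegenerateGeometryError(ValueError):
    """Geometry admits no well-posed solution (coplanar cloud, zero vector)."""


@dataclass(frozen=True)
class RigidInit:
    """Rotation initializing CPD; orthonormal with det +1."""

    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, float)
        if R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("R not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("det(R) != +1")
        object.__setattr__(self, "R", R)


@dataclass(frozen=True)
class AffineTransform:
    """Maps a point y to B @ y + t (micrometres)."""

    B: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        B = np.asarray(self.B, float).reshape(3, 3)
        t = np.asarray(self.t, float).reshape(3)
        if not (np.all(np.isfinite(B)) and np.all(np.isfinite(t))):
            raise ValueError("non-finite transform")
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "t", t)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.B))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.B.T + self.t


@dataclass
class RegistrationResult:
    init: RigidInit
    transform: AffineTransform
    sigma2_trace: list[float]
    nll_trace: list[float]
    n_iterations: int
    converged: bool
    correspondence: dict[str, str]
    distances: dict[str, float]


@dataclass
class RegistrationParams:
    w: float = 0.0                 # uniform outlier weight, in [0, 1)
    max_iterations: int = 1000
    tolerance: float = 1e-3        # |delta NLL| convergence threshold
    anchor_names: list[str] | None = None   # None -> all shared anchors
    target_classes: list[str] | None = None  # reference subset for fixtures
    one_to_one: bool = False       # Hungarian assignment instead of NN


@dataclass
class LabeledAssignment:
    """Label transfer of one dataset onto the reference cells.

    ``labels`` maps each matched reference cell to the union of labels of the
    source cells matched to it; ``multiplicity`` counts those source cells.
    Reference cells absent from ``labels`` received no source cell (no-call).
    """

    dataset_id: str
    reference_ids: list[str]
    labels: dict[str, frozenset[str]]
    multiplicity: dict[str, int]
    registration: RegistrationResult

    def no_call_ids(self) -> list[str]:
        return [r for r in self.reference_ids if r not in self.labels]


# ---------------------------------------------------------------------------
# Anchor rotation

def _reference_view(ref, target_classes=None):
    """(ids, points, anchors) for either a CentroidDataset or CircuitFixture."""
    if isinstance(ref, CircuitFixture):
        ids, pts = fixture_points(ref, target_classes)
        return ids, pts, fixture_anchors(ref)
    if target_classes is not None:
        raise ConfigurationError(
            "target_classes applies only to circuit-fixture references")
    return list(ref.cell_ids), np.asarray(ref.positions, float), dict(ref.anchors)


def _minimal_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smallest rotation taking direction u onto direction v (Rodrigues)."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("zero-length anchor vector")
    u = u / nu
    v = v / nv
    c = float(np.clip(u @ v, -1.0, 1.0))
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 degrees about a deterministic perpendicular
        p = np.array([1.0, 0.0, 0.0])
        if abs(u @ p) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation minimizing ||R P - Q|| over centered point pairs."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def anchor_rotation(
    src: CentroidDataset,
    ref,
    anchor_names: list[str] | None = None,
    target_classes: list[str] | None = None,
) -> RigidInit:
    """Rotation aligning the source anchor->cluster geometry to the reference's.

    With one shared anchor, the minimal rotation taking the source
    anchor->cluster-centroid vector onto the reference's (roll about that axis
    is unconstrained by a single landmark and left at zero).  With two or more
    shared anchors, the orthogonal Procrustes rotation over the anchor points
    plus the cluster centroid.
    """
    ref_ids, ref_pts, ref_anchors = _reference_view(ref, target_classes)
    shared = [a for a in (anchor_names or sorted(src.anchors))
              if a in src.anchors and a in ref_anchors]
    if not shared:
        raise ConfigurationError("no shared anchor between source and reference")
    if len(ref_pts) == 0 or len(src.positions) == 0:
        raise ConfigurationError("empty target cell cluster")

    c_src = src.positions.mean(axis=0)
    c_ref = ref_pts.mean(axis=0)

    if len(shared) == 1:
        v_src = c_src - src.anchors[shared[0]]
        v_ref = c_ref - ref_anchors[shared[0]]
        return RigidInit(_minimal_rotation(v_src, v_ref))

    P = np.array([src.anchors[a] for a in shared] + [c_src])
    Q = np.array([ref_anchors[a] for a in shared] + [c_ref])
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.norm(Pc) < 1e-12 or np.linalg.norm(Qc) < 1e-12:
        raise DegenerateGeometryError("anchors coincident with cluster centroid")
    return RigidInit(_kabsch(Pc, Qc))


# ---------------------------------------------------------------------------
# Affine coherent point drift

def cpd_affine_register(
    source_points: np.ndarray,
    reference_points: np.ndarray,
    w: float = 0.0,
    max_iterations: int = 1000,
    tolerance: float = 1e-3,
) -> tuple[AffineTransform, list[float], list[float], int, bool]:
    """Fit the affine transform mapping source onto reference by EM.

    Returns ``(transform, sigma2_trace, nll_trace, n_iterations, converged)``.
    The source plays the Gaussian-mixture centroids; the reference plays the
    observations.  ``w`` is the uniform outlier weight.
    """
    Y = np.asarray(source_points, float).reshape(-1, 3)   # GMM centroids
    X = np.asarray(reference_points, float).reshape(-1, 3)  # observations
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite input points")
    if not 0.0 <= w < 1.0:
        raise ValueError("outlier weight w must be in [0, 1)")
    M, N, D = len(Y), len(X), 3
    if M < 4:
        raise DegenerateGeometryError("need >= 4 source points")
    if np.linalg.matrix_rank(Y - Y.mean(axis=0), tol=1e-9) < 3:
        raise DegenerateGeometryError("source points are coplanar/degenerate")

    # center and jointly scale by the reference RMS radius
    mu_x = X.mean(axis=0)
    mu_y = Y.mean(axis=0)
    s = float(np.sqrt(np.mean(np.sum((X - mu_x) ** 2, axis=1))))
    if s < 1e-12:
        s = 1.0
    Xn = (X - mu_x) / s
    Yn = (Y - mu_y) / s

    B = np.eye(D)
    t = np.zeros(D)
    TY = Yn @ B.T + t
    sigma2 = float(np.sum((Xn[None, :, :] - TY[:, None, :]) ** 2) / (D * M * N))
    sigma2 = max(sigma2, 1e-12)

    sigma2_trace: list[float] = []
    nll_trace: list[float] = []
    converged = False
    n_iter = 0
    nll_prev = np.inf

    for n_iter in range(1, max_iterations + 1):
        # E-step: log posteriors with the uniform outlier component
        d2 = np.sum((Xn[None, :, :] - TY[:, None, :]) ** 2, axis=2)  # (M, N)
        log_gauss = -d2 / (2 * sigma2) - 0.5 * D * np.log(2 * np.pi * sigma2)
        log_mix = log_gauss + np.log((1.0 - w) / M)
        log_den = logsumexp(log_mix, axis=0)                          # (N,)
        if w > 0:
            log_out = np.log(w / N)
            log_den = np.logaddexp(log_den, log_out)
        nll = -float(np.sum(log_den))
        P = np.exp(log_mix - log_den[None, :])                        # (M, N)

        nll_trace.append(nll)

        # M-step: closed-form affine update
        P1 = P.sum(axis=1)          # (M,)
        Pt1 = P.sum(axis=0)         # (N,)
        Np = float(P1.sum())
        if Np < 1e-12:
            raise DegenerateGeometryError("posterior mass vanished")
        mu_xp = (Xn.T @ Pt1) / Np
        mu_yp = (Yn.T @ P1) / Np
        Xh = Xn - mu_xp
        Yh = Yn - mu_yp
        A1 = (Xh.T @ P.T) @ Yh                      # (D, D)
        A2 = (Yh.T * P1) @ Yh                       # (D, D)
        try:
            B = np.linalg.solve(A2.T, A1.T).T
        except np.linalg.LinAlgError as exc:
            raise DegenerateGeometryError("singular M-step update") from exc
        t = mu_xp - B @ mu_yp
        tr_xPx = float(np.sum(Pt1 * np.sum(Xh * Xh, axis=1)))
        sigma2 = (tr_xPx - float(np.trace(A1 @ B.T))) / (Np * D)
        sigma2 = max(sigma2, 1e-12)
        sigma2_trace.append(sigma2 * s * s)   # record in squared micrometres

        TY = Yn @ B.T + t

        if abs(nll_prev - nll) < tolerance:
            converged = True
            break
        nll_prev = nll

    # compose back to micrometre coordinates:
    # x ~ s * (B @ (y - mu_y)/s + t) + mu_x  =  B y + (mu_x + s t - B mu_y)
    B_full = B
    t_full = mu_x + s * t - B @ mu_y
    return (
        AffineTransform(B_full, t_full),
        sigma2_trace,
        nll_trace,
        n_iter,
        converged,
    )


# ---------------------------------------------------------------------------
# Correspondence

def map_nearest(
    transformed_source: np.ndarray,
    source_ids: list[str],
    reference: np.ndarray,
    reference_ids: list[str],
    one_to_one: bool = False,
) -> tuple[dict[str, str], dict[str, float]]:
    """Match each source cell to its Euclidean-nearest reference cell.

    Many-to-one by default (each source cell matched independently); exact
    distance ties break to the lexicographically smallest reference cell_id.
    With ``one_to_one`` a global Hungarian assignment is used instead.
    """
    S = np.asarray(transformed_source, float).reshape(-1, 3)
    R = np.asarray(reference, float).reshape(-1, 3)
    if len(S) == 0 or len(R) == 0:
        raise ValueError("empty point set")

    # order reference lexicographically so argmin resolves ties deterministically
    order = sorted(range(len(R)), key=lambda i: reference_ids[i])
    R_ord = R[order]
    ids_ord = [reference_ids[i] for i in order]
    d = np.sqrt(((S[:, None, :] - R_ord[None, :, :]) ** 2).sum(axis=2))

    correspondence: dict[str, str] = {}
    distances: dict[str, float] = {}
    if one_to_one:
        rows, cols = linear_sum_assignment(d)
        for i, j in zip(rows, cols):
            correspondence[source_ids[i]] = ids_ord[j]
            distances[source_ids[i]] = float(d[i, j])
    else:
        nearest = np.argmin(d, axis=1)  # first minimum = smallest id
        for i, j in enumerate(nearest):
            correspondence[source_ids[i]] = ids_ord[j]
            distances[source_ids[i]] = float(d[i, j])
    return correspondence, distances


# ---------------------------------------------------------------------------
# Full pipeline

def register_dataset(
    src: CentroidDataset,
    ref,
    params: RegistrationParams | None = None,
) -> LabeledAssignment:
    """Anchor rotation -> affine CPD -> nearest-neighbor label transfer.

    ``ref`` may be another :class:`CentroidDataset` or a
    :class:`CircuitFixture` (optionally restricted to ``params.target_classes``).
    Each source cell's label set is transferred to its matched reference cell;
    reference cells matched by several source cells accumulate the union of
    their labels with a multiplicity record; unmatched reference cells carry
    no call.
    """
    params = params or RegistrationParams()
    if not src.anchors:
        raise ConfigurationError(
            f"dataset {src.dataset_id!r} has no anchors; cannot register")
    ref_ids, ref_pts, _ = _reference_view(ref, params.target_classes)

    init = anchor_rotation(src, ref, params.anchor_names, params.target_classes)
    c_src = src.positions.mean(axis=0)
    c_ref = ref_pts.mean(axis=0)
    rotated = (src.positions - c_src) @ init.R.T + c_ref

    transform, sigma2_trace, nll_trace, n_iter, converged = cpd_affine_register(
        rotated, ref_pts,
        w=params.w,
        max_iterations=params.max_iterations,
        tolerance=params.tolerance,
    )
    moved = transform.apply(rotated)
    correspondence, distances = map_nearest(
        moved, src.cell_ids, ref_pts, ref_ids, one_to_one=params.one_to_one)

    # compose the rigid init into the reported affine so transform.apply on
    # the *original* source positions reproduces the registered cloud
    B_total = transform.B @ init.R
    t_total = (transform.B @ (c_ref - init.R @ c_src)) + transform.t
    result = RegistrationResult(
        init=init,
        transform=AffineTransform(B_total, t_total),
        sigma2_trace=sigma2_trace,
        nll_trace=nll_trace,
        n_iterations=n_iter,
        converged=converged,
        correspondence=correspondence,
        distances=distances,
    )

    labels: dict[str, frozenset[str]] = {}
    multiplicity: dict[str, int] = {}
    for cid, rid in correspondence.items():
        labels[rid] = labels.get(rid, frozenset()) | src.label_of(cid)
        multiplicity[rid] = multiplicity.get(rid, 0) + 1

    return LabeledAssignment(
        dataset_id=src.dataset_id,
        reference_ids=list(ref_ids),
        labels=labels,
        multiplicity=multiplicity,
        registration=result,
    )
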