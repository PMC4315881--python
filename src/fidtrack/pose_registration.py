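"""Marker labeling, rigid pose registration and needle-tip geometry.

Once the localizer returns an unordered set of 3D marker positions, the
instrument pose is recovered in three steps: (1) assign each observed
point to its counterpart on the nominal marker model, exploiting the fact
that the model's pairwise distances are all distinct by design; (2) fit
the proper rigid transform (rotation + translation, no reflection) that
minimizes the sum of squared distances between nominal and observed
points; (3) map the known needle geometry through the fitted transform.

For three markers the labeling rule is: the marker common to the two
largest pairwise distances is 'A', the other endpoint of the largest
distance is 'B', the remaining one is 'C'.  For more than three markers an
exhaustive search over permutations minimizes the squared mismatch of the
pairwise distance matrices (at most 720 permutations for six markers).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .errors import AmbiguousLabelingError, DegenerateConfigurationError

_DISTANCE_TIE_TOL = 1e-6


@dataclass(frozen=True)
class MarkerModel:
    """Nominal marker coordinates in the probe frame (mm).

    All pairwise distances must differ by more than 1e-6 mm; this is what
    makes the correspondence problem well-posed.
    """

    points: np.ndarray
    labels: tuple

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != len(pts):
            raise ValueError("one label per marker required")
        if len(pts) >= 2:
            d = np.sort(pdist(pts))
            if np.any(np.diff(d) <= _DISTANCE_TIE_TOL):
                raise AmbiguousLabelingError("marker model has tied pairwise distances")

    @property
    def n_markers(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflections are not rigid motions of a physical probe")

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


@dataclass(frozen=True)
class NeedleGeometry:
    """Needle tip offset and axis direction in the probe frame."""

    tip_offset: np.ndarray
    direction_offset: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "tip_offset", np.asarray(self.tip_offset, dtype=float).reshape(3))
        d = np.asarray(self.direction_offset, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("needle direction must be nonzero")
        object.__setattr__(self, "direction_offset", d / n)


def _abc_order(points: np.ndarray) -> np.ndarray:
    """Index order (A, B, C) of three points by the distance rule."""
    d = squareform(pdist(points))
    pairs = [(d[i, j], (i, j)) for i, j in itertools.combinations(range(3), 2)]
    pairs.sort(reverse=True)
    if pairs[0][0] - pairs[1][0] <= _DISTANCE_TIE_TOL or pairs[1][0] - pairs[2][0] <= _DISTANCE_TIE_TOL:
        raise AmbiguousLabelingError("tied pairwise distances; cannot apply the A/B/C rule")
    largest, second = set(pairs[0][1]), set(pairs[1][1])
    a = (largest & second).pop()
    b = (largest - {a}).pop()
    c = ({0, 1, 2} - {a, b}).pop()
    return np.array([a, b, c])


def label_markers(points, model: MarkerModel) -> np.ndarray:
    """Correspondence of observed points to model markers.

    Returns an index array ``order`` such that ``points[order[i]]``
    corresponds to ``model.points[i]``.  Three markers use the A/B/C
    largest-distance rule applied to both point sets; more markers use an
    exhaustive permutation search minimizing the squared difference
    between the pairwise distance matrices.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = model.n_markers
    if len(points) != n:
        raise ValueError(f"expected {n} points, got {len(points)}")
    if n < 3:
        raise ValueError("correspondence needs at least 3 markers")
    if n == 3:
        obs = _abc_order(points)
        nom = _abc_order(model.points)
        order = np.empty(3, dtype=int)
        order[nom] = obs
        return order
    d_model = squareform(pdist(model.points))
    d_obs = squareform(pdist(points))
    perms = np.array(list(itertools.permutations(range(n))))
    costs = ((d_obs[perms[:, :, None], perms[:, None, :]] - d_model[None]) ** 2).sum(axis=(1, 2))
    best = np.argsort(costs)
    if len(best) > 1 and costs[best[1]] - costs[best[0]] <= _DISTANCE_TIE_TOL:
        raise AmbiguousLabelingError("two permutations fit the distance profile equally well")
    return perms[best[0]]


def rigid_fit(source, target) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``source`` to ``target``.

    Solves the orthogonal Procrustes problem on centred coordinates with
    the reflection excluded (a physical probe cannot mirror) and reports
    the RMS residual.  Requires at least three non-collinear point pairs.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    tgt = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != tgt.shape or len(src) < 3:
        raise DegenerateConfigurationError("need >= 3 corresponding point pairs")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    src_c, tgt_c = src - sc, tgt - tc
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise DegenerateConfigurationError("collinear points cannot fix a rotation")
    rot, rssd = Rotation.align_vectors(tgt_c, src_c)
    R = rot.as_matrix()
    t = tc - R @ sc
    return RigidTransform(rotation=R, translation=t, residual_rms=float(rssd) / np.sqrt(len(src)))


def needle_tip(transform: RigidTransform, geometry: NeedleGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Needle tip position and axis direction in the scanner frame."""
    tip = transform.rotation @ geometry.tip_offset + transform.translation
    direction = transform.rotation @ geometry.direction_offset
    return tip, direction


def targeting_error(estimated_tip, true_tip) -> float:
    """Euclidean distance (mm) between estimated and true target point."""
    a = np.asarray(estimated_tip, dtype=float)
    b = np.asarray(true_tip, dtype=float)
    return float(np.linalg.norm(a - b))


def moving_average(stream, window: int = 5) -> np.ndarray:
    """Causal moving average of a position stream.

    Output ``k`` is the mean of the last ``window`` positions (or of the
    available prefix for the first ``window - 1`` samples).  Used to
    stabilize the displayed probe position at the cost of a small lag.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(stream, dtype=float)
    flat = x.reshape(len(x), -1)
    out = np.empty_like(flat)
    csum = np.cumsum(flat, axis=0)
    for k in range(len(flat)):
        lo = max(0, k - window + 1)
        total = csum[k] - (csum[lo - 1] if lo > 0 else 0.0)
        out[k] = total / (k - lo + 1)
    return out.reshape(x.shape)
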