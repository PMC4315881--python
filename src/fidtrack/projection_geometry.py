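"""Geometry of 1D projection directions and three-plane intersections.

A 1D MR projection measures, for each marker at position ``P`` (mm, scanner
frame), the scalar offset ``p = N . P`` along the unit projection direction
``N``.  Every detected peak therefore constrains the marker to the plane
``N . P = p``.  Three planes with non-coplanar normals intersect in a single
point

    P = [p1 (N2 x N3) + p2 (N3 x N1) + p3 (N1 x N2)] / det(N1, N2, N3)

and, because the map is linear in the offsets, peak-position errors dp
propagate into the reconstructed point as

    dP = [dp1 (N2 x N3) + dp2 (N3 x N1) + dp3 (N1 x N2)] / det(N1, N2, N3).

``|det|`` in the denominator makes well-spread direction triples the
accurate ones, which is why candidate triples are ranked by decreasing
``|det|`` and why the direction sets themselves are taken from the voxel
neighbourhoods of discrete geometry (the 6-, 18- and 26-neighbourhoods give
3, 9 and 13 regularly distributed projection lines after collapsing
antipodal offsets).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTripleError

#: Triples with |det| below this floor are unusable for plane intersection.
DEGENERACY_FLOOR = 1e-6

_LEVELS = (6, 18, 26)


@dataclass(frozen=True)
class DirectionTriple:
    """Three direction indices with the determinant of their 3x3 matrix.

    ``usable`` is False when ``|det_value|`` falls below
    :data:`DEGENERACY_FLOOR`; such triples are ranked last and must not be
    used for plane intersection.
    """

    indices: tuple[int, int, int]
    det_value: float
    usable: bool = True


@dataclass(frozen=True)
class ErrorEstimate:
    """First-order propagation of per-projection peak errors.

    ``delta_p`` are the three peak-position errors (mm along each
    direction); ``delta_P`` is the induced error on the intersected 3D
    point (mm, scanner frame).  The map is exactly linear.
    """

    delta_p: np.ndarray
    delta_P: np.ndarray


def canonical_direction(v) -> np.ndarray:
    """Normalize ``v`` to unit length and canonical sign.

    The canonical representative of the antipodal pair {v, -v} has its
    first nonzero component positive, so a projection *line* maps to a
    unique unit vector.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("zero vector has no direction")
    v = v / norm
    for component in v:
        if abs(component) > 1e-12:
            if component < 0:
                v = -v
            break
    return v


def neighbourhood_offsets(level: int) -> np.ndarray:
    """Integer voxel offsets for one representative of each projection line.

    Offsets are drawn from {-1, 0, 1}^3 \\ {0}; the 6-neighbourhood keeps
    the axis offsets, the 18-neighbourhood adds face diagonals and the
    26-neighbourhood adds cube diagonals.  Antipodal pairs are collapsed to
    the representative whose first nonzero component is positive.  Order is
    canonical: by neighbourhood class (axis, face diagonal, cube diagonal)
    then lexicographic on the integer offsets.
    """
    if level not in _LEVELS:
        raise ValueError(f"unsupported neighbourhood level {level!r}; expected one of {_LEVELS}")
    max_nonzero = {6: 1, 18: 2, 26: 3}[level]
    seen = set()
    reps = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        nnz = sum(1 for c in off if c != 0)
        if nnz > max_nonzero:
            continue
        # canonical antipodal representative: first nonzero component positive
        for c in off:
            if c != 0:
                rep = off if c > 0 else tuple(-x for x in off)
                break
        if rep not in seen:
            seen.add(rep)
            reps.append(rep)
    reps.sort(key=lambda o: (sum(1 for c in o if c != 0), o))
    return np.array(reps, dtype=int)


def neighbourhood_directions(level: int) -> np.ndarray:
    """Unit projection directions of a voxel neighbourhood.

    Returns an ``(m, 3)`` array with m = 3, 9 or 13 for levels 6, 18 and
    26.  Rows are unit-norm, canonically signed and in the deterministic
    canonical order of :func:`neighbourhood_offsets`.
    """
    offsets = neighbourhood_offsets(level).astype(float)
    return offsets / np.linalg.norm(offsets, axis=1, keepdims=True)


def enumerate_triples(directions) -> list[DirectionTriple]:
    """All C(n, 3) index triples ranked by decreasing ``|det|``.

    Ties are broken by lexicographic index order.  Triples whose ``|det|``
    falls below :data:`DEGENERACY_FLOOR` are flagged unusable and placed at
    the end of the list.
    """
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    n = len(directions)
    if n < 3:
        raise ValueError("need at least 3 directions to form a triple")
    combos = list(itertools.combinations(range(n), 3))
    mats = directions[np.array(combos)]
    dets = np.linalg.det(mats)
    triples = [
        DirectionTriple(indices=c, det_value=float(d), usable=bool(abs(d) >= DEGENERACY_FLOOR))
        for c, d in zip(combos, dets)
    ]
    triples.sort(key=lambda t: (not t.usable, -abs(t.det_value), t.indices))
    return triples


def _cross_matrix(directions: np.ndarray) -> tuple[np.ndarray, float]:
    n1, n2, n3 = directions
    det = float(np.linalg.det(directions))
    crosses = np.stack([np.cross(n2, n3), np.cross(n3, n1), np.cross(n1, n2)])
    return crosses, det


def intersect_planes(directions, offsets) -> np.ndarray:
    """Intersection point of three planes ``N_k . P = p_k``.

    ``directions`` is a (3, 3) array of unit normals (rows), ``offsets``
    the three plane offsets in mm.  Raises
    :class:`~fidtrack.errors.DegenerateTripleError` when the normals are
    near-coplanar (``|det|`` below :data:`DEGENERACY_FLOOR`).
    """
    directions = np.asarray(directions, dtype=float).reshape(3, 3)
    offsets = np.asarray(offsets, dtype=float).reshape(3)
    crosses, det = _cross_matrix(directions)
    if abs(det) < DEGENERACY_FLOOR:
        raise DegenerateTripleError(f"near-coplanar normals, |det| = {abs(det):.3e}")
    return offsets @ crosses / det


def propagate_error(directions, delta_p) -> ErrorEstimate:
    """First-order error on the intersection point for peak errors ``delta_p``.

    Exactly linear: equals ``intersect_planes(directions, p + delta_p) -
    intersect_planes(directions, p)`` for any offsets ``p``.
    """
    directions = np.asarray(directions, dtype=float).reshape(3, 3)
    delta_p = np.asarray(delta_p, dtype=float).reshape(3)
    crosses, det = _cross_matrix(directions)
    if abs(det) < DEGENERACY_FLOOR:
        raise DegenerateTripleError(f"near-coplanar normals, |det| = {abs(det):.3e}")
    return ErrorEstimate(delta_p=delta_p, delta_P=delta_p @ crosses / det)
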