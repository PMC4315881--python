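"""Candidate generation and fictitious-point elimination.

The localization algorithm for N markers seen in n 1D projections:

1. pick three *reference* projections -- walking the determinant-ranked
   triple list, the first triple in which every projection shows exactly N
   distinct peaks separated by more than a threshold ``d``;
2. intersect every combination of one peak plane per reference projection,
   producing N^3 candidate points of which N^3 - N are fictitious;
3. order the remaining *test* projections by decreasing minimum peak
   separation, projections with fewer than N peaks last;
4. for each test projection in turn, project every candidate onto its
   direction and discard candidates whose projected value is farther than a
   tolerance ``epsilon`` from every detected peak.  When a test projection
   carries fewer than N peaks (merged peaks), the tolerance is enlarged to
   ``epsilon_merged`` (two pixels by default) so that merged peaks cannot
   eliminate true points.

The solution is accepted only if exactly N candidates survive; otherwise
the whole frame is discarded (``success`` is False).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateTripleError, NoReferenceFoundError
from .projection_geometry import (
    DEGENERACY_FLOOR,
    DirectionTriple,
    enumerate_triples,
)

_DEFAULT_PIXEL_MM = 300.0 / 320  # 0.9375 mm: 300 mm FOV over 320 samples

#: Surviving candidates closer than this are considered the same point.
DEDUP_TOL_MM = 1e-6


@dataclass(frozen=True)
class ProjectionPeaks:
    """Peak positions detected along one projection direction."""

    direction: np.ndarray
    positions: np.ndarray
    pixel_size: float = _DEFAULT_PIXEL_MM

    def __post_init__(self):
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        pos = np.sort(np.asarray(self.positions, dtype=float).ravel())
        object.__setattr__(self, "positions", pos)

    @classmethod
    def from_peaks(cls, direction, peaks, pixel_size: float = _DEFAULT_PIXEL_MM):
        return cls(direction=direction, positions=[p.position for p in peaks], pixel_size=pixel_size)

    @property
    def n_peaks(self) -> int:
        return len(self.positions)

    def min_separation(self) -> float:
        """Smallest gap between two peaks; +inf with fewer than two peaks."""
        if self.n_peaks < 2:
            return np.inf
        return float(np.min(np.diff(self.positions)))


@dataclass
class LocalizationConfig:
    """Tolerances of the elimination stage.

    ``epsilon`` is the vicinity tolerance for a candidate to survive a test
    projection; the default is ten peak-position standard deviations
    (sigma_peak = 0.08 mm), which absorbs the stochastic spread of peak
    estimates.  ``epsilon_merged`` replaces it on test projections with
    fewer than N peaks (default two pixels, the scale at which peaks
    merge).  ``min_peak_separation_d`` is the minimum intra-projection peak
    distance required of a reference projection.
    """

    n_markers: int
    epsilon: float = 0.8
    epsilon_merged: float = 2 * _DEFAULT_PIXEL_MM
    min_peak_separation_d: float = 2 * _DEFAULT_PIXEL_MM

    def __post_init__(self):
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.epsilon_merged < self.epsilon:
            raise ValueError("epsilon_merged must be >= epsilon")


@dataclass
class LocalizationResult:
    """Outcome of one localization attempt."""

    points: np.ndarray
    success: bool
    reference_triple: DirectionTriple | None
    n_candidates_initial: int
    eliminations_per_test: list[int] = field(default_factory=list)
    n_zero_peak_tests: int = 0
    failure_reason: str | None = None


class RankedTriples:
    """Determinant-ranked triples of a direction set with cached inverses.

    The inverse of the row matrix ``A = [N1; N2; N3]`` maps plane offsets
    to the intersection point (``P = A^-1 p``); caching it makes repeated
    candidate generation cheap.
    """

    def __init__(self, directions):
        self.directions = np.atleast_2d(np.asarray(directions, dtype=float))
        self.triples = enumerate_triples(self.directions)
        self.indices = np.array([t.indices for t in self.triples], dtype=int)
        self.usable = np.array([t.usable for t in self.triples], dtype=bool)
        self.n_usable = int(self.usable.sum())
        mats = self.directions[self.indices[: self.n_usable]]
        self.inverses = np.linalg.inv(mats) if self.n_usable else np.empty((0, 3, 3))

    def __len__(self):
        return len(self.triples)


def select_reference(peaksets, ranked_triples, config: LocalizationConfig) -> DirectionTriple:
    """First ranked triple whose three projections all qualify.

    A projection qualifies when it has exactly N distinct peaks and its
    minimum pairwise peak distance exceeds ``min_peak_separation_d``
    (well-separated peaks give well-distributed candidates).  Raises
    :class:`~fidtrack.errors.NoReferenceFoundError` when no triple
    qualifies.
    """
    triples = ranked_triples.triples if isinstance(ranked_triples, RankedTriples) else ranked_triples
    valid = _valid_mask(peaksets, config)
    for triple in triples:
        if not triple.usable:
            break
        i, j, k = triple.indices
        if valid[i] and valid[j] and valid[k]:
            return triple
    raise NoReferenceFoundError(
        "no direction triple has three projections with "
        f"exactly {config.n_markers} well-separated peaks"
    )


def _valid_mask(peaksets, config: LocalizationConfig) -> np.ndarray:
    n = config.n_markers
    d = config.min_peak_separation_d
    return np.array(
        [ps.n_peaks == n and (n < 2 or ps.min_separation() > d) for ps in peaksets],
        dtype=bool,
    )


def generate_candidates(ref_peaksets, triple: DirectionTriple, inverse=None) -> np.ndarray:
    """All one-peak-per-projection plane intersections (N^3 points).

    ``ref_peaksets`` are the three reference projections in the order of
    ``triple.indices``; ``inverse`` may supply the precomputed inverse of
    the direction matrix.
    """
    if not triple.usable or abs(triple.det_value) < DEGENERACY_FLOOR:
        raise DegenerateTripleError("reference triple is degenerate")
    if inverse is None:
        mat = np.stack([ps.direction for ps in ref_peaksets])
        inverse = np.linalg.inv(mat)
    p1, p2, p3 = (ps.positions for ps in ref_peaksets)
    grid = np.stack(np.meshgrid(p1, p2, p3, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid @ inverse.T


def order_test_projections(remaining, n_markers: int) -> list:
    """Test projections sorted by decreasing minimum peak separation.

    Projections with fewer than N peaks (possible merged peaks) are
    appended last, in their input order, so that they are least likely to
    influence the elimination.
    """
    full = [(idx, ps) for idx, ps in enumerate(remaining) if ps.n_peaks >= n_markers]
    short = [(idx, ps) for idx, ps in enumerate(remaining) if ps.n_peaks < n_markers]
    full.sort(key=lambda item: (-item[1].min_separation(), item[0]))
    return [ps for _, ps in full] + [ps for _, ps in short]


def eliminate(candidates, test: ProjectionPeaks, config: LocalizationConfig) -> np.ndarray:
    """Keep candidates with a detected peak within tolerance on ``test``.

    The tolerance is ``epsilon`` when the test projection carries at least
    N peaks and ``epsilon_merged`` otherwise.  A projection with zero peaks
    eliminates nothing (it vacuously passes every candidate).
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if test.n_peaks == 0 or len(candidates) == 0:
        return candidates
    tol = config.epsilon if test.n_peaks >= config.n_markers else config.epsilon_merged
    projected = candidates @ test.direction
    dist = np.min(np.abs(projected[:, None] - test.positions[None, :]), axis=1)
    return candidates[dist <= tol]


def deduplicate_points(points, tol: float = DEDUP_TOL_MM) -> np.ndarray:
    """Collapse points closer than ``tol`` (mm) to a single representative."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        return points
    keep = np.ones(len(points), dtype=bool)
    for i in range(len(points)):
        if not keep[i]:
            continue
        d = np.linalg.norm(points[i + 1 :] - points[i], axis=1)
        keep[i + 1 :] &= d > tol
    return points[keep]


def localize(peaksets, config: LocalizationConfig, ranked_triples=None) -> LocalizationResult:
    """Full pipeline: reference selection, candidates, elimination, verdict.

    ``peaksets`` is one :class:`ProjectionPeaks` per acquired projection
    (at least four for N >= 2: three reference plus one test).
    ``ranked_triples`` may be a precomputed :class:`RankedTriples` over the
    same directions (in the same order); it is rebuilt otherwise.  Failures
    are reported through the ``success`` flag, never as exceptions.
    """
    peaksets = list(peaksets)
    if ranked_triples is None:
        ranked_triples = RankedTriples([ps.direction for ps in peaksets])
    elif not isinstance(ranked_triples, RankedTriples):
        ranked = RankedTriples.__new__(RankedTriples)
        ranked.directions = np.stack([ps.direction for ps in peaksets])
        ranked.triples = list(ranked_triples)
        ranked.indices = np.array([t.indices for t in ranked.triples], dtype=int)
        ranked.usable = np.array([t.usable for t in ranked.triples], dtype=bool)
        ranked.n_usable = int(ranked.usable.sum())
        mats = ranked.directions[ranked.indices[: ranked.n_usable]]
        ranked.inverses = np.linalg.inv(mats) if ranked.n_usable else np.empty((0, 3, 3))
        ranked_triples = ranked

    valid = _valid_mask(peaksets, config)
    qualifying = valid[ranked_triples.indices].all(axis=1) & ranked_triples.usable
    ranks = np.nonzero(qualifying)[0]
    if len(ranks) == 0:
        return LocalizationResult(
            points=np.empty((0, 3)),
            success=False,
            reference_triple=None,
            n_candidates_initial=0,
            failure_reason="no qualifying reference triple",
        )
    rank = int(ranks[0])
    reference = ranked_triples.triples[rank]
    inverse = ranked_triples.inverses[rank] if rank < ranked_triples.n_usable else None
    ref_sets = [peaksets[i] for i in reference.indices]
    candidates = generate_candidates(ref_sets, reference, inverse=inverse)
    n_initial = len(candidates)

    remaining = [ps for i, ps in enumerate(peaksets) if i not in reference.indices]
    tests = order_test_projections(remaining, config.n_markers)
    eliminations = []
    n_zero = 0
    for test in tests:
        if test.n_peaks == 0:
            n_zero += 1
            eliminations.append(0)
            continue
        before = len(candidates)
        candidates = eliminate(candidates, test, config)
        eliminations.append(before - len(candidates))

    points = deduplicate_points(candidates)
    order = np.lexsort((points[:, 2], points[:, 1], points[:, 0])) if len(points) else []
    points = points[order] if len(points) else points
    success = len(points) == config.n_markers
    return LocalizationResult(
        points=points,
        success=success,
        reference_triple=reference,
        n_candidates_initial=n_initial,
        eliminations_per_test=eliminations,
        n_zero_peak_tests=n_zero,
        failure_reason=None if success else f"{len(points)} candidates survived, expected {config.n_markers}",
    )
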