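import itertools

import numpy as np
import pytest

from fidtrack.errors import NoReferenceFoundError
from fidtrack.localizer import (
    LocalizationConfig,
    ProjectionPeaks,
    RankedTriples,
    deduplicate_points,
    eliminate,
    generate_candidates,
    localize,
    order_test_projections,
    select_reference,
)
from fidtrack.monte_carlo import direction_subset, place_markers, project_markers
from fidtrack.monte_carlo import RobustnessConfig
from fidtrack.projection_geometry import neighbourhood_directions

PX = 300.0 / 320


def _peaksets(markers, directions, noise=None):
    markers = np.atleast_2d(markers)
    values = directions @ markers.T
    if noise is not None:
        values = values + noise
    return [ProjectionPeaks(direction=d, positions=row) for d, row in zip(directions, values)]


def test_select_reference_returns_top_triple_when_all_clean(rng):
    dirs = neighbourhood_directions(26)
    markers = np.array([[50.0, -40.0, 30.0], [-60.0, 70.0, -20.0], [10.0, 20.0, 90.0]])
    peaksets = _peaksets(markers, dirs)
    ranked = RankedTriples(dirs)
    triple = select_reference(peaksets, ranked, LocalizationConfig(n_markers=3))
    assert triple.indices == ranked.triples[0].indices
    assert abs(triple.det_value) == pytest.approx(1.0)


def test_select_reference_skips_projection_with_missing_peak():
    dirs = neighbourhood_directions(26)
    markers = np.array([[50.0, -40.0, 30.0], [-60.0, 70.0, -20.0], [10.0, 20.0, 90.0]])
    peaksets = _peaksets(markers, dirs)
    top = RankedTriples(dirs).triples[0]
    broken = top.indices[0]
    peaksets[broken] = ProjectionPeaks(
        direction=peaksets[broken].direction, positions=peaksets[broken].positions[:2]
    )
    config = LocalizationConfig(n_markers=3)
    triple = select_reference(peaksets, RankedTriples(dirs), config)
    assert broken not in triple.indices
    # oracle: first ranked triple avoiding the broken projection
    for t in RankedTriples(dirs).triples:
        if broken not in t.indices:
            assert triple.indices == t.indices
            break


def test_select_reference_fails_when_all_projections_short():
    dirs = neighbourhood_directions(26)
    peaksets = [ProjectionPeaks(direction=d, positions=[0.0, 10.0]) for d in dirs]
    with pytest.raises(NoReferenceFoundError):
        select_reference(peaksets, RankedTriples(dirs), LocalizationConfig(n_markers=3))


@pytest.mark.parametrize("n_markers,expected", [(1, 1), (2, 8), (3, 27)])
def test_candidate_counts_are_n_cubed(n_markers, expected, rng):
    dirs = np.eye(3)
    markers = rng.uniform(-100, 100, (n_markers, 3))
    peaksets = _peaksets(markers, dirs)
    triple = RankedTriples(dirs).triples[0]
    candidates = generate_candidates([peaksets[i] for i in triple.indices], triple)
    assert len(candidates) == expected


def test_candidates_on_orthogonal_axes_form_cartesian_grid(rng):
    dirs = np.eye(3)
    markers = rng.uniform(-100, 100, (3, 3))
    peaksets = _peaksets(markers, dirs)
    triple = RankedTriples(dirs).triples[0]
    candidates = generate_candidates([peaksets[i] for i in triple.indices], triple)
    xs, ys, zs = (np.sort(peaksets[i].positions) for i in range(3))
    grid = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    got = candidates[np.lexsort((candidates[:, 2], candidates[:, 1], candidates[:, 0]))]
    want = grid[np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0]))]
    assert np.allclose(got, want, atol=1e-9)


def test_order_test_projections_by_min_separation():
    d = np.eye(3)
    a = ProjectionPeaks(direction=d[0], positions=[0.0, 5.0, 50.0])
    b = ProjectionPeaks(direction=d[1], positions=[0.0, 12.0, 50.0])
    c = ProjectionPeaks(direction=d[2], positions=[0.0, 3.0, 50.0])
    short = ProjectionPeaks(direction=d[0], positions=[0.0, 40.0])  # N-1 peaks
    ordered = order_test_projections([a, short, b, c], n_markers=3)
    assert [o.min_separation() for o in ordered[:3]] == [12.0, 5.0, 3.0]
    assert ordered[3] is short
    assert order_test_projections([], 3) == []


def test_eliminate_vicinity_rule():
    config = LocalizationConfig(n_markers=2, epsilon=0.5)
    test = ProjectionPeaks(direction=[1.0, 0, 0], positions=[10.0, 40.0])
    candidates = np.array([[10.0, 5.0, 5.0], [10.4, 0.0, 0.0], [20.0, 0.0, 0.0]])
    kept = eliminate(candidates, test, config)
    assert np.allclose(kept, candidates[:2])
    # zero-peak projection eliminates nothing
    empty = ProjectionPeaks(direction=[1.0, 0, 0], positions=[])
    assert len(eliminate(candidates, empty, config)) == 3


def test_eliminate_uses_enlarged_tolerance_on_short_projection():
    config = LocalizationConfig(n_markers=2, epsilon=0.1, epsilon_merged=2 * PX)
    test = ProjectionPeaks(direction=[1.0, 0, 0], positions=[10.0])  # < N peaks
    candidates = np.array([[11.0, 0.0, 0.0], [14.0, 0.0, 0.0]])
    kept = eliminate(candidates, test, config)
    assert np.allclose(kept, candidates[:1])


def test_fourth_projection_eliminates_four_of_eight_candidates():
    """Two markers, three orthogonal reference projections (8 candidates),
    one diagonal test projection: 4 fictitious points are eliminated."""
    markers = np.array([[20.0, 30.0, 40.0], [-50.0, 10.0, -30.0]])
    dirs = np.eye(3)
    peaksets = _peaksets(markers, dirs)
    triple = RankedTriples(dirs).triples[0]
    candidates = generate_candidates([peaksets[i] for i in triple.indices], triple)
    assert len(candidates) == 8
    test_dir = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    test = ProjectionPeaks(direction=test_dir, positions=markers @ test_dir)
    kept = eliminate(candidates, test, LocalizationConfig(n_markers=2, epsilon=0.5))
    assert len(kept) == 4


def test_localize_two_markers_five_projections_exact():
    markers = np.array([[20.0, 30.0, 40.0], [-50.0, 10.0, -30.0]])
    dirs = direction_subset(5)
    peaksets = _peaksets(markers, dirs)
    result = localize(peaksets, LocalizationConfig(n_markers=2, epsilon=1e-6))
    assert result.success
    assert result.n_candidates_initial == 8
    d = np.linalg.norm(result.points[:, None] - markers[None], axis=2)
    assert np.sort(d.min(axis=1)).max() < 1e-9


@pytest.mark.parametrize("n_markers", [3, 4, 5, 6])
def test_localize_exact_recovery_zero_noise(n_markers):
    cfg = RobustnessConfig(n_markers=n_markers, n_projections=13, sigma_peak=0.0, n_trials=1)
    rng = np.random.default_rng(99 + n_markers)
    markers = place_markers(cfg, rng)
    peaksets = project_markers(markers, direction_subset(13), 0.0, rng)
    result = localize(peaksets, cfg.localization_config())
    assert result.success
    d = np.linalg.norm(result.points[:, None] - markers[None], axis=2)
    assert d.min(axis=1).max() < 1e-9


def test_localize_failure_is_flagged_not_raised():
    dirs = neighbourhood_directions(26)
    peaksets = [ProjectionPeaks(direction=d, positions=[0.0]) for d in dirs]
    result = localize(peaksets, LocalizationConfig(n_markers=3))
    assert not result.success
    assert result.reference_triple is None
    assert len(result.points) == 0


def test_true_points_survive_when_errors_within_tolerance(rng):
    """Soundness: when the peak errors are small enough that the
    reference-amplified candidate error stays below epsilon on every test
    projection, no true marker is ever eliminated."""
    dirs = direction_subset(7)
    config = LocalizationConfig(n_markers=3, epsilon=0.8)
    bound = config.epsilon / 8
    checked = 0
    for trial in range(100):
        cfg = RobustnessConfig(n_markers=3, volume_halfwidth=100.0, seed=trial)
        markers = place_markers(cfg, rng)
        noise = rng.uniform(-bound, bound, (7, 3))
        peaksets = _peaksets(markers, dirs, noise=noise)
        result = localize(peaksets, config)
        if result.reference_triple is None:
            continue
        inv = np.linalg.inv(dirs[list(result.reference_triple.indices)])
        worst = np.linalg.norm(inv, 2) * np.sqrt(3) * bound + bound
        if worst > config.epsilon:
            continue  # conditioning too poor for the guarantee to apply
        checked += 1
        assert len(result.points) >= 3
        d = np.linalg.norm(result.points[:, None] - markers[None], axis=2)
        assert d.min(axis=0).max() <= worst + 1e-9
    assert checked > 50


def test_localize_matches_exhaustive_elimination_oracle(rng):
    """The surviving set equals a brute-force filter of all N^3 candidates
    against every test projection, over 1000 random instances."""
    for _ in range(1000):
        n_markers = int(rng.integers(2, 5))
        n_proj = int(rng.integers(5, 8))
        dirs = direction_subset(n_proj)
        markers = rng.uniform(-120, 120, (n_markers, 3))
        sigma = 0.05
        noise = rng.normal(0, sigma, (n_proj, n_markers))
        peaksets = _peaksets(markers, dirs, noise=noise)
        config = LocalizationConfig(n_markers=n_markers, epsilon=10 * sigma)
        result = localize(peaksets, config)
        if result.reference_triple is None:
            continue
        # independent oracle: re-derive candidates with a linear solver and
        # intersect the vicinity filters of all test projections at once
        ref = result.reference_triple.indices
        mat = dirs[list(ref)]
        survivors = []
        for combo in itertools.product(*(peaksets[i].positions for i in ref)):
            point = np.linalg.solve(mat, np.array(combo))
            ok = True
            for j, ps in enumerate(peaksets):
                if j in ref or ps.n_peaks == 0:
                    continue
                tol = config.epsilon if ps.n_peaks >= n_markers else config.epsilon_merged
                if np.min(np.abs(point @ ps.direction - ps.positions)) > tol:
                    ok = False
                    break
            if ok:
                survivors.append(point)
        survivors = np.array(survivors) if survivors else np.empty((0, 3))
        assert len(survivors) == len(result.points)
        assert result.success == (len(survivors) == n_markers)
        if len(survivors):
            order = np.lexsort((survivors[:, 2], survivors[:, 1], survivors[:, 0]))
            assert np.allclose(survivors[order], result.points, atol=1e-9)


def test_deduplicate_points_collapses_near_duplicates():
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1e-8], [1.0, 0.0, 0.0]])
    assert len(deduplicate_points(pts)) == 2


def test_eliminations_diagnostics_are_consistent():
    markers = np.array([[20.0, 30.0, 40.0], [-50.0, 10.0, -30.0], [70.0, -60.0, 15.0]])
    dirs = direction_subset(13)
    result = localize(_peaksets(markers, dirs), LocalizationConfig(n_markers=3, epsilon=1e-6))
    assert result.n_candidates_initial == 27
    assert all(e >= 0 for e in result.eliminations_per_test)
    assert sum(result.eliminations_per_test) == 27 - len(result.points)
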