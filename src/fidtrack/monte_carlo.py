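"""Monte Carlo verification studies of the localization pipeline.

Three studies mirror the verification protocol of the method:

* **robustness** -- random sets of N markers (uniform in a cube, at least
  30 mm apart) are projected onto n directions with Gaussian peak noise
  (sigma_peak = 0.08 mm by default) and localized; the success rate as a
  function of N (3..6) and n (5..13) quantifies robustness;
* **accuracy** -- the same protocol on a grid of (n, sigma_peak) values,
  reporting the maximum and mean localization error over successful
  trials;
* **targeting** -- a synthetic biopsy probe carrying 3..6 markers is
  rotated randomly (30-80 degrees in the sagittal plane, +/-25 degrees in
  the coronal plane), its markers are localized, labeled and rigidly
  fitted to the nominal model, and the needle-tip error measures how peak
  noise propagates to the instrument's point of interest.

Peak merging is emulated at the peak-list level: projected positions
closer than two pixels collapse into a single peak, so some projections
carry fewer than N peaks exactly as in acquired data.

Direction subsets for n < 13 are deterministic prefixes of a greedy
max-min-angle ordering of the 13-direction set, so subsets are nested and
regularly spread.  All randomness flows from a single integer seed through
per-trial generators, which makes every study bit-reproducible and couples
trials across study cells (common random numbers) so that the tabulated
trends are not drowned by Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import InfeasibleConfigurationError
from .localizer import LocalizationConfig, ProjectionPeaks, RankedTriples, localize
from .pose_registration import MarkerModel, NeedleGeometry, label_markers, needle_tip, rigid_fit, targeting_error
from .projection_geometry import neighbourhood_directions

_PIXEL_MM = 300.0 / 320
_MAX_MARKERS = 6
_MAX_REJECTIONS = 100_000


@dataclass
class RobustnessConfig:
    """Conditions of a robustness/accuracy study cell."""

    n_markers: int = 3
    n_projections: int = 13
    sigma_peak: float = 0.08
    n_trials: int = 10_000
    min_separation: float = 30.0
    volume_halfwidth: float = 150.0
    seed: int = 0
    pixel_size: float = _PIXEL_MM
    merging: bool = True

    def __post_init__(self):
        if not 1 <= self.n_markers <= _MAX_MARKERS:
            raise ValueError(f"n_markers must be in 1..{_MAX_MARKERS}")
        if self.n_projections < 5:
            raise ValueError("need at least 5 projections")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")

    def localization_config(self) -> LocalizationConfig:
        """Tolerances implied by the study conditions: epsilon = 10 sigma_peak,
        merged tolerance and reference separation d both two pixels."""
        eps = 10.0 * self.sigma_peak if self.sigma_peak > 0 else 1e-6
        return LocalizationConfig(
            n_markers=self.n_markers,
            epsilon=eps,
            epsilon_merged=max(eps, 2.0 * self.pixel_size),
            min_peak_separation_d=2.0 * self.pixel_size,
        )


@dataclass
class TargetingConfig:
    """Conditions of a targeting-error study."""

    marker_model: MarkerModel
    needle: NeedleGeometry
    sagittal_rotation_range: tuple = (30.0, 80.0)
    coronal_rotation_range: tuple = (-25.0, 25.0)
    sigma_peak: float = 0.08
    n_trials: int = 3_000
    n_projections: int = 13
    seed: int = 0
    pixel_size: float = _PIXEL_MM
    merging: bool = True


@dataclass
class StudyResult:
    """Summary of one Monte Carlo study cell."""

    success_rate: float
    max_error: float
    mean_error: float
    error_sd: float
    n_trials: int
    n_successes: int
    config: object = None


@lru_cache(maxsize=16)
def direction_subset(n: int) -> np.ndarray:
    """First ``n`` directions of a greedy max-min-angle ordering of the 13.

    Starting from the canonical first axis, each step appends the direction
    maximizing the minimal angle to those already chosen (ties broken by
    canonical order).  Prefixes are therefore nested and well spread --
    e.g. the 5-direction set is the three axes plus two cube diagonals.
    """
    dirs = neighbourhood_directions(26)
    if not 1 <= n <= len(dirs):
        raise ValueError(f"n must be in 1..{len(dirs)}")
    chosen = [0]
    remaining = list(range(1, len(dirs)))
    while len(chosen) < n:
        best, best_angle = None, -1.0
        for idx in remaining:
            cosines = np.abs(dirs[chosen] @ dirs[idx])
            min_angle = float(np.min(np.arccos(np.clip(cosines, 0.0, 1.0))))
            if min_angle > best_angle + 1e-12:
                best, best_angle = idx, min_angle
        chosen.append(best)
        remaining.remove(best)
    out = dirs[chosen]
    out.setflags(write=False)
    return out


@lru_cache(maxsize=16)
def _ranked_for(n: int) -> RankedTriples:
    return RankedTriples(direction_subset(n))


def place_markers(config: RobustnessConfig, rng) -> np.ndarray:
    """Uniform markers in the cube, rejection-sampled to min separation.

    Points are drawn one at a time so that, for a fixed seed, the first
    N points of an (N+1)-marker placement coincide with the N-marker
    placement (common random numbers across marker counts).
    """
    half = config.volume_halfwidth
    points = np.empty((config.n_markers, 3))
    placed = 0
    rejections = 0
    while placed < config.n_markers:
        candidate = rng.uniform(-half, half, 3)
        if placed == 0 or np.min(np.linalg.norm(points[:placed] - candidate, axis=1)) >= config.min_separation:
            points[placed] = candidate
            placed += 1
            rejections = 0
        else:
            rejections += 1
            if rejections > _MAX_REJECTIONS:
                raise InfeasibleConfigurationError(
                    f"cannot place {config.n_markers} markers {config.min_separation} mm apart"
                )
    return points


def _merge_positions(positions: np.ndarray, threshold: float) -> np.ndarray:
    """Collapse peak positions closer than ``threshold`` into one peak.

    Emulates spectral peak merging: positions are clustered by gaps below
    the threshold and each cluster is represented by its centroid -- the
    superposition of two comparable Gaussian peaks has its single maximum
    between the component centres, so every merged marker stays within
    half the merge distance of the surviving peak.
    """
    positions = np.sort(positions)
    if len(positions) < 2:
        return positions
    clusters = [[positions[0]]]
    for p in positions[1:]:
        if p - clusters[-1][-1] < threshold:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return np.array([float(np.mean(c)) for c in clusters])


def project_markers(markers, directions, sigma_peak, rng, pixel_size: float = _PIXEL_MM,
                    merging: bool = True, noise=None) -> list[ProjectionPeaks]:
    """Noisy peak lists for each direction.

    Peak positions are ``N_k . P_i`` plus i.i.d. Gaussian errors of
    standard deviation ``sigma_peak``; positions closer than two pixels
    merge into a single peak when ``merging`` is on.  ``noise`` may supply
    a pre-drawn ``(n_directions, n_markers)`` error array (used by the
    studies for common random numbers); otherwise it is drawn from ``rng``.
    """
    markers = np.atleast_2d(np.asarray(markers, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    values = directions @ markers.T
    if noise is None:
        noise = rng.normal(0.0, sigma_peak, values.shape) if sigma_peak > 0 else 0.0
    values = values + noise
    out = []
    for row, direction in zip(values, directions):
        positions = _merge_positions(row, 2.0 * pixel_size) if merging else np.sort(row)
        out.append(ProjectionPeaks(direction=direction, positions=positions, pixel_size=pixel_size))
    return out


def _match_errors(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-marker distances under minimum-cost assignment."""
    d = cdist(estimated, truth)
    rows, cols = linear_sum_assignment(d)
    return d[rows, cols]


def run_robustness_study(config: RobustnessConfig) -> StudyResult:
    """Success rate and localization error over repeated random marker sets.

    Each trial places markers, projects them with noise (drawn once for
    the full 13-direction set and sliced, so results for different
    ``n_projections`` share trials), localizes, and on success measures
    per-marker errors after minimum-cost matching to the truth.
    """
    directions = direction_subset(config.n_projections)
    ranked = _ranked_for(config.n_projections)
    loc_config = config.localization_config()
    n_success = 0
    errors = []
    max_error = 0.0
    for trial in range(config.n_trials):
        marker_rng = np.random.default_rng([config.seed, trial, 0])
        noise_rng = np.random.default_rng([config.seed, trial, 1])
        markers = place_markers(config, marker_rng)
        noise = noise_rng.normal(0.0, config.sigma_peak, (13, _MAX_MARKERS)) if config.sigma_peak > 0 else np.zeros((13, _MAX_MARKERS))
        peaksets = project_markers(
            markers, directions, config.sigma_peak, noise_rng,
            pixel_size=config.pixel_size, merging=config.merging,
            noise=noise[: config.n_projections, : config.n_markers],
        )
        result = localize(peaksets, loc_config, ranked_triples=ranked)
        if result.success:
            n_success += 1
            e = _match_errors(result.points, markers)
            errors.extend(e)
            max_error = max(max_error, float(e.max()))
    errors = np.asarray(errors)
    return StudyResult(
        success_rate=100.0 * n_success / config.n_trials,
        max_error=max_error,
        mean_error=float(errors.mean()) if len(errors) else 0.0,
        error_sd=float(errors.std(ddof=1)) if len(errors) > 1 else 0.0,
        n_trials=config.n_trials,
        n_successes=n_success,
        config=config,
    )


def run_error_study(base: RobustnessConfig, n_projections_list=(5, 7, 10, 13),
                    sigma_list=(0.05,)) -> pd.DataFrame:
    """Grid of robustness cells over projection counts and noise levels."""
    rows = []
    for sigma in sigma_list:
        for n_proj in n_projections_list:
            cell = replace(base, n_projections=n_proj, sigma_peak=sigma)
            res = run_robustness_study(cell)
            rows.append(
                {
                    "n_markers": cell.n_markers,
                    "n_projections": n_proj,
                    "sigma_peak": sigma,
                    "success_rate": res.success_rate,
                    "max_error": res.max_error,
                    "mean_error": res.mean_error,
                    "error_sd": res.error_sd,
                    "n_trials": res.n_trials,
                }
            )
    return pd.DataFrame(rows)


def robustness_table(n_markers_list=(3, 4, 5, 6), n_projections_list=(5, 7, 10, 13),
                     sigma_peak: float = 0.08, n_trials: int = 10_000, seed: int = 0,
                     merging: bool = True) -> pd.DataFrame:
    """Success-rate table: one row per marker count, one column per
    projection count (the robustness study on the full grid)."""
    data = {}
    for n_markers in n_markers_list:
        row = []
        for n_proj in n_projections_list:
            cfg = RobustnessConfig(
                n_markers=n_markers, n_projections=n_proj, sigma_peak=sigma_peak,
                n_trials=n_trials, seed=seed, merging=merging,
            )
            row.append(run_robustness_study(cfg).success_rate)
        data[n_markers] = row
    table = pd.DataFrame(data, index=[f"{n} proj." for n in n_projections_list]).T
    table.index = [f"{n} markers" for n in n_markers_list]
    table.columns = [f"{n} proj." for n in n_projections_list]
    return table


def _pose_rotation(sagittal_deg: float, coronal_deg: float) -> np.ndarray:
    """Probe pose: rotation in the sagittal plane (about x), then in the
    coronal plane (about y), composed about the isocentre."""
    return (Rotation.from_euler("y", coronal_deg, degrees=True)
            * Rotation.from_euler("x", sagittal_deg, degrees=True)).as_matrix()


def run_targeting_study(config: TargetingConfig) -> StudyResult:
    """Needle-tip targeting error over random probe poses.

    Per trial: sample a pose, project the posed markers with noise,
    localize, label against the nominal model, fit the rigid transform and
    compare the transformed needle tip with the true one.  Trials whose
    localization or labeling fails are excluded from the error statistics
    (they are counted in the success rate).
    """
    model = config.marker_model
    n = model.n_markers
    directions = direction_subset(config.n_projections)
    ranked = _ranked_for(config.n_projections)
    eps = 10.0 * config.sigma_peak if config.sigma_peak > 0 else 1e-6
    loc_config = LocalizationConfig(
        n_markers=n,
        epsilon=eps,
        epsilon_merged=max(eps, 2.0 * config.pixel_size),
        min_peak_separation_d=2.0 * config.pixel_size,
    )
    errors = []
    n_success = 0
    for trial in range(config.n_trials):
        pose_rng = np.random.default_rng([config.seed, trial, 0])
        noise_rng = np.random.default_rng([config.seed, trial, 1])
        sag = pose_rng.uniform(*config.sagittal_rotation_range)
        cor = pose_rng.uniform(*config.coronal_rotation_range)
        R = _pose_rotation(sag, cor)
        posed = model.points @ R.T
        noise = noise_rng.normal(0.0, config.sigma_peak, (13, _MAX_MARKERS)) if config.sigma_peak > 0 else np.zeros((13, _MAX_MARKERS))
        peaksets = project_markers(
            posed, directions, config.sigma_peak, noise_rng,
            pixel_size=config.pixel_size, merging=config.merging,
            noise=noise[: config.n_projections, :n],
        )
        result = localize(peaksets, loc_config, ranked_triples=ranked)
        if not result.success:
            continue
        try:
            order = label_markers(result.points, model)
        except Exception:
            continue
        transform = rigid_fit(model.points, result.points[order])
        tip_est, _ = needle_tip(transform, config.needle)
        tip_true = R @ config.needle.tip_offset
        errors.append(targeting_error(tip_est, tip_true))
        n_success += 1
    errors = np.asarray(errors)
    return StudyResult(
        success_rate=100.0 * n_success / config.n_trials,
        max_error=float(errors.max()) if len(errors) else 0.0,
        mean_error=float(errors.mean()) if len(errors) else 0.0,
        error_sd=float(errors.std(ddof=1)) if len(errors) > 1 else 0.0,
        n_trials=config.n_trials,
        n_successes=n_success,
        config=config,
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    y = np.asarray(observed, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if y.shape != f.shape or y.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for a constant observed vector")
    return 1.0 - float(np.sum((y - f) ** 2)) / ss_tot


# --- synthetic probe geometry -------------------------------------------

_PROBE_POINTS = np.array(
    [
        [0.0, 0.0, 0.0],
        [62.0, 0.0, 8.0],
        [23.0, 31.0, 0.0],
        [85.0, 14.0, 27.0],
        [40.0, -22.0, 55.0],
        [-18.0, 45.0, 36.0],
    ]
)
_PROBE_LABELS = ("A", "B", "C", "D", "E", "F")


def synthetic_probe(n_markers: int = 3) -> MarkerModel:
    """A synthetic biopsy-probe marker model with 3..6 markers.

    The coordinates (mm, probe frame) are an invented but realistic
    arrangement: every prefix subset has strictly distinct pairwise
    distances, which the labeling step requires.
    """
    if not 3 <= n_markers <= _MAX_MARKERS:
        raise ValueError("n_markers must be in 3..6")
    return MarkerModel(points=_PROBE_POINTS[:n_markers].copy(), labels=_PROBE_LABELS[:n_markers])


def synthetic_needle() -> NeedleGeometry:
    """Needle geometry of the synthetic probe: tip about 130 mm from the
    marker cluster along the probe axis."""
    return NeedleGeometry(tip_offset=(120.0, 0.0, -30.0), direction_offset=(0.97, 0.05, -0.24))
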