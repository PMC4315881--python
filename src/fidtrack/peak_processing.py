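"""Synthetic 1D projections and robust sub-pixel peak detection.

A 1D projection is the inverse Fourier transform of a readout acquired
with a single frequency-encoding gradient: a non-negative magnitude
profile of total signal versus position along one direction.  Each fiducial
marker appears as a narrow peak whose position along the direction is the
quantity fed to the plane-intersection localizer.

Peak processing follows four steps:

1. local maxima by sign change of the first difference;
2. ghost suppression -- a single marker can produce two detected maxima
   exactly one pixel apart, in which case the smaller one is discarded;
3. SNR gating -- the N largest surviving maxima are kept only if their
   amplitude exceeds ``lambda`` times the standard deviation of the
   background (all samples outside a +/- 4-sample window around each peak);
4. sub-pixel refinement by three-point Gaussian interpolation,

    Xhat = x - 1/2 * (ln c - ln a) / (ln a + ln c - 2 ln b),

   where ``b`` is the maximum sample and ``a``, ``c`` its neighbours; the
   correction is exact when the underlying peak is Gaussian and is always
   bounded by half a pixel.

Coordinate convention: sample ``i`` of an ``n``-sample projection with
field of view ``fov`` (mm) sits at ``(i + 0.5 - n/2) * fov/n`` mm, i.e.
sample centres with the scanner isocentre at the FOV midpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidConfigurationError
from .projection_geometry import canonical_direction

#: Default readout geometry: 300 mm field of view over 320 samples
#: (pixel size 0.9375 mm).
DEFAULT_N_SAMPLES = 320
DEFAULT_FOV_MM = 300.0


@dataclass(frozen=True)
class Projection1D:
    """A sampled magnitude signal along a projection direction."""

    direction: np.ndarray
    samples: np.ndarray
    fov: float = DEFAULT_FOV_MM

    def __post_init__(self):
        object.__setattr__(self, "direction", np.asarray(self.direction, dtype=float))
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pixel_size(self) -> float:
        """mm per sample."""
        return self.fov / self.n_samples

    def coordinates(self) -> np.ndarray:
        """mm position of every sample centre (isocentre-centred)."""
        n = self.n_samples
        return (np.arange(n) + 0.5 - n / 2) * self.pixel_size

    def coordinate(self, index: int) -> float:
        return (index + 0.5 - self.n_samples / 2) * self.pixel_size


@dataclass(frozen=True)
class Peak:
    """A detected peak: sub-pixel position (mm), amplitude and the integer
    sample index of the underlying maximum."""

    position: float
    amplitude: float
    index: int


@dataclass
class PeakDetectionParams:
    """Knobs of the detection step.

    ``n_expected`` is the known number of markers N; ``snr_threshold`` is
    the dimensionless acceptance threshold lambda (amplitude over
    background standard deviation); ``background_halfwidth`` is the number
    of samples excluded on either side of each peak when estimating the
    background.
    """

    n_expected: int
    snr_threshold: float = 5.0
    background_halfwidth: int = 4

    def __post_init__(self):
        if self.n_expected < 1:
            raise ValueError("n_expected must be >= 1")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")


def local_maxima(samples: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima by first-difference sign change."""
    s = np.asarray(samples, dtype=float)
    if len(s) < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, len(s) - 1)
    mask = (s[interior] > s[interior - 1]) & (s[interior] >= s[interior + 1])
    return interior[mask]


def drop_one_pixel_ghosts(indices, amplitudes) -> np.ndarray:
    """Discard the smaller of any two maxima exactly one pixel apart.

    A single marker can generate two distinct peaks one pixel apart; the
    lower one is a ghost and is removed so that it cannot displace a real
    peak from the N-largest shortlist.  Returns the surviving indices.
    """
    indices = np.asarray(indices, dtype=int)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(indices) < 2:
        return indices
    order = np.argsort(indices)
    idx, amp = indices[order], amplitudes[order]
    keep = np.ones(len(idx), dtype=bool)
    for k in range(len(idx) - 1):
        if idx[k + 1] - idx[k] == 1:
            if amp[k] < amp[k + 1]:
                keep[k] = False
            else:
                keep[k + 1] = False
    return idx[keep]


def snr(proj: Projection1D, peaks, background_halfwidth: int = 4) -> np.ndarray:
    """Signal-to-noise ratio of each peak.

    The background is every sample outside ``index +/- background_halfwidth``
    of *all* peaks; each ratio is peak amplitude over the background
    standard deviation.  A zero-variance background (noiseless fixture)
    yields ``+inf`` rather than an error.
    """
    peaks = list(peaks)
    mask = np.ones(proj.n_samples, dtype=bool)
    for p in peaks:
        lo = max(0, p.index - background_halfwidth)
        hi = min(proj.n_samples, p.index + background_halfwidth + 1)
        mask[lo:hi] = False
    if not mask.any():
        raise InvalidConfigurationError("background window excludes every sample")
    sd = float(np.std(proj.samples[mask]))
    if sd == 0.0:
        return np.full(len(peaks), np.inf)
    return np.array([p.amplitude / sd for p in peaks])


def subpixel_gaussian(a: float, b: float, c: float, x: float, pixel_size: float = 1.0) -> float:
    """Three-point Gaussian interpolation of a peak position.

    ``b`` is the amplitude at the maximum (position ``x`` in mm), ``a`` and
    ``c`` the amplitudes one sample to the left and right.  Falls back to
    ``x`` when any amplitude is non-positive or the log-denominator is
    degenerate (flat top).  The correction never exceeds half a pixel for
    ``b >= a, c``.
    """
    if a <= 0.0 or b <= 0.0 or c <= 0.0:
        return x
    la, lb, lc = math.log(a), math.log(b), math.log(c)
    denom = la + lc - 2.0 * lb
    if abs(denom) < 1e-12:
        return x
    return x - 0.5 * ((lc - la) / denom) * pixel_size


def detect_peaks(proj: Projection1D, params: PeakDetectionParams) -> list[Peak]:
    """Detect up to ``n_expected`` marker peaks with sub-pixel positions.

    Pipeline: local maxima -> one-pixel ghost suppression -> keep the
    ``n_expected`` largest -> SNR gate at ``snr_threshold`` -> Gaussian
    sub-pixel refinement.  Returns the accepted peaks sorted by position;
    an empty list is a valid result.
    """
    s = proj.samples
    maxima = local_maxima(s)
    if len(maxima) == 0:
        return []
    maxima = drop_one_pixel_ghosts(maxima, s[maxima])
    # N largest surviving maxima, deterministic tie-break by index
    order = np.lexsort((maxima, -s[maxima]))
    shortlist = maxima[order][: params.n_expected]
    candidates = [Peak(position=proj.coordinate(i), amplitude=float(s[i]), index=int(i)) for i in shortlist]
    ratios = snr(proj, candidates, params.background_halfwidth)
    accepted = []
    px = proj.pixel_size
    for peak, ratio in zip(candidates, ratios):
        if ratio < params.snr_threshold:
            continue
        i = peak.index
        pos = subpixel_gaussian(s[i - 1], s[i], s[i + 1], peak.position, px)
        accepted.append(Peak(position=float(pos), amplitude=peak.amplitude, index=i))
    accepted.sort(key=lambda p: p.position)
    return accepted


def synth_projection(
    true_positions,
    amplitudes,
    peak_width_sigma: float,
    noise_sigma: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    fov: float = DEFAULT_FOV_MM,
    seed=None,
    direction=(0.0, 0.0, 1.0),
) -> Projection1D:
    """Synthesize a projection: Gaussian bumps plus rectified Gaussian noise.

    Each marker contributes ``amp * exp(-(u - pos)^2 / (2 sigma_w^2))``;
    i.i.d. Gaussian background noise of standard deviation ``noise_sigma``
    is added and the result is rectified (absolute value) because MR
    magnitude data is non-negative.  Deterministic under a fixed ``seed``.
    Two markers closer than about two pixels may merge into a single
    resolvable maximum.
    """
    true_positions = np.asarray(true_positions, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if true_positions.shape != amplitudes.shape:
        raise ValueError("positions and amplitudes must have matching shapes")
    if np.any(np.abs(true_positions) > fov / 2):
        raise ValueError("marker position outside the field of view")
    if peak_width_sigma <= 0:
        raise ValueError("peak_width_sigma must be positive")
    coords = (np.arange(n_samples) + 0.5 - n_samples / 2) * (fov / n_samples)
    signal = np.zeros(n_samples)
    for pos, amp in zip(true_positions, amplitudes):
        signal += amp * np.exp(-((coords - pos) ** 2) / (2.0 * peak_width_sigma**2))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, n_samples)
    return Projection1D(direction=canonical_direction(direction), samples=np.abs(signal), fov=fov)


def normality_chi2(samples, n_bins: int = 12) -> tuple[float, float]:
    """Chi-square goodness-of-fit test of normality.

    Bins the samples into ``n_bins`` equal-probability bins of the fitted
    normal and compares observed with expected counts; two degrees of
    freedom are absorbed by the estimated mean and standard deviation.
    Returns ``(statistic, p_value)``.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 5 * n_bins:
        raise ValueError("too few samples for a binned chi-square test")
    mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample (zero variance)")
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(n_bins, len(x) / n_bins)
    statistic, p_value = stats.chisquare(observed, expected, ddof=2)
    return float(statistic), float(p_value)
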