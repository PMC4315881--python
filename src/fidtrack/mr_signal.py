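"""Spoiled-GRE steady-state signal of a resonant microcoil marker.

A semi-active marker is a resonant microcoil that locally amplifies the
transmit field: an applied flip angle ``alpha_app`` becomes an effective
flip angle ``alpha_eff = Q * alpha_app`` inside the coil, where ``Q`` is
the resonance quality factor (``f_r / delta_f`` at -3 dB).  During a
tracking shot the marker is excited once per repetition time TR, and with
``TR << T1`` the longitudinal magnetization converges to the spoiled
steady state

    M_z* = M0 (1 - E1) / (1 - E1 cos(alpha_eff)),   E1 = exp(-TR / T1),

so the echo amplitude at time TE settles at
``M_z* sin(alpha_eff) exp(-TE / T2)``.  Large effective flip angles give a
bright first echo but drain longitudinal magnetization quickly, so the
late echoes of a multi-projection set are brighter at moderate flip
angles -- the trade-off that fixes the applied flip angle of the tracking
sequence.

The recursion implemented here assumes ideal spoiling (transverse
magnetization destroyed by the dephaser gradient before each excitation)
and on-resonance precession; only echo magnitudes are reported, so the
precession phase is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RelaxationParams:
    """Relaxation times of the marker filling (ms); M0 normalized to 1.

    Defaults are for the water-gel filling of the microcoil markers
    (T1 = 160 ms, T2 = 14 ms).
    """

    T1: float = 160.0
    T2: float = 14.0
    M0: float = 1.0

    def __post_init__(self):
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("relaxation times must be positive")
        if self.T2 > self.T1:
            raise ValueError("T2 cannot exceed T1")


@dataclass(frozen=True)
class SequenceTiming:
    """Timing and excitation parameters of the tracking sequence.

    Defaults follow the tracking readout (TR = 5.6 ms, TE = 3.5 ms) with
    one excitation per projection of a 13-projection set.  ``alpha_app``
    is the applied flip angle in degrees and ``Q`` the microcoil quality
    factor multiplying it.
    """

    TE: float = 3.5
    TR: float = 5.6
    alpha_app: float = 0.2
    n_excitations: int = 13
    Q: float = 120.0

    def __post_init__(self):
        if not 0 < self.TE < self.TR:
            raise ValueError("need 0 < TE < TR")
        if self.alpha_app < 0:
            raise ValueError("flip angle must be non-negative")
        if self.n_excitations < 1:
            raise ValueError("n_excitations must be >= 1")


def effective_flip(alpha_app: float, q: float) -> float:
    """Effective flip angle (degrees) inside the coil: ``Q * alpha_app``."""
    if alpha_app < 0 or q <= 0:
        raise ValueError("flip angle and Q must be positive")
    return q * alpha_app


def q_factor(f_r: float, delta_f: float) -> float:
    """Quality factor from resonance frequency and -3 dB bandwidth (MHz)."""
    if f_r <= 0 or delta_f <= 0:
        raise ValueError("frequencies must be positive")
    return f_r / delta_f


def steady_state_series(relax: RelaxationParams, timing: SequenceTiming) -> np.ndarray:
    """Transverse echo magnitude at TE for each of ``n_excitations`` shots.

    Starting from thermal equilibrium, each repetition applies an
    instantaneous nutation by ``alpha_eff`` about the transverse axis,
    relaxes to TE where the echo magnitude ``sqrt(Mx^2 + My^2)`` is
    recorded, then relaxes to TR and spoils the transverse component
    before the next excitation.
    """
    alpha = math.radians(effective_flip(timing.alpha_app, timing.Q)) if timing.alpha_app > 0 else 0.0
    e1_tr = math.exp(-timing.TR / relax.T1)
    e2_te = math.exp(-timing.TE / relax.T2)
    mz = relax.M0
    echoes = np.empty(timing.n_excitations)
    for k in range(timing.n_excitations):
        mxy = mz * math.sin(alpha)  # transverse right after the pulse
        mz_post = mz * math.cos(alpha)
        echoes[k] = abs(mxy) * e2_te
        # longitudinal recovery over the full TR; transverse spoiled
        mz = relax.M0 + (mz_post - relax.M0) * e1_tr
    return echoes


def spoiled_steady_state_amplitude(relax: RelaxationParams, timing: SequenceTiming) -> float:
    """Closed-form spoiled steady-state echo amplitude at TE.

    ``M0 (1 - E1) sin(alpha_eff) / (1 - E1 cos(alpha_eff)) * exp(-TE/T2)``,
    the fixed point of :func:`steady_state_series`.
    """
    alpha = math.radians(effective_flip(timing.alpha_app, timing.Q)) if timing.alpha_app > 0 else 0.0
    e1 = math.exp(-timing.TR / relax.T1)
    denom = 1.0 - e1 * math.cos(alpha)
    if denom == 0.0:
        return 0.0
    return relax.M0 * (1.0 - e1) * math.sin(alpha) / denom * math.exp(-timing.TE / relax.T2)
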