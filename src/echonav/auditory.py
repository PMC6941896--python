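"""Cochlear model and first-echo detection.

The receiver chain converts each ear's waveform into a smooth envelope:
4th-order gammatone bandpass at the 40 kHz carrier -> half-wave
rectification -> power-law compression (exponent 0.4) -> causal 2nd-order
Butterworth low-pass at 1 kHz.  The envelope of the emission itself
(recorded by the on-board microphones) is subtracted before detection.

Detection: the earliest envelope local maximum exceeding a threshold in
either ear marks the arrival of the first echo.  Its delay t gives the
nearest-obstacle distance estimate d_hat = c t / 2, and the onset loudness
in each ear is the envelope integrated over a 1 ms window (300 samples at
300 kHz) starting 150 samples before that peak — the interaural level
difference cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .acoustics import SPEED_OF_SOUND, EmissionModel, emitted_pulse

__all__ = [
    "CochlearParams",
    "SonarReading",
    "cochlear_model",
    "remove_emission",
    "detect_first_echo",
    "emission_envelope",
    "calibrate_threshold",
    "find_peaks",
    "save_envelope_csv",
]

INTEGRATION_SAMPLES = 300
"""Length of the onset-energy window: 300 samples = 1 ms at 300 kHz."""

PRE_PEAK_SAMPLES = 150
"""The window starts 150 samples before the first-echo peak."""

THRESHOLD_FLOOR = 1e-9
"""Lower bound on the detection threshold (relevant only at zero noise)."""


@dataclass(frozen=True)
class CochlearParams:
    """Parameters of the single-channel cochlear model."""

    center_frequency: float = 40_000.0
    compression_exponent: float = 0.4
    lowpass_cutoff: float = 1_000.0
    sample_rate: float = 300_000.0

    def __post_init__(self) -> None:
        if not (0 < self.compression_exponent <= 1):
            raise ValueError("compression_exponent must be in (0, 1]")
        if self.lowpass_cutoff >= self.center_frequency:
            raise ValueError("lowpass_cutoff must be below center_frequency")


@dataclass
class SonarReading:
    """Per-call sonar percept: nearest distance estimate and onset ILD cue."""

    detected: bool
    first_echo_time: float  # s from emission onset
    d_hat: float  # m
    energy_left: float
    energy_right: float
    call_index: int = 0

    @property
    def ild(self) -> float:
        """Onset level difference, right minus left (positive = source right)."""
        return self.energy_right - self.energy_left


@lru_cache(maxsize=8)
def _filters(params: CochlearParams):
    b_gt, a_gt = signal.gammatone(
        params.center_frequency, "iir", fs=params.sample_rate
    )
    b_lp, a_lp = signal.butter(2, params.lowpass_cutoff, fs=params.sample_rate)
    return (b_gt, a_gt), (b_lp, a_lp)


def cochlear_model(waveform: np.ndarray, params: CochlearParams | None = None) -> np.ndarray:
    """Envelope of ``waveform`` through the cochlear chain (non-negative, same length).

    gammatone(40 kHz, order 4) -> half-wave rectify -> x**0.4 -> low-pass (1 kHz,
    applied forward only, as in a causal real-time system).
    """
    params = params or CochlearParams()
    (b_gt, a_gt), (b_lp, a_lp) = _filters(params)
    y = signal.lfilter(b_gt, a_gt, np.asarray(waveform, dtype=float))
    y = np.maximum(y, 0.0) ** params.compression_exponent
    y = signal.lfilter(b_lp, a_lp, y)
    return np.maximum(y, 0.0)


@lru_cache(maxsize=8)
def _emission_envelope_cached(
    emission: EmissionModel, params: CochlearParams, level: float, n_samples: int
) -> np.ndarray:
    buf = np.zeros(n_samples)
    pulse = emitted_pulse(emission, params.sample_rate)
    buf[: len(pulse)] = level * pulse
    env = cochlear_model(buf, params)
    env.setflags(write=False)
    return env


def emission_envelope(
    emission: EmissionModel,
    params: CochlearParams | None = None,
    level: float = 1.0,
    tail: float = 6e-3,
) -> np.ndarray:
    """Cochlear envelope of the bare emission (direct pickup at ``level``).

    Computed over the pulse duration plus a ``tail`` covering the filter
    ring-down; this is the template subtracted by :func:`remove_emission`.
    """
    params = params or CochlearParams()
    n = int(round((emission.effective_duration + tail) * params.sample_rate))
    return _emission_envelope_cached(emission, params, level, n)


def remove_emission(envelope: np.ndarray, emission_env: np.ndarray) -> np.ndarray:
    """Subtract the emission's own envelope, clipping at zero over its window.

    Samples beyond the emission template are returned unchanged.
    """
    out = np.array(envelope, dtype=float, copy=True)
    n = min(len(out), len(emission_env))
    out[:n] = np.maximum(out[:n] - emission_env[:n], 0.0)
    return out


def find_peaks(envelope: np.ndarray) -> np.ndarray:
    """Indices of local maxima (strictly above the previous sample, at least
    equal to the next), so plateau ties resolve to the earlier sample."""
    e = np.asarray(envelope)
    if len(e) < 3:
        return np.empty(0, dtype=int)
    return np.flatnonzero((e[1:-1] > e[:-2]) & (e[1:-1] >= e[2:])) + 1


def calibrate_threshold(
    noise_rms: float,
    params: CochlearParams | None = None,
    factor: float = 10.0,
    duration: float = 0.04,
    calibration_seed: int = 987_654_321,
) -> float:
    """Detection threshold: ``factor`` x RMS of the cochlear output on a
    pure-noise calibration call.

    The calibration call uses a fixed internal seed so the threshold is a
    deterministic function of (noise_rms, params) alone.
    """
    params = params or CochlearParams()
    if noise_rms <= 0:
        return THRESHOLD_FLOOR
    rng = np.random.default_rng(calibration_seed)
    n = int(round(duration * params.sample_rate))
    env = cochlear_model(rng.normal(0.0, noise_rms, n), params)
    return max(factor * float(np.sqrt(np.mean(env**2))), THRESHOLD_FLOOR)


def save_envelope_csv(path, sample_rate: float = 300_000.0, **channels: np.ndarray) -> None:
    """Dump envelope traces (one column per keyword) with a time column, for
    plotting echo-processing figures."""
    import pandas as pd

    n = max(len(v) for v in channels.values())
    data = {"t": np.arange(n) / sample_rate}
    for name, v in channels.items():
        data[name] = np.pad(np.asarray(v, dtype=float), (0, n - len(v)))
    pd.DataFrame(data).to_csv(path, index=False)


def detect_first_echo(
    envelope_left: np.ndarray,
    envelope_right: np.ndarray,
    threshold: float,
    params: CochlearParams | None = None,
    *,
    speed_of_sound: float = SPEED_OF_SOUND,
    call_index: int = 0,
) -> SonarReading:
    """First-echo detection and onset-energy integration.

    The earliest supra-threshold peak in either ear sets the first-echo
    time; both ears are then integrated over the same 1 ms window around
    that peak (truncated at the array bounds).  With no supra-threshold
    peak, ``detected`` is False and both energies are zero.
    """
    params = params or CochlearParams()
    if len(envelope_left) != len(envelope_right):
        raise ValueError("envelopes must have the same length")

    first = None
    for env in (envelope_left, envelope_right):
        peaks = find_peaks(env)
        above = peaks[env[peaks] > threshold]
        if len(above):
            cand = int(above[0])
            if first is None or cand < first:
                first = cand
    if first is None:
        return SonarReading(
            detected=False,
            first_echo_time=float("nan"),
            d_hat=float("nan"),
            energy_left=0.0,
            energy_right=0.0,
            call_index=call_index,
        )

    lo = max(first - PRE_PEAK_SAMPLES, 0)
    hi = min(lo + INTEGRATION_SAMPLES, len(envelope_left))
    e_l = float(np.sum(envelope_left[lo:hi]))
    e_r = float(np.sum(envelope_right[lo:hi]))
    t = first / params.sample_rate
    return SonarReading(
        detected=True,
        first_echo_time=t,
        d_hat=speed_of_sound * t / 2.0,
        energy_left=e_l,
        energy_right=e_r,
        call_index=call_index,
    )
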