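"""Binaural echo synthesis for one sonar call.

Emission: a narrowband 40 kHz tone burst (the small-diameter emitter is
modelled as a circular piston, giving a bat-like beam width).  Reception:
two ears whose azimuth-dependent gains are mirrored Gaussians peaking at
±25°, which produces a monotone interaural level difference (ILD) over the
frontal hemisphere — the only directional cue the controllers use.

Each point scatterer at range r and azimuth az (relative to the acoustic
gaze) contributes to each ear a delayed, scaled copy of the emitted pulse:

    amplitude = strength * D_emit(az) * D_ear(az, side) * r^-2 * 10^(-alpha*2r/20)
    delay     = 2 r / c

with two-way spherical spreading (r^-2) and atmospheric absorption alpha in
dB/m.  Scatterers behind the head (|az| > 90°) are excluded.  Azimuth is
measured positive to the RIGHT of the gaze axis (so a source at positive
azimuth is louder in the right ear), while turn angles elsewhere in the
package are positive counterclockwise (left); this mirrors the sign
convention "right ear louder -> turn left (positive)".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import j1

from .environments import Environment

__all__ = [
    "SPEED_OF_SOUND",
    "EmissionModel",
    "BinauralGainModel",
    "BinauralRecording",
    "emitted_pulse",
    "emitter_directivity",
    "ear_directivity",
    "synthesize_echoes",
    "recording_length",
]

SPEED_OF_SOUND = 343.0
"""Speed of sound in air at ~20 degC, m/s."""

DEFAULT_RANGE_CAP = 6.0
"""Maximum echo range synthesized (m); keeps the recording window (35 ms)
shorter than the 50 ms interpulse interval."""

DEFAULT_ABSORPTION_DB_PER_M = 1.3
"""Atmospheric absorption at 40 kHz, dB per metre of path."""


@dataclass(frozen=True)
class EmissionModel:
    """Parameters of the emitted sonar pulse.

    The emitter is excited for 0.3 ms but rings for about 1.5 ms; the
    synthetic pulse models the resulting effective emission directly as a
    1.5 ms raised-cosine tone burst at 40 kHz.
    """

    carrier_frequency: float = 40_000.0
    effective_duration: float = 1.5e-3
    excitation_duration: float = 0.3e-3  # informational
    source_level: float = 1.0
    emitter_diameter: float = 0.010

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0 or self.effective_duration <= 0:
            raise ValueError("carrier_frequency and effective_duration must be > 0")


@dataclass(frozen=True)
class BinauralGainModel:
    """Mirrored-Gaussian approximation of the ear directionality.

    Right-ear gain peaks at +peak_offset degrees (to the right of the gaze),
    left-ear gain at -peak_offset; both have width ``beam_width_sigma``.
    ``ear_separation`` is informational: both ears sit at the robot centre,
    so the model carries a pure level-difference cue and no time difference.
    """

    peak_offset: float = 25.0
    beam_width_sigma: float = 40.0
    ear_separation: float = 0.04

    def gain(self, azimuth_deg: np.ndarray | float, side: str) -> np.ndarray | float:
        mu = self.peak_offset if side == "right" else -self.peak_offset
        az = np.asarray(azimuth_deg, dtype=float)
        g = np.exp(-((az - mu) ** 2) / (2.0 * self.beam_width_sigma**2))
        return g if g.ndim else float(g)


@dataclass
class BinauralRecording:
    """Two-channel received waveform for one call (linear amplitude)."""

    sample_rate: float
    left: np.ndarray
    right: np.ndarray
    call_time: float = 0.0

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("left and right channels must have the same length")


@lru_cache(maxsize=8)
def _cached_pulse(
    carrier: float, duration: float, level: float, sample_rate: float
) -> np.ndarray:
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    envelope = 0.5 * (1.0 - np.cos(2.0 * math.pi * t / duration))
    w = level * np.sin(2.0 * math.pi * carrier * t) * envelope
    w.setflags(write=False)
    return w


def emitted_pulse(model: EmissionModel, sample_rate: float) -> np.ndarray:
    """The emitted tone burst sampled at ``sample_rate``.

    A 40 kHz sinusoid of ``effective_duration`` under a raised-cosine
    envelope with peak amplitude ``source_level`` (1.5 ms -> 450 samples at
    300 kHz).  Raises if the sample rate is below 4x the carrier.
    """
    if sample_rate < 4 * model.carrier_frequency:
        raise ValueError(
            f"sample rate {sample_rate} Hz undersamples the {model.carrier_frequency} Hz carrier"
        )
    return _cached_pulse(
        model.carrier_frequency, model.effective_duration, model.source_level, sample_rate
    )


def emitter_directivity(
    azimuth_deg: np.ndarray | float,
    model: EmissionModel,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> np.ndarray | float:
    """Circular-piston directivity |2 J1(x)/x|, x = k a sin(az), normalised on-axis.

    With the default 10 mm aperture at 40 kHz the first null lies beyond 90°,
    so the pattern decreases monotonically over the frontal hemisphere.
    """
    az = np.radians(np.asarray(azimuth_deg, dtype=float))
    a = model.emitter_diameter / 2.0
    k = 2.0 * math.pi * model.carrier_frequency / speed_of_sound
    x = k * a * np.sin(np.abs(az))
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(x < 1e-12, 1.0, 2.0 * j1(np.maximum(x, 1e-12)) / np.maximum(x, 1e-12))
    g = np.abs(g)
    return g if g.ndim else float(g)


def ear_directivity(
    azimuth_deg: np.ndarray | float, side: str, model: BinauralGainModel
) -> np.ndarray | float:
    """Azimuth-dependent gain of one ear (``side`` in {'left', 'right'})."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    return model.gain(azimuth_deg, side)


def recording_length(
    emission: EmissionModel,
    sample_rate: float,
    range_cap: float = DEFAULT_RANGE_CAP,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> int:
    """Number of samples covering the two-way travel to ``range_cap`` plus the pulse."""
    n_delay = int(round(2.0 * range_cap / speed_of_sound * sample_rate))
    n_pulse = int(round(emission.effective_duration * sample_rate))
    return n_delay + 2 * n_pulse


def synthesize_echoes(
    position,
    gaze_direction: float,
    env: Environment,
    emission: EmissionModel | None = None,
    ears: BinauralGainModel | None = None,
    noise_rms: float = 0.0,
    seed: int | np.random.Generator | None = None,
    *,
    sample_rate: float = 300_000.0,
    range_cap: float = DEFAULT_RANGE_CAP,
    absorption_db_per_m: float = DEFAULT_ABSORPTION_DB_PER_M,
    speed_of_sound: float = SPEED_OF_SOUND,
    include_emission: bool = True,
    direct_level: float = 1.0,
    call_time: float = 0.0,
) -> BinauralRecording:
    """Synthesize the two-channel received waveform for one call.

    Parameters
    ----------
    position
        Robot (= emitter/ear) position in world coordinates, m.
    gaze_direction
        Acoustic gaze direction in world frame, degrees CCW from +x.
    noise_rms
        Standard deviation of the independent Gaussian receiver noise added
        to each channel.
    seed
        Integer seed or a ``numpy.random.Generator``; the same seed yields
        the identical noise realisation.
    include_emission
        Whether the direct pickup of the emission (amplitude
        ``direct_level``) is added at time zero, as on the physical robot
        where the microphones sit next to the emitter.
    """
    emission = emission or EmissionModel()
    ears = ears or BinauralGainModel()
    pulse = emitted_pulse(emission, sample_rate)
    n = recording_length(emission, sample_rate, range_cap, speed_of_sound)
    left = np.zeros(n)
    right = np.zeros(n)
    if include_emission and direct_level > 0:
        left[: len(pulse)] += direct_level * pulse
        right[: len(pulse)] += direct_level * pulse

    xy = env.scatterer_xy
    if len(xy):
        p = np.asarray(position, dtype=float)
        delta = xy - p
        r = np.hypot(delta[:, 0], delta[:, 1])
        bearing = np.degrees(np.arctan2(delta[:, 1], delta[:, 0]))
        # positive azimuth = clockwise from gaze = to the right of the gaze axis
        az = (gaze_direction - bearing + 180.0) % 360.0 - 180.0
        sel = (r > 1e-6) & (r <= range_cap) & (np.abs(az) <= 90.0)
        if np.any(sel):
            r = r[sel]
            az = az[sel]
            s = env.scatterer_strength[sel]
            spread = 1.0 / (r * r)
            absorb = 10.0 ** (-absorption_db_per_m * 2.0 * r / 20.0)
            base = s * emitter_directivity(az, emission, speed_of_sound) * spread * absorb
            # angular reflectance of directional (panel) scatterers:
            # cos(incidence)^p, evaluated on the scatterer->robot ray
            normals, exponents = env.scatterer_directivity
            exponents = exponents[sel]
            directional = exponents > 0
            if np.any(directional):
                u = -delta[sel][directional] / r[directional, None]  # toward robot
                cosang = np.maximum(
                    np.einsum("ij,ij->i", u, normals[sel][directional]), 0.0
                )
                base[directional] *= cosang ** exponents[directional]
            amp_l = base * ears.gain(az, "left")
            amp_r = base * ears.gain(az, "right")
            delay = np.round(2.0 * r / speed_of_sound * sample_rate).astype(np.int64)
            idx = (delay[:, None] + np.arange(len(pulse))[None, :]).ravel()
            outer = pulse[None, :]
            left += np.bincount(idx, weights=(amp_l[:, None] * outer).ravel(), minlength=n)[:n]
            right += np.bincount(idx, weights=(amp_r[:, None] * outer).ravel(), minlength=n)[:n]

    if noise_rms > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        left += rng.normal(0.0, noise_rms, n)
        right += rng.normal(0.0, noise_rms, n)
    return BinauralRecording(sample_rate=sample_rate, left=left, right=right, call_time=call_time)
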