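"""Magnetic-stimulation protocol: waveform, harmonics and treatment schedule.

The stimulation applies a biphasic (zero-mean) rectangular magnetic field.
By Fourier analysis an ideal 50%-duty square wave of fundamental f0 contains
only odd harmonics (2k-1)*f0 with amplitudes proportional to 1/(2k-1) —
relative to the fundamental: 1, 1/3, 1/5, 1/7, ... The absolute Fourier
coefficient of the k-th odd harmonic of a square wave of amplitude A is
(4A/pi)/(2k-1).

Field strength is quoted as the time-average mean of |B| (in mT); for an
ideal 50%-duty square wave this equals both the amplitude and the RMS, so the
``convention`` flag on :func:`synthesize_waveform` only matters for non-ideal
extensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "HarmonicSpectrum",
    "TreatmentProtocol",
    "square_wave_harmonics",
    "synthesize_waveform",
    "build_schedule",
]

FREQUENCY_PLANS = ("2Hz-only", "10Hz-only", "10/2Hz-sequential")


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Odd-harmonic content of a square wave, fundamental-normalized."""

    entries: tuple[tuple[float, float], ...]  # (frequency_Hz, relative_amplitude)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("spectrum must contain at least the fundamental")
        amps = [a for _, a in self.entries]
        if amps[0] != 1.0:
            raise ValueError("first (fundamental) amplitude must be 1")
        if any(a2 >= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ValueError("relative amplitudes must be strictly decreasing")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for f, _ in self.entries])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["frequency_hz", "relative_amplitude"])


def square_wave_harmonics(
    base_frequency: float, n_harmonics: int, absolute_amplitude: float | None = None
) -> HarmonicSpectrum:
    """Odd-harmonic spectrum of a square wave.

    The k-th entry (k = 1..n_harmonics) is ``((2k-1)*f0, 1/(2k-1))``. With
    ``absolute_amplitude=A`` the amplitudes become the absolute Fourier
    coefficients ``(4A/pi)/(2k-1)`` instead (the spectrum is then returned as
    a plain DataFrame-compatible tuple; the fundamental-normalized invariant
    only applies to the relative form).
    """
    if base_frequency <= 0:
        raise ValueError("base_frequency must be positive")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    odd = 2 * np.arange(1, n_harmonics + 1) - 1
    if absolute_amplitude is not None:
        scale = 4.0 * absolute_amplitude / np.pi
        return _AbsoluteSpectrum(tuple((float(base_frequency * m), float(scale / m)) for m in odd))
    return HarmonicSpectrum(tuple((float(base_frequency * m), 1.0 / float(m)) for m in odd))


class _AbsoluteSpectrum(HarmonicSpectrum):
    """Harmonic spectrum carrying absolute 4A/pi Fourier coefficients."""

    def __post_init__(self) -> None:  # amplitudes decrease but first != 1
        amps = [a for _, a in self.entries]
        if any(a2 >= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ValueError("amplitudes must be strictly decreasing")


def synthesize_waveform(
    frequency: float,
    field_strength_mt: float = 10.0,
    duration_s: float = 1.0,
    sample_rate_hz: float = 10_000.0,
    convention: str = "mean_abs",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a biphasic rectangular field waveform.

    Returns ``(t, b)`` with ``b`` in mT. The waveform is a zero-mean 50%-duty
    square wave whose time-average |b| equals ``field_strength_mt``
    (``convention="mean_abs"``, the quoted calibration) — identical to the
    RMS convention for the ideal square wave (``convention="rms"`` accepted
    for explicitness). Rejects undersampling below 10 samples per period.
    """
    if frequency <= 0 or duration_s <= 0:
        raise ValueError("frequency and duration must be positive")
    if sample_rate_hz < 10 * frequency:
        raise ValueError(
            f"sample_rate {sample_rate_hz} Hz undersamples a {frequency} Hz square wave "
            "(need >= 10 samples per period)"
        )
    if convention not in ("mean_abs", "rms"):
        raise ValueError("convention must be 'mean_abs' or 'rms'")
    amplitude = field_strength_mt  # mean|b| == rms == amplitude for the ideal square
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    b = amplitude * signal.square(2.0 * np.pi * frequency * t)
    return t, b


@dataclass(frozen=True)
class TreatmentProtocol:
    """Four-session magnetic stimulation protocol.

    Defaults: sessions at 30/35/40/45 DIV of 7/7/7/3.5 h at a 10 mT
    time-average field. ``frequency_plan`` selects 2 Hz only, 10 Hz only, or
    the sequential plan (three 10 Hz sessions, then one 2 Hz session).
    """

    frequency_plan: str = "10/2Hz-sequential"
    field_strength_mt: float = 10.0
    session_days: tuple[int, ...] = (30, 35, 40, 45)
    session_durations_h: tuple[float, ...] = (7.0, 7.0, 7.0, 3.5)

    def __post_init__(self) -> None:
        if self.frequency_plan not in FREQUENCY_PLANS:
            raise ValueError(f"frequency_plan must be one of {FREQUENCY_PLANS}")
        if len(self.session_days) != len(self.session_durations_h):
            raise ValueError("session_days and session_durations_h lengths differ")
        if any(d <= 0 for d in self.session_durations_h):
            raise ValueError("session durations must be positive")
        if list(self.session_days) != sorted(self.session_days):
            raise ValueError("sessions must be ordered by DIV")


def build_schedule(protocol: TreatmentProtocol) -> pd.DataFrame:
    """Ordered session table (div, frequency_hz, duration_h).

    The sequential plan assigns 10 Hz to all sessions but the last, which
    runs at 2 Hz.
    """
    n = len(protocol.session_days)
    if protocol.frequency_plan == "2Hz-only":
        freqs = [2.0] * n
    elif protocol.frequency_plan == "10Hz-only":
        freqs = [10.0] * n
    else:
        freqs = [10.0] * (n - 1) + [2.0]
    return pd.DataFrame(
        {
            "div": list(protocol.session_days),
            "frequency_hz": freqs,
            "duration_h": list(protocol.session_durations_h),
            "field_strength_mt": protocol.field_strength_mt,
        }
    )
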