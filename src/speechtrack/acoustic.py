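"""Acoustic envelope stimulus functions and modulation spectra.

The amplitude envelope of each talker is extracted with a Hilbert
transform and split into a delta band (low-pass 4 Hz — no high-pass, since
natural speech carries almost no energy in the lowest modulation
frequencies) and a theta band (4–8 Hz), using first-order zero-phase
Butterworth filters, then decimated to 32 Hz and z-normalized per block.

The modulation spectrum summarises a talker's envelope rhythm as
DC-normalized power in octave-spaced modulation bands (a single-carrier
simplification of the multi-resolution envelope power spectrum model);
read speech peaks near 4 Hz, the syllable rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .lexical import STIM_FS, StimulusFunction


class SamplingRateError(ValueError):
    """Input sampling rate too low for the requested band."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. all-zero envelope)."""


@dataclass(frozen=True)
class BandSpec:
    """A modulation band of the speech envelope; ``low_hz == 0`` means no
    high-pass stage."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("need 0 <= low_hz < high_hz")


DELTA = BandSpec("delta", 0.0, 4.0)
THETA = BandSpec("theta", 4.0, 8.0)
BROADBAND = BandSpec("broadband", 0.0, 8.0)

#: octave-spaced modulation band centers (Hz) for the modulation spectrum
DEFAULT_BAND_CENTERS = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def zero_phase_butter(
    x: np.ndarray, fs: float, cutoff_hz: float, btype: str, order: int = 1
) -> np.ndarray:
    """First-order zero-phase Butterworth filter (forward-backward)."""
    sos = signal.butter(order, cutoff_hz, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling to fs_out; the FIR stage provides anti-aliasing."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10**6)
    y = signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)
    n_target = int(math.ceil(x.size * fs_out / fs_in))
    if y.size > n_target:
        y = y[:n_target]
    elif y.size < n_target:
        y = np.pad(y, (0, n_target - y.size))
    return y


def compute_band_envelope(
    x: np.ndarray,
    fs_in: float,
    band: BandSpec,
    input_is_envelope: bool = False,
    fs_out: float = STIM_FS,
    normalize: bool = True,
    block_id: str = "",
) -> StimulusFunction:
    """Band-limited amplitude-envelope stimulus function at 32 Hz.

    Pipeline: Hilbert magnitude (skipped when the input is already an
    envelope) → optional first-order zero-phase high-pass at ``band.low_hz``
    → first-order zero-phase low-pass at ``band.high_hz`` → polyphase
    decimation to ``fs_out`` → per-block z-normalization.  Filtering runs
    at the input rate, before decimation, so the decimation stage sees a
    band-limited signal.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a one-dimensional signal")
    if fs_in <= 2 * band.high_hz:
        raise SamplingRateError(
            f"fs_in={fs_in} Hz too low for band up to {band.high_hz} Hz"
        )
    env = x if input_is_envelope else np.abs(signal.hilbert(x))
    if band.low_hz > 0:
        env = zero_phase_butter(env, fs_in, band.low_hz, "highpass")
    env = zero_phase_butter(env, fs_in, band.high_hz, "lowpass")
    env = _resample_to(env, fs_in, fs_out)
    if normalize:
        sd = env.std()
        if sd > 0:
            env = (env - env.mean()) / sd
        else:
            env = env - env.mean()
    return StimulusFunction(env, fs_out, f"{band.name}_env", block_id)


@dataclass
class ModulationSpectrum:
    """Octave-band envelope power, normalized by DC (squared-mean) power."""

    centers: np.ndarray
    power: np.ndarray

    @property
    def peak_hz(self) -> float:
        """Center frequency of the band with maximal normalized power."""
        return float(self.centers[int(np.argmax(self.power))])


def modulation_spectrum(
    envelope: np.ndarray,
    fs: float,
    band_centers=DEFAULT_BAND_CENTERS,
) -> ModulationSpectrum:
    """Envelope power in octave-spaced modulation bands.

    Each band spans one octave around its center (c/sqrt(2) .. c*sqrt(2));
    AC envelope power in the band is integrated from the periodogram and
    normalized by the DC power (squared mean of the envelope).
    """
    env = np.asarray(envelope, dtype=float)
    centers = np.asarray(band_centers, dtype=float)
    if env.ndim != 1 or env.size == 0:
        raise ValueError("expected a nonempty one-dimensional envelope")
    if not np.any(env):
        raise DegenerateInputError("all-zero envelope")
    if env.size / fs < 4.0 / centers.min():
        raise ValueError("envelope too short for the lowest modulation band")
    if centers.max() * math.sqrt(2) > fs / 2:
        raise SamplingRateError("highest modulation band exceeds Nyquist")

    freqs, pxx = signal.periodogram(env, fs=fs)
    dc_power = float(env.mean() ** 2)
    power = np.empty(centers.size)
    for i, c in enumerate(centers):
        in_band = (freqs >= c / math.sqrt(2)) & (freqs < c * math.sqrt(2)) & (freqs > 0)
        df = freqs[1] - freqs[0]
        power[i] = float(np.sum(pxx[in_band]) * df) / dc_power
    return ModulationSpectrum(centers, power)
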