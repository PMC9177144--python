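"""Analog multi-unit activity (aMUA) extraction.

Converts raw voltage recordings into one scalar response per
(level, channel, trial) in four steps:

1. band-pass filter the spike band (325-6000 Hz, 4th-order Butterworth,
   causal) to strip local-field potentials and high-frequency noise;
2. excise the stimulus-artifact window (first 2 ms after onset) from the
   sample stream before any rectification;
3. full-wave rectify, low-pass at 475 Hz (Butterworth, causal) and
   downsample 25 -> 12 kHz by polyphase resampling;
4. integrate the envelope over the 2-15 ms post-onset window
   (trapezoidal rule), yielding an area in volt-seconds.

Filtering is causal (forward-only) so response latency is preserved and
no artifact energy leaks backward past the excision point.  Negative
ripple introduced by the low-pass is clipped to zero before integration,
keeping the area of a rectified signal non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import RecordingContainer, StimulusProtocol, ValidationError

#: default filter and window settings
DEFAULTS = dict(
    low_hz=325.0,
    high_hz=6000.0,
    order=4,
    lp_hz=475.0,
    fs_out=12_000.0,
    blank_s=0.002,
    window_s=(0.002, 0.015),
)


class ParameterError(ValueError):
    """A filter or window parameter is inconsistent with the data."""


@dataclass
class AmuaTable:
    """Scalar aMUA response per (level, channel, trial), volt-seconds."""

    values: np.ndarray  # (n_levels, n_channels, n_repeats)
    levels: np.ndarray  # native units
    levels_db: np.ndarray
    modality: str
    window_s: tuple[float, float]
    params: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be levels x channels x trials")
        if np.any(self.values < -1e-12):
            raise ValidationError("aMUA values must be non-negative")

    @property
    def n_levels(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[2]

    def mean_over_trials(self) -> np.ndarray:
        return self.values.mean(axis=2)


def filter_spike_band(
    data: np.ndarray,
    fs: float,
    low_hz: float = DEFAULTS["low_hz"],
    high_hz: float = DEFAULTS["high_hz"],
    order: int = DEFAULTS["order"],
) -> np.ndarray:
    """Causal Butterworth band-pass along the last (time) axis."""
    if not 0 < low_hz < high_hz:
        raise ParameterError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist rate {fs / 2}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfilt(sos, np.asarray(data, dtype=float), axis=-1)


def butter_bandpass_gain(
    freq_hz: float,
    fs: float,
    low_hz: float = DEFAULTS["low_hz"],
    high_hz: float = DEFAULTS["high_hz"],
    order: int = DEFAULTS["order"],
) -> float:
    """Analytic steady-state magnitude response of :func:`filter_spike_band`."""
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]))


def exclude_artifact(
    data: np.ndarray,
    fs: float,
    onset_s: float,
    blank_s: float = DEFAULTS["blank_s"],
) -> np.ndarray:
    """Remove the artifact-contaminated samples [onset, onset + blank).

    Samples are excised (not zero-filled), so everything after the blank
    shifts earlier by ``blank_s`` on the returned time axis.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    if blank_s < 0:
        raise ParameterError("blank_s must be >= 0")
    if blank_s == 0:
        return data
    j0 = int(round(onset_s * fs))
    j1 = int(round((onset_s + blank_s) * fs))
    if j0 < 0 or j1 > n:
        raise ParameterError("blank window extends beyond the trial epoch")
    return np.delete(data, np.s_[j0:j1], axis=-1)


def envelope(
    data: np.ndarray,
    fs: float,
    lp_hz: float = DEFAULTS["lp_hz"],
    fs_out: float = DEFAULTS["fs_out"],
    order: int = DEFAULTS["order"],
) -> np.ndarray:
    """Full-wave rectify, low-pass, and resample to ``fs_out``.

    The low-pass already provides anti-aliasing for the subsequent
    polyphase rational resampling, so cutoff order matches the chain
    rectify -> low-pass -> downsample.
    """
    if fs_out > fs:
        raise ParameterError("fs_out must not exceed the input rate")
    if lp_hz >= fs_out / 2:
        raise ParameterError("lp_hz must be below the output Nyquist rate")
    rect = np.abs(np.asarray(data, dtype=float))
    sos = signal.butter(order, lp_hz, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfilt(sos, rect, axis=-1)
    if fs_out != fs:
        frac = Fraction(fs_out / fs).limit_denominator(1000)
        env = signal.resample_poly(env, frac.numerator, frac.denominator, axis=-1)
    return np.clip(env, 0.0, None)


def response_magnitude(
    env: np.ndarray, fs_env: float, start_s: float, stop_s: float
) -> np.ndarray:
    """Trapezoidal area under the envelope over [start_s, stop_s]."""
    if stop_s <= start_s:
        raise ParameterError("integration window is empty")
    i0 = int(round(start_s * fs_env))
    i1 = int(round(stop_s * fs_env))
    n = env.shape[-1]
    if i0 < 0 or i1 >= n:
        raise ParameterError("integration window extends beyond the envelope")
    return np.trapezoid(env[..., i0 : i1 + 1], dx=1.0 / fs_env, axis=-1)


def compute_amua(
    rec: RecordingContainer,
    protocol: StimulusProtocol | None = None,
    low_hz: float = DEFAULTS["low_hz"],
    high_hz: float = DEFAULTS["high_hz"],
    order: int = DEFAULTS["order"],
    blank_s: float = DEFAULTS["blank_s"],
    lp_hz: float = DEFAULTS["lp_hz"],
    fs_out: float = DEFAULTS["fs_out"],
    window_s: tuple[float, float] = DEFAULTS["window_s"],
) -> AmuaTable:
    """Run the full aMUA chain on a recording.

    The integration window ``window_s`` is expressed relative to stimulus
    onset on the *original* timeline; the excision of the blank interval
    is accounted for internally.
    """
    protocol = protocol or rec.protocol
    if protocol is None:
        raise ValidationError("no stimulus protocol available")
    w0, w1 = window_s
    if w0 < blank_s:
        raise ParameterError(
            "integration window must start at or after the artifact blank"
        )
    filtered = filter_spike_band(rec.data, rec.fs, low_hz, high_hz, order)
    cut = exclude_artifact(filtered, rec.fs, protocol.onset_s, blank_s)
    env = envelope(cut, rec.fs, lp_hz, fs_out, order)
    # on the excised timeline the window shifts earlier by blank_s
    start = protocol.onset_s + w0 - blank_s
    stop = protocol.onset_s + w1 - blank_s
    areas = response_magnitude(env, fs_out, start, stop)  # (trials, channels)
    values = areas.reshape(
        protocol.n_levels, protocol.repeats, rec.n_channels
    ).transpose(0, 2, 1)
    params = dict(
        low_hz=low_hz,
        high_hz=high_hz,
        order=order,
        blank_s=blank_s,
        lp_hz=lp_hz,
        fs_out=fs_out,
        window_s=list(window_s),
    )
    return AmuaTable(
        values=values,
        levels=protocol.levels,
        levels_db=protocol.levels_db,
        modality=protocol.modality,
        window_s=window_s,
        params=params,
    )
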