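"""Synthetic multichannel IC recordings with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes: a 16-channel probe (50 um pitch, 25 kHz sampling) along the IC
tonotopic axis, sigmoidal recruitment of multi-unit firing with
modality-dependent threshold gradient across channels, Poisson spiking
convolved with a biphasic 1-ms spike waveform over white Gaussian noise,
and a deterministic stimulus artifact confined to the first 2 ms after
onset.

Channel 0 is ventral and maps to the highest characteristic frequency;
CF decreases log-spaced toward dorsal (48 -> 8 kHz by default).

The per-channel recruitment threshold (on the modality's dB axis) is

* acoustic:  theta(ch) = theta_c + octave_slope_db * |log2(f / CF(ch))|
  (a 'V'-shaped tuning curve around the channel whose CF matches the
  tone), and
* electric / magnetic: theta(ch) = theta_c
  + spread_slope_db * |ch - center| / spread_sigma,
  so ``spread_sigma`` sets how many channels the threshold takes to rise
  by ``spread_slope_db`` dB -- large sigma means broad recruitment
  (electric-like), small sigma means focal recruitment (magnetic-like).

A ``rect`` profile replaces the linear threshold gradient with a flat-top
window of known width (infinite threshold outside), giving rectangular
activation for spread-recovery experiments.

Given the threshold, the added firing rate at stimulus level L (dB) is
``rmax_hz * logistic((L - theta(ch)) / slope_db)``; spikes are drawn as a
Poisson process over a response window starting 2 ms after stimulus
onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import oaconvolve
from scipy.special import expit

from .containers import (
    RecordingContainer,
    StimulusProtocol,
    ValidationError,
    to_db,
)

N_CHANNELS_DEFAULT = 16
FS_DEFAULT = 25_000.0
CHANNEL_PITCH_UM_DEFAULT = 50.0
EPOCH_S_DEFAULT = 0.030
ARTIFACT_S = 0.002  # stimulus artifact occupies [onset, onset + 2 ms)


def default_cf_map(
    n_channels: int = N_CHANNELS_DEFAULT,
    cf_ventral_khz: float = 48.0,
    cf_dorsal_khz: float = 8.0,
) -> np.ndarray:
    """Log-spaced characteristic frequencies, ventral (high) to dorsal (low)."""
    return np.geomspace(cf_ventral_khz, cf_dorsal_khz, n_channels)


@dataclass
class GroundTruth:
    """Generator parameters; every field is recoverable downstream.

    ``threshold_at_center`` is in the modality's native units (dB SPL for
    acoustic, mA for electric, V for magnetic); it is converted to the dB
    axis internally.  ``center_channel`` may be fractional; for acoustic
    runs it is ignored (the tone frequency and CF map place the center)
    unless explicitly set.
    """

    cf_khz: np.ndarray = field(default_factory=default_cf_map)
    center_channel: float | None = 7.5
    spread_sigma: float = 3.0
    threshold_at_center: float = 30.0
    slope_db: float = 5.91
    rmax_hz: float = 2500.0
    noise_sd: float = 0.1
    artifact_amp: float = 0.5
    octave_slope_db: float = 80.0
    spread_slope_db: float = 10.0
    profile: str = "linear"
    rect_width_channels: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.cf_khz = np.asarray(self.cf_khz, dtype=float)
        if np.any(self.cf_khz <= 0):
            raise ValidationError("cf_khz must be positive")
        d = np.diff(self.cf_khz)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("cf_khz must be strictly monotone")
        if not self.spread_sigma > 0:
            raise ValidationError("spread_sigma must be > 0")
        if self.rmax_hz < 0:
            raise ValidationError("rmax_hz must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.profile not in ("linear", "rect"):
            raise ValidationError(f"unknown profile {self.profile!r}")
        if self.profile == "rect" and not self.rect_width_channels:
            raise ValidationError("rect profile needs rect_width_channels")

    @property
    def n_channels(self) -> int:
        return int(self.cf_khz.size)


def channel_thresholds_db(
    truth: GroundTruth, protocol: StimulusProtocol
) -> np.ndarray:
    """Recruitment threshold per channel on the modality's dB axis."""
    theta_c = float(to_db([truth.threshold_at_center], protocol.modality)[0])
    ch = np.arange(truth.n_channels, dtype=float)
    if protocol.modality == "acoustic" and truth.profile == "linear":
        if truth.center_channel is not None and truth.octave_slope_db == 0:
            return np.full(truth.n_channels, theta_c)
        octaves = np.abs(np.log2(protocol.frequency_khz / truth.cf_khz))
        return theta_c + truth.octave_slope_db * octaves
    center = truth.center_channel
    if center is None:
        raise ValidationError("center_channel required for this profile")
    if truth.profile == "rect":
        half = (truth.rect_width_channels - 1) / 2.0
        theta = np.full(truth.n_channels, np.inf)
        inside = np.abs(ch - center) <= half + 1e-9
        theta[inside] = theta_c
        return theta
    return theta_c + truth.spread_slope_db * np.abs(ch - center) / truth.spread_sigma


def expected_rate(
    truth: GroundTruth, protocol: StimulusProtocol
) -> np.ndarray:
    """Added firing rate lambda(level, channel) in Hz (levels x channels)."""
    theta = channel_thresholds_db(truth, protocol)
    ldb = protocol.levels_db[:, None]
    with np.errstate(invalid="ignore"):
        x = (ldb - theta[None, :]) / truth.slope_db
    x = np.where(np.isneginf(x), -np.inf, x)
    return truth.rmax_hz * expit(x)


def spike_kernel(fs: float = FS_DEFAULT, duration_s: float = 0.001) -> np.ndarray:
    """Biphasic unit-peak spike waveform: one sine cycle, 1 ms long."""
    n = max(2, int(round(duration_s * fs)))
    return np.sin(2.0 * np.pi * np.arange(n) / n)


def _artifact_waveform(
    n_samples: int, fs: float, onset_s: float, amp: float
) -> np.ndarray:
    """Deterministic artifact transient, exactly zero outside the window."""
    t = np.arange(n_samples) / fs
    rel = t - onset_s
    inside = (rel >= 0) & (rel < ARTIFACT_S)
    wave = np.zeros(n_samples)
    r = rel[inside]
    wave[inside] = amp * np.sin(2.0 * np.pi * 1500.0 * r) * (1.0 - r / ARTIFACT_S)
    return wave


def generate_recording(
    truth: GroundTruth,
    protocol: StimulusProtocol,
    fs: float = FS_DEFAULT,
    epoch_s: float = EPOCH_S_DEFAULT,
    channel_pitch_um: float = CHANNEL_PITCH_UM_DEFAULT,
    response_window: tuple[float, float] = (0.002, 0.015),
) -> RecordingContainer:
    """Simulate one recording session (all levels, all repeats).

    For each trial and channel, a Poisson number of spikes with rate
    lambda(channel, level) is placed uniformly within the response window
    (relative to stimulus onset), convolved with the biphasic spike
    kernel, and added to white Gaussian noise.  The stimulus artifact is
    a deterministic transient in [onset, onset + 2 ms) whose amplitude
    scales with the stimulus level (amplitude ratio re the top level).
    Identical ``truth.seed`` reproduces the tensor bit for bit.
    """
    if protocol.modality == "acoustic" and truth.center_channel is None:
        truth = replace(
            truth,
            center_channel=float(
                np.argmin(np.abs(np.log2(truth.cf_khz / protocol.frequency_khz)))
            ),
        )
    n_ch = truth.n_channels
    n_samples = int(round(epoch_s * fs))
    w0, w1 = response_window
    i0 = int(round((protocol.onset_s + w0) * fs))
    i1 = int(round((protocol.onset_s + w1) * fs))
    if not (0 <= i0 < i1 <= n_samples):
        raise ValidationError("response window outside the trial epoch")
    window_s = (i1 - i0) / fs

    rates = expected_rate(truth, protocol)  # (levels, channels)
    rng = np.random.default_rng(truth.seed)
    n_trials = protocol.n_levels * protocol.repeats
    deltas = np.zeros((n_trials, n_ch, n_samples))

    for li in range(protocol.n_levels):
        lam_t = rates[li] * window_s
        counts = rng.poisson(lam_t[None, :], size=(protocol.repeats, n_ch))
        for r in range(protocol.repeats):
            trial = li * protocol.repeats + r
            for ch in range(n_ch):
                c = counts[r, ch]
                if c:
                    idx = rng.integers(i0, i1, size=c)
                    np.add.at(deltas[trial, ch], idx, 1.0)

    kernel = spike_kernel(fs)
    data = oaconvolve(deltas, kernel[None, None, :], axes=-1)[..., :n_samples]
    if truth.noise_sd > 0:
        data += truth.noise_sd * rng.standard_normal(data.shape)

    if truth.artifact_amp != 0:
        base = _artifact_waveform(
            n_samples, fs, protocol.onset_s, truth.artifact_amp
        )
        ldb = protocol.levels_db
        scale = 10.0 ** ((ldb - ldb[-1]) / 20.0)  # amplitude re top level
        for li in range(protocol.n_levels):
            sl = slice(li * protocol.repeats, (li + 1) * protocol.repeats)
            data[sl] += scale[li] * base[None, None, :]

    meta = {
        "generator": "icspread.synthetic",
        "truth": {
            "center_channel": truth.center_channel,
            "spread_sigma": truth.spread_sigma,
            "threshold_at_center": truth.threshold_at_center,
            "slope_db": truth.slope_db,
            "rmax_hz": truth.rmax_hz,
            "noise_sd": truth.noise_sd,
            "artifact_amp": truth.artifact_amp,
            "octave_slope_db": truth.octave_slope_db,
            "spread_slope_db": truth.spread_slope_db,
            "profile": truth.profile,
            "rect_width_channels": truth.rect_width_channels,
            "seed": int(truth.seed),
            "cf_khz": [float(x) for x in truth.cf_khz],
        },
        "response_window_s": list(response_window),
        "epoch_s": epoch_s,
    }
    return RecordingContainer(
        data=data,
        fs=fs,
        channel_pitch_um=channel_pitch_um,
        protocol=protocol,
        metadata=meta,
    )


def tonotopic_ground_truth(truth: GroundTruth):
    """Expose the generator's CF map as a TonotopicMap for recovery tests."""
    from .stc import TonotopicMap

    return TonotopicMap.from_cf(truth.cf_khz, source="ground_truth")


# ---------------------------------------------------------------------------
# Study-condition defaults.  One protocol + ground truth per modality,
# chosen so that each level grid starts just below recruitment threshold,
# recruitment slopes reproduce the characteristic dynamic-range ordering
# (electric < magnetic < acoustic), and threshold gradients across the
# array reproduce the spread ordering (acoustic ~ magnetic < electric).
# See docs/methods.md for the rationale behind each number.
# ---------------------------------------------------------------------------

_MODALITY_PROTOCOLS = {
    # 20..90 dB SPL in 10 dB steps, 32 kHz tone
    "acoustic": dict(levels_db=np.arange(20.0, 91.0, 10.0), frequency_khz=32.0),
    # 2..23 dB V in 3 dB steps (1.26 .. 14.1 V drive)
    "magnetic": dict(levels_db=np.arange(2.0, 23.1, 3.0), frequency_khz=None),
    # -16..-2 dB mA in 2 dB steps (0.16 .. 0.79 mA)
    "electric": dict(levels_db=np.arange(-16.0, -1.9, 2.0), frequency_khz=None),
}

_MODALITY_TRUTHS = {
    "acoustic": dict(threshold_db=30.0, slope_db=5.91, spread_sigma=3.0),
    "magnetic": dict(threshold_db=5.0, slope_db=2.29, spread_sigma=2.0),
    "electric": dict(threshold_db=-14.0, slope_db=0.737, spread_sigma=12.0),
}

#: nominal micro-coil / electrode insertion sites along the cochlear spiral,
#: expressed as the IC channel at the center of recruitment (kept away from
#: the array ends so wide activation is not always edge-censored)
SITE_CENTERS = {"base": 5.5, "apex": 10.0}


def default_protocol(
    modality: str, frequency_khz: float = 32.0, repeats: int = 39
) -> StimulusProtocol:
    """Study-condition stimulus protocol for one modality."""
    if modality not in _MODALITY_PROTOCOLS:
        raise ValidationError(f"unknown modality {modality!r}")
    cfg = _MODALITY_PROTOCOLS[modality]
    levels_db = cfg["levels_db"]
    if modality == "acoustic":
        levels = levels_db
        freq = frequency_khz
    else:
        levels = 10.0 ** (levels_db / 20.0)
        freq = None
    return StimulusProtocol(
        modality=modality,
        levels=levels,
        repeats=repeats,
        onset_s=0.005,
        frequency_khz=freq,
        pulse_rate_hz=25.0,
    )


def default_truth(
    modality: str, site: str = "base", seed: int = 0, **overrides
) -> GroundTruth:
    """Study-condition ground truth for one modality and insertion site."""
    if modality not in _MODALITY_TRUTHS:
        raise ValidationError(f"unknown modality {modality!r}")
    cfg = _MODALITY_TRUTHS[modality]
    thr_db = cfg["threshold_db"]
    # threshold is stored in native units
    thr_native = thr_db if modality == "acoustic" else 10.0 ** (thr_db / 20.0)
    center = None if modality == "acoustic" else SITE_CENTERS[site]
    params = dict(
        center_channel=center,
        spread_sigma=cfg["spread_sigma"],
        threshold_at_center=thr_native,
        slope_db=cfg["slope_db"],
        seed=seed,
    )
    params.update(overrides)
    return GroundTruth(**params)
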