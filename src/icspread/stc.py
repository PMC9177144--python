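"""Spatial tuning curves, spread of excitation, tips, and tonotopy.

A spatial tuning curve (STC) is the cumulative-d' surface over the
(stimulus level, recording channel) grid.  From it we derive:

* the *threshold* of each channel -- the lowest level at which its
  cumulative d' reaches 1 (linear interpolation between tested levels);
* the *best site* (BS) -- the channel with the lowest threshold, i.e.
  the minimum of the d' = 1 iso-contour;
* the *spatial spread* at a reference discrimination level (cumulative
  d' of 2 or 4 at the BS) -- the distance between the ventral- and
  dorsal-most channels whose cumulative d' exceeds 1 at that stimulus
  level, in channels and micrometres;
* the *tip count* -- the number of isolated contiguous suprathreshold
  channel groups at the d' = 2 reference level; and
* the *spectral spread* -- the spatial spread converted to octaves via
  the tonotopic map assigned from acoustic runs.

Iso-d' contours at {1, 2, 4} are extracted by marching squares on a
bilinearly refined surface; they are exported for plotting, while the
spread and tip measures use the discrete electrode definition directly
(the operative definition does not depend on the interpolation scheme).

The suprathreshold mask for spread/tips is evaluated at the nearest
tested level at or above the interpolated reference level L*, because
trial samples (hence masks) only exist at tested levels.  Activation
touching either end of the array marks the spread as a censored lower
bound; a BS that never reaches the reference d' leaves the measure
missing (also flagged censored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.stats import linregress
from skimage import measure

from .containers import ValidationError
from .neurometric import DPrimeMatrix

CONTOUR_LEVELS_DEFAULT = (1.0, 2.0, 4.0)
THRESHOLD_DPRIME = 1.0


class InsufficientDataError(ValueError):
    """Not enough valid observations to fit the requested quantity."""


# ---------------------------------------------------------------------------
# tonotopic map
# ---------------------------------------------------------------------------


@dataclass
class TonotopicMap:
    """Channel index -> characteristic frequency (kHz).

    ``fit`` holds (intercept, slope) of the log2(CF)-vs-channel
    regression; channels outside the measured BS range carry
    extrapolated CFs and are flagged in ``extrapolated``.
    """

    cf_khz: np.ndarray
    fit: tuple[float, float]  # log2(cf) = intercept + slope * channel
    source: str = "measured"
    extrapolated: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.cf_khz = np.asarray(self.cf_khz, dtype=float)
        if np.any(self.cf_khz <= 0):
            raise ValidationError("cf_khz must be positive")
        if self.fit[1] == 0:
            raise ValidationError("fitted tonotopic map must be monotone")
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.cf_khz.size, dtype=bool)

    @property
    def n_channels(self) -> int:
        return int(self.cf_khz.size)

    @classmethod
    def from_cf(cls, cf_khz, source: str = "ground_truth") -> "TonotopicMap":
        cf_khz = np.asarray(cf_khz, dtype=float)
        ch = np.arange(cf_khz.size)
        res = linregress(ch, np.log2(cf_khz))
        return cls(
            cf_khz=cf_khz, fit=(float(res.intercept), float(res.slope)),
            source=source,
        )

    def cf_at(self, channel: float) -> float:
        """CF at a channel; integer in-range channels use the stored map,
        anything else falls back to the fitted log-linear map."""
        if (
            float(channel).is_integer()
            and 0 <= int(channel) < self.n_channels
        ):
            return float(self.cf_khz[int(channel)])
        a, b = self.fit
        return float(2.0 ** (a + b * float(channel)))


def assign_cf(
    best_sites, frequencies_khz, n_channels: int = 16
) -> TonotopicMap:
    """Fit the tonotopic map from acoustic best sites.

    Regresses log2(tone frequency) on BS channel index and inverts the
    fit to give a CF for every channel.  Channels outside the measured
    BS range get extrapolated CFs, flagged in ``extrapolated``.
    """
    pairs = [
        (float(bs), float(f))
        for bs, f in zip(best_sites, frequencies_khz)
        if bs is not None and np.isfinite(bs)
    ]
    if len(pairs) < 2:
        raise InsufficientDataError(
            "need at least 2 (frequency, best-site) pairs to fit a map"
        )
    bs = np.array([p[0] for p in pairs])
    logf = np.log2([p[1] for p in pairs])
    order = np.argsort(bs)
    d = np.diff(logf[order])
    if bs[order].size > 2 and not (np.all(d <= 0) or np.all(d >= 0)):
        warnings.warn(
            "best-site sequence is not monotone in frequency; "
            "fitting the map anyway",
            stacklevel=2,
        )
    if np.unique(bs).size < 2:
        raise InsufficientDataError(
            "all best sites identical; tonotopic fit is degenerate"
        )
    res = linregress(bs, logf)
    ch = np.arange(n_channels)
    cf = 2.0 ** (res.intercept + res.slope * ch)
    extrapolated = (ch < bs.min()) | (ch > bs.max())
    return TonotopicMap(
        cf_khz=cf,
        fit=(float(res.intercept), float(res.slope)),
        source="measured",
        extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# STC construction
# ---------------------------------------------------------------------------


@dataclass
class SpatialTuningCurve:
    """Cumulative-d' surface with interpolated contours and BS/threshold."""

    matrix: np.ndarray  # (n_levels, n_channels) cumulative d'
    levels: np.ndarray  # dB axis of the modality
    modality: str
    contours: dict  # d' level -> list of (k, 2) arrays [level, channel]
    best_site: int | None
    threshold_level: float | None
    has_response: bool
    channel_thresholds: np.ndarray  # per-channel d'=1 crossing level (nan if none)
    upsample: int

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


def _first_crossing(levels: np.ndarray, values: np.ndarray, target: float):
    """Lowest level where ``values`` first reaches ``target``; linear
    interpolation between the bracketing tested levels.  None if never."""
    above = values >= target
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(levels[0])
    v0, v1 = values[k - 1], values[k]
    if not np.isfinite(v1):
        return float(levels[k])
    frac = (target - v0) / (v1 - v0)
    return float(levels[k - 1] + frac * (levels[k] - levels[k - 1]))


def build_stc(
    dp: DPrimeMatrix,
    upsample: int = 10,
    contour_levels=CONTOUR_LEVELS_DEFAULT,
) -> SpatialTuningCurve:
    """Build the STC from a cumulative-d' matrix.

    The surface is refined ``upsample``-fold in both axes by bilinear
    interpolation and iso-d' contours are extracted by marching squares.
    Threshold and best site follow the discrete definitions above.  If no
    channel reaches d' = 1 the STC carries a no-response flag.
    """
    if dp.n_levels < 2 or dp.n_channels < 2:
        raise ValidationError("need at least 2 levels and 2 channels")
    cum = np.where(np.isfinite(dp.cumulative), dp.cumulative, np.nan)
    levels = np.asarray(dp.levels_db, dtype=float)
    channels = np.arange(dp.n_channels, dtype=float)

    safe = np.nan_to_num(cum, nan=0.0)
    spl = RectBivariateSpline(levels, channels, safe, kx=1, ky=1)
    levels_fine = np.linspace(levels[0], levels[-1], (dp.n_levels - 1) * upsample + 1)
    chan_fine = np.linspace(0.0, dp.n_channels - 1.0, (dp.n_channels - 1) * upsample + 1)
    fine = spl(levels_fine, chan_fine)

    contours: dict = {}
    dl = levels_fine[1] - levels_fine[0]
    dc = chan_fine[1] - chan_fine[0]
    for lv in contour_levels:
        polylines = []
        for seg in measure.find_contours(fine, lv):
            phys = np.empty_like(seg)
            phys[:, 0] = levels_fine[0] + seg[:, 0] * dl
            phys[:, 1] = seg[:, 1] * dc
            polylines.append(phys)
        contours[float(lv)] = polylines

    thresholds = np.full(dp.n_channels, np.nan)
    for ch in range(dp.n_channels):
        t = _first_crossing(levels, safe[:, ch], THRESHOLD_DPRIME)
        if t is not None:
            thresholds[ch] = t

    if np.all(np.isnan(thresholds)):
        return SpatialTuningCurve(
            matrix=cum,
            levels=levels,
            modality=dp.modality,
            contours=contours,
            best_site=None,
            threshold_level=None,
            has_response=False,
            channel_thresholds=thresholds,
            upsample=upsample,
        )

    t_min = np.nanmin(thresholds)
    tied = np.flatnonzero(
        np.isclose(thresholds, t_min, rtol=0.0, atol=1e-9 * max(1.0, abs(t_min)))
    )
    if tied.size == 1:
        bs = int(tied[0])
    else:
        # tie-break: steeper growth one level grid-step above threshold wins,
        # then the lower channel index
        scores = []
        for ch in tied:
            k = int(np.argmax(safe[:, ch] >= THRESHOLD_DPRIME))
            scores.append(safe[min(k + 1, dp.n_levels - 1), ch])
        bs = int(tied[int(np.argmax(scores))])
    return SpatialTuningCurve(
        matrix=cum,
        levels=levels,
        modality=dp.modality,
        contours=contours,
        best_site=bs,
        threshold_level=float(thresholds[bs]),
        has_response=True,
        channel_thresholds=thresholds,
        upsample=upsample,
    )


def best_site(stc: SpatialTuningCurve) -> tuple[int, float]:
    """(channel, threshold level) of the best site; errors if no response."""
    if not stc.has_response or stc.best_site is None:
        raise InsufficientDataError("no channel reached cumulative d' = 1")
    return stc.best_site, stc.threshold_level


# ---------------------------------------------------------------------------
# spread of excitation
# ---------------------------------------------------------------------------


@dataclass
class SpreadMeasure:
    """Spread of excitation at one reference d' level."""

    at_d: float
    level: float | None  # stimulus level (dB axis) where BS reaches at_d
    spread_channels: float | None
    spread_um: float | None
    censored: bool
    ch_min: int | None = None
    ch_max: int | None = None
    octaves: float | None = None


def reference_level(stc: SpatialTuningCurve, at_d: float):
    """Lowest (interpolated) level at which the BS reaches cumulative d'
    ``at_d``; None if never reached within the tested range."""
    if not stc.has_response:
        return None
    profile = np.nan_to_num(stc.matrix[:, stc.best_site], nan=0.0)
    return _first_crossing(stc.levels, profile, at_d)


def _mask_at_reference(stc: SpatialTuningCurve, at_d: float):
    lstar = reference_level(stc, at_d)
    if lstar is None:
        return None, None
    idx = int(np.searchsorted(stc.levels, lstar - 1e-9))
    idx = min(idx, stc.n_levels - 1)
    mask = np.nan_to_num(stc.matrix[idx], nan=0.0) > THRESHOLD_DPRIME
    return lstar, mask


def spatial_spread(
    stc: SpatialTuningCurve, at_d: float, channel_pitch_um: float = 50.0
) -> SpreadMeasure:
    """Spread of excitation at the level where the BS reaches ``at_d``.

    The suprathreshold set is every channel with cumulative d' > 1 at
    the nearest tested level at or above L*; the spread is the index
    span of that set (x pitch for micrometres).
    """
    if not stc.has_response:
        raise InsufficientDataError("no-response STC has no spread")
    lstar, mask = _mask_at_reference(stc, at_d)
    if lstar is None:
        return SpreadMeasure(
            at_d=at_d, level=None, spread_channels=None, spread_um=None,
            censored=True,
        )
    chans = np.flatnonzero(mask)
    if chans.size == 0:  # only possible for pathological surfaces
        return SpreadMeasure(
            at_d=at_d, level=lstar, spread_channels=None, spread_um=None,
            censored=True,
        )
    lo, hi = int(chans.min()), int(chans.max())
    span = hi - lo
    censored = lo == 0 or hi == stc.n_channels - 1
    return SpreadMeasure(
        at_d=at_d,
        level=lstar,
        spread_channels=float(span),
        spread_um=float(span) * channel_pitch_um,
        censored=censored,
        ch_min=lo,
        ch_max=hi,
    )


def spectral_spread(ch_min: int, ch_max: int, tmap: TonotopicMap) -> float:
    """Octave width between the CFs of the two extreme channels."""
    return abs(np.log2(tmap.cf_at(ch_min) / tmap.cf_at(ch_max)))


def _count_runs(mask: np.ndarray) -> int:
    """Number of maximal runs of True in a boolean vector."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return 0
    starts = int(mask[0]) + int(np.sum(mask[1:] & ~mask[:-1]))
    return starts


def count_tips(stc: SpatialTuningCurve):
    """Isolated suprathreshold channel groups at the d' = 2 reference level.

    Returns None (missing) if the BS never reaches cumulative d' = 2.
    """
    if not stc.has_response:
        return None
    lstar, mask = _mask_at_reference(stc, 2.0)
    if lstar is None:
        return None
    return _count_runs(mask)


@dataclass
class SpreadResult:
    """Spread, tips, and octave conversion for one STC."""

    modality: str
    best_site: int | None
    threshold_level: float | None
    d2: SpreadMeasure | None
    d4: SpreadMeasure | None
    n_tips: int | None
    bs_cf_khz: float | None = None


def measure_spread(
    stc: SpatialTuningCurve,
    channel_pitch_um: float = 50.0,
    tmap: TonotopicMap | None = None,
) -> SpreadResult:
    """Spread at d' in {2, 4}, tip count, and optional octave conversion."""
    if not stc.has_response:
        return SpreadResult(
            modality=stc.modality, best_site=None, threshold_level=None,
            d2=None, d4=None, n_tips=None,
        )
    measures = {}
    for at_d in (2.0, 4.0):
        m = spatial_spread(stc, at_d, channel_pitch_um)
        if tmap is not None and m.ch_min is not None:
            m.octaves = spectral_spread(m.ch_min, m.ch_max, tmap)
        measures[at_d] = m
    bs_cf = tmap.cf_at(stc.best_site) if tmap is not None else None
    return SpreadResult(
        modality=stc.modality,
        best_site=stc.best_site,
        threshold_level=stc.threshold_level,
        d2=measures[2.0],
        d4=measures[4.0],
        n_tips=count_tips(stc),
        bs_cf_khz=bs_cf,
    )
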