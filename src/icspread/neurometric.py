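"""Pairwise and cumulative d-prime neurometrics over stimulus levels.

The discriminability between responses to successive stimulus levels is

    d' = |mu_a - mu_b| / sigma_rms,

where mu_a, mu_b are the mean aMUA at the two levels and sigma_rms is
the root-mean-square of the two sample standard deviations (unequal
variance convention, denominator n-1):

    sigma_rms = sqrt((sd_a^2 + sd_b^2) / 2).

A pooled-by-n variant is available via ``variance="pooled"``.  Running
sums of the successive-pair d' values give the cumulative d' used as the
response-strength axis of spatial tuning curves; the cumulative value at
the lowest level is 0 by definition.

Degenerate inputs (both samples constant with different means, so
sigma_rms = 0) yield +inf and raise a per-channel degeneracy flag rather
than being silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amua import AmuaTable
from .containers import ValidationError


class SampleSizeError(ValueError):
    """Fewer than 2 observations in a sample."""


def pairwise_dprime(a, b, variance: str = "rms") -> float:
    """d' between two samples of scalar responses.

    Returns 0 when both samples are constant and equal, +inf when
    sigma_rms is 0 but the means differ (degenerate separation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("need at least 2 observations per sample")
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if variance == "rms":
        sigma = np.sqrt((var_a + var_b) / 2.0)
    elif variance == "pooled":
        na, nb = a.size, b.size
        sigma = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    else:
        raise ValidationError(f"unknown variance convention {variance!r}")
    diff = abs(mu_a - mu_b)
    if sigma == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return diff / sigma


@dataclass
class DPrimeMatrix:
    """Pairwise and cumulative d' per channel over the level grid."""

    pairwise: np.ndarray  # (n_levels - 1, n_channels)
    cumulative: np.ndarray  # (n_levels, n_channels)
    levels: np.ndarray  # native units
    levels_db: np.ndarray
    modality: str
    n_trials: np.ndarray  # per-level trial counts
    degenerate: np.ndarray  # (n_channels,) bool

    def __post_init__(self) -> None:
        if np.any(self.pairwise < 0):
            raise ValidationError("pairwise d' must be non-negative")
        finite = np.isfinite(self.cumulative)
        diffs = np.diff(np.where(finite, self.cumulative, np.nan), axis=0)
        if np.nanmin(diffs, initial=0.0) < -1e-12:
            raise ValidationError("cumulative d' must be non-decreasing")

    @property
    def n_levels(self) -> int:
        return self.cumulative.shape[0]

    @property
    def n_channels(self) -> int:
        return self.cumulative.shape[1]


def cumulative_dprime(amua: AmuaTable, variance: str = "rms") -> DPrimeMatrix:
    """Successive-pair d' per channel, accumulated up to each level."""
    if amua.n_levels < 2:
        raise ValidationError("need at least 2 stimulus levels")
    if amua.n_repeats < 2:
        raise SampleSizeError("need at least 2 trials per level")
    n_pairs = amua.n_levels - 1
    pairwise = np.zeros((n_pairs, amua.n_channels))
    for k in range(n_pairs):
        for ch in range(amua.n_channels):
            pairwise[k, ch] = pairwise_dprime(
                amua.values[k, ch], amua.values[k + 1, ch], variance=variance
            )
    cumulative = np.zeros((amua.n_levels, amua.n_channels))
    cumulative[1:] = np.cumsum(pairwise, axis=0)
    degenerate = ~np.isfinite(pairwise).all(axis=0)
    return DPrimeMatrix(
        pairwise=pairwise,
        cumulative=cumulative,
        levels=amua.levels,
        levels_db=amua.levels_db,
        modality=amua.modality,
        n_trials=np.full(amua.n_levels, amua.n_repeats),
        degenerate=degenerate,
    )
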