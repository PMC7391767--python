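"""Stationary noise analysis of macroscopic currents.

For N independent identical channels with unitary current i and open
probability Po, the steady-state macroscopic current has binomial
moments I = N·i·Po and σ² = N·i²·Po(1−Po), which combine to

    N = I² / (i·I − σ²)

so that a patch's channel count, its maximum attainable current
I_max = N·i, and the open probability Po = I/(N·i) all follow from the
measured mean, variance and an independently measured unitary current.
The estimate is undefined when the measured variance reaches the
binomial bound i·I (e.g. extra instrumentation noise was not
subtracted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentStats",
    "NoiseEstimate",
    "segment_stats",
    "channel_count",
    "po_from_noise",
    "analyze_segment",
]


@dataclass
class SegmentStats:
    mean_current: float  # pA
    variance: float  # pA^2, unbiased
    n_samples: int


@dataclass
class NoiseEstimate:
    n_channels: float  # real-valued N; round only for display
    unitary_current: float  # pA
    i_max: float  # pA, N*i
    p_open: float


def segment_stats(samples) -> SegmentStats:
    """Mean and unbiased variance of a stationary current segment."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return SegmentStats(float(x.mean()), float(x.var(ddof=1)), int(x.size))


def channel_count(
    i_mean: float,
    variance: float,
    unitary_current: float,
    background_variance: float = 0.0,
) -> float:
    """Channel count N = I²/(i·I − σ²) from stationary binomial moments.

    ``background_variance`` (e.g. measured with the channels shut) is
    subtracted from the raw variance before applying the identity.
    """
    if unitary_current <= 0:
        raise ValueError("unitary_current must be > 0")
    if i_mean <= 0:
        raise ValueError("mean current must be > 0")
    sigma2 = variance - background_variance
    if sigma2 < 0:
        raise ValueError("background variance exceeds measured variance")
    denom = unitary_current * i_mean - sigma2
    if denom <= 0:
        raise ValueError(
            "variance exceeds binomial bound i*I: channel count undefined "
            "(check unitary current and background variance)"
        )
    return float(i_mean**2 / denom)


def po_from_noise(
    measured_current: float,
    n_channels: float,
    unitary_current: float,
    tolerance: float = 0.02,
) -> float:
    """Open probability as measured current over the noise-predicted maximum.

    Po = I/(N·i).  Values in (1, 1+tolerance] are clipped to 1 (sampling
    jitter); anything larger signals an inconsistency between the
    measurement and the noise estimate.
    """
    if n_channels <= 0 or unitary_current <= 0:
        raise ValueError("n_channels and unitary_current must be > 0")
    if measured_current < 0:
        raise ValueError("measured current must be >= 0")
    po = measured_current / (n_channels * unitary_current)
    if po > 1.0 + tolerance:
        raise ValueError(
            f"Po = {po:.3f} > 1: measured current exceeds the predicted "
            "maximum — measurement and noise estimate are inconsistent"
        )
    return float(min(po, 1.0))


def analyze_segment(
    samples,
    unitary_current: float,
    background_variance: float = 0.0,
) -> NoiseEstimate:
    """Full stationary noise analysis of one segment: stats, N, I_max, Po."""
    stats = segment_stats(samples)
    n = channel_count(stats.mean_current, stats.variance, unitary_current,
                      background_variance)
    i_max = n * unitary_current
    po = po_from_noise(stats.mean_current, n, unitary_current)
    return NoiseEstimate(n, unitary_current, float(i_max), po)
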