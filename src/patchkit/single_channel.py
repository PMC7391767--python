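"""Single-channel analysis: amplitude levels, half-amplitude idealization,
two-state rate estimation and Brønsted (rate-equilibrium) Φ analysis.

The analysis model throughout is the simple two-state scheme

    C  --beta-->  O,    O  --alpha-->  C

with exponentially distributed dwell times.  A noisy current trace is
converted into an alternating sequence of closed/open dwell events by
thresholding at 50 % of the unitary amplitude; events shorter than the
recording dead time are merged away before any kinetic quantity is
computed.  Across a series of point mutations at one site, the slope of
log10(opening rate) against log10(equilibrium constant) is the Φ value:
Φ near 1 means the mutated residue's energetic perturbation is already
felt at the transition state (the residue moves early in activation),
Φ near 0 means it is felt only after the channel opens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

__all__ = [
    "DwellEvent",
    "IdealizedRecord",
    "KineticRates",
    "AmplitudeFit",
    "PhiResult",
    "detect_levels",
    "idealize_half_amplitude",
    "estimate_rates",
    "open_probability",
    "fit_bronsted",
]

CLOSED = "closed"
OPEN = "open"


@dataclass(frozen=True)
class DwellEvent:
    """One sojourn in a single conformational state."""

    state: str  # "closed" or "open"
    start: float  # s, from the beginning of the record
    duration: float  # s, > 0

    def __post_init__(self) -> None:
        if self.state not in (CLOSED, OPEN):
            raise ValueError(f"state must be 'closed' or 'open', got {self.state!r}")
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class IdealizedRecord:
    """Alternating dwell events plus the parameters that produced them.

    ``events[0]`` and ``events[-1]`` are edge events: their durations are
    censored by the record boundaries, so kinetic estimators exclude them.
    """

    events: list[DwellEvent]
    dead_time: float  # s
    total_duration: float  # s
    threshold_current: float  # pA
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if a.state == b.state:
                raise ValueError("consecutive events must alternate state")

    def durations(self, state: str, include_edges: bool = False) -> np.ndarray:
        ev = self.events if include_edges else self.events[1:-1]
        return np.array([e.duration for e in ev if e.state == state])

    def reconstruct(self, baseline: float = 0.0, open_level: float = 1.0) -> np.ndarray:
        """Render the piecewise-constant current implied by the events."""
        dt = 1.0 / self.sampling_rate
        counts = [int(round(e.duration / dt)) for e in self.events]
        levels = [open_level if e.state == OPEN else baseline for e in self.events]
        return np.repeat(np.asarray(levels, dtype=float), counts)


@dataclass
class KineticRates:
    opening_rate: float  # per s (closed -> open)
    closing_rate: float  # per s (open -> closed)
    k_eq: float  # opening_rate / closing_rate
    n_open_events: int
    n_closed_events: int
    se_opening: float
    se_closing: float
    dead_time_corrected: bool = False


@dataclass
class AmplitudeFit:
    baseline_mean: float  # pA
    open_mean: float | None  # pA; None when only one level is present
    unitary_current: float | None  # pA
    conductance: float | None  # pS, when voltage supplied
    n_levels: int
    histogram: tuple[np.ndarray, np.ndarray] = field(repr=False, default=None)


@dataclass
class PhiResult:
    phi: float
    intercept: float
    se_slope: float
    r_squared: float
    points: list[tuple[str, float, float]]  # (label, k_eq, opening_rate)


def detect_levels(trace: np.ndarray, voltage: float | None = None) -> AmplitudeFit:
    """Locate closed and open current levels from an all-point histogram.

    The two dominant modes of the (lightly smoothed) histogram — with a
    minimum separation of 10 % of the data range and a 5 % prominence
    gate to reject sampling noise — are taken as the two levels; each
    level is then refined to the mean of the samples falling in a window
    around its mode.  ``voltage`` is the holding potential in mV; when
    given, the single-channel conductance g = i/V is reported in pS.

    Returns an ``AmplitudeFit`` with ``n_levels == 1`` (and undefined
    unitary current) when the histogram is unimodal, i.e. the channel
    never opened or never closed during the record.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace is empty")

    lo, hi = trace.min(), trace.max()
    span = hi - lo
    if span == 0:
        return AmplitudeFit(lo, None, None, None, 1, (np.array([lo]), np.array([trace.size])))

    nbins = 256
    counts, edges = np.histogram(trace, bins=nbins, range=(lo - 0.01 * span, hi + 0.01 * span))
    centers = 0.5 * (edges[:-1] + edges[1:])
    from scipy.ndimage import gaussian_filter1d as _smooth

    pad = 9  # zero-pad so modes at the histogram edges keep full prominence
    smoothed = _smooth(np.pad(counts.astype(float), pad), 2.0)
    min_sep_bins = max(1, int(0.10 * nbins))
    peaks, _ = _signal.find_peaks(smoothed, distance=min_sep_bins,
                                  prominence=0.05 * smoothed.max())
    peaks = peaks[(peaks >= pad) & (peaks < pad + nbins)] - pad
    if peaks.size == 0:  # monotone histogram; fall back to the max bin
        peaks = np.array([int(np.argmax(smoothed[pad:pad + nbins]))])
    smoothed = smoothed[pad:pad + nbins]
    # keep the two tallest modes
    order = np.argsort(smoothed[peaks])[::-1]
    peaks = np.sort(peaks[order[:2]])

    def _refine(pk: int, halfwidth: float) -> float:
        sel = np.abs(trace - centers[pk]) <= halfwidth
        if not np.any(sel):
            return float(centers[pk])
        return float(trace[sel].mean())

    if peaks.size == 1:
        level = _refine(int(peaks[0]), 0.25 * span)
        return AmplitudeFit(level, None, None, None, 1, (centers, counts))

    sep = centers[peaks[1]] - centers[peaks[0]]
    lower = _refine(int(peaks[0]), 0.25 * sep)
    upper = _refine(int(peaks[1]), 0.25 * sep)
    unitary = upper - lower
    conductance = None
    if voltage is not None:
        if voltage == 0:
            raise ValueError("voltage must be nonzero to compute conductance")
        conductance = unitary / voltage * 1000.0  # pA/mV = nS -> pS
    return AmplitudeFit(lower, upper, unitary, conductance, 2, (centers, counts))


def _runs_from_bool(is_open: np.ndarray) -> list[list]:
    """Collapse a boolean sample-state vector into [state, n_samples] runs."""
    change = np.flatnonzero(np.diff(is_open.view(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [is_open.size]))
    return [[OPEN if is_open[s] else CLOSED, int(e - s)] for s, e in zip(starts, ends)]


def idealize_half_amplitude(
    trace: np.ndarray,
    sampling_rate: float,
    baseline: float,
    open_level: float,
    dead_time: float = 0.0,
) -> IdealizedRecord:
    """Idealize a trace by thresholding at the half-amplitude point.

    The threshold is the midpoint of ``baseline`` and ``open_level``; each
    sample is assigned to the level on its side of the threshold (samples
    exactly at threshold keep the previous sample's state, the first such
    sample defaulting to closed).  Runs of equal state become dwell
    events.  Events shorter than ``dead_time`` are then removed by
    merging them into the preceding event and coalescing the resulting
    neighbours, repeated until stable — the standard retrospective
    dead-time imposition.  Edge events (first/last) are never merged away.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("trace is empty")
    if open_level == baseline:
        raise ValueError("open_level must differ from baseline")
    if dead_time < 0:
        raise ValueError("dead_time must be >= 0")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")

    dt = 1.0 / sampling_rate
    threshold = 0.5 * (baseline + open_level)
    sign = 1.0 if open_level > baseline else -1.0
    x = sign * trace
    thr = sign * threshold

    is_open = x > thr
    ties = np.flatnonzero(x == thr)
    for i in ties:  # ties inherit the previous sample's state; rare
        is_open[i] = is_open[i - 1] if i > 0 else False

    runs = _runs_from_bool(is_open)

    if 0 < dead_time < dt:
        warnings.warn(
            "dead_time is shorter than one sample period; no events can be merged",
            stacklevel=2,
        )
    if dead_time > dt:
        changed = True
        while changed:
            changed = False
            i = 1
            while i < len(runs) - 1:
                if runs[i][1] * dt < dead_time - 1e-12:
                    # absorb into the preceding event
                    runs[i - 1][1] += runs[i][1]
                    del runs[i]
                    # coalesce with the (now adjacent) next run of equal state
                    if i < len(runs) and runs[i][0] == runs[i - 1][0]:
                        runs[i - 1][1] += runs[i][1]
                        del runs[i]
                    changed = True
                    i = max(1, i - 1)
                else:
                    i += 1

    events = []
    t = 0.0
    for state, n in runs:
        events.append(DwellEvent(state, t, n * dt))
        t += n * dt
    return IdealizedRecord(
        events=events,
        dead_time=dead_time,
        total_duration=trace.size * dt,
        threshold_current=threshold,
        sampling_rate=sampling_rate,
    )


def estimate_rates(
    record: IdealizedRecord, dead_time_correction: bool = False
) -> KineticRates:
    """Exponential-MLE rate estimates from an idealized record.

    opening_rate = 1/mean(closed dwells) and closing_rate = 1/mean(open
    dwells), excluding the censored first and last events.  With
    ``dead_time_correction`` the imposed dead time is subtracted from
    every dwell before averaging — a first-order correction for the
    left-truncation of the dwell distributions; it is off by default.
    Standard errors are rate/sqrt(n), the exponential-sample result.
    """
    closed = record.durations(CLOSED)
    opened = record.durations(OPEN)
    if closed.size < 2 or opened.size < 2:
        raise ValueError(
            "need at least 2 interior events of each state to estimate rates "
            f"(got {closed.size} closed, {opened.size} open)"
        )
    if dead_time_correction:
        closed = closed - record.dead_time
        opened = opened - record.dead_time
    mean_c, mean_o = closed.mean(), opened.mean()
    if mean_c <= 0 or mean_o <= 0:
        raise ValueError("non-positive mean dwell after dead-time correction")
    beta = 1.0 / mean_c
    alpha = 1.0 / mean_o
    return KineticRates(
        opening_rate=beta,
        closing_rate=alpha,
        k_eq=beta / alpha,
        n_open_events=int(opened.size),
        n_closed_events=int(closed.size),
        se_opening=beta / np.sqrt(closed.size),
        se_closing=alpha / np.sqrt(opened.size),
        dead_time_corrected=dead_time_correction,
    )


def open_probability(record: IdealizedRecord) -> float:
    """Fraction of the record spent in the open state (edge events included)."""
    if record.total_duration <= 0:
        raise ValueError("total_duration must be > 0")
    open_time = sum(e.duration for e in record.events if e.state == OPEN)
    return open_time / record.total_duration


def fit_bronsted(
    points: list[tuple[str, float, float]], min_points: int = 3
) -> PhiResult:
    """Brønsted plot: OLS of log10(opening rate) on log10(equilibrium constant).

    ``points`` holds one ``(label, k_eq, opening_rate)`` triple per mutant
    at a single site (wild type included).  The fitted slope is the Φ
    value; the fit is unweighted, matching how such plots are normally
    drawn from a handful of mutants.
    """
    if len(points) < min_points:
        raise ValueError(f"need at least {min_points} points, got {len(points)}")
    k = np.array([p[1] for p in points], dtype=float)
    beta = np.array([p[2] for p in points], dtype=float)
    if np.any(k <= 0) or np.any(beta <= 0):
        raise ValueError("equilibrium constants and opening rates must be > 0")
    logk = np.log10(k)
    if np.ptp(logk) == 0:
        raise ValueError("degenerate abscissa: all equilibrium constants equal")
    res = _stats.linregress(logk, np.log10(beta))
    return PhiResult(
        phi=float(res.slope),
        intercept=float(res.intercept),
        se_slope=float(res.stderr),
        r_squared=float(res.rvalue**2),
        points=list(points),
    )
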