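"""Seeded generators for every input class the analysis pipeline consumes.

Each generator returns its ground truth alongside the data, so every
downstream stage can be tested against known parameters without any
recorded data.  The study conditions emulated are those of a typical
patch-clamp rig: single-channel current sampled at 10 kHz and low-pass
filtered at 2.9 kHz, two-state stochastic gating with exponential dwell
times, stationary binomial multichannel patches, Hill-shaped
concentration–response curves with replicate noise, and skewed unimodal
fluorescence emission bands.

All randomness flows through ``numpy.random.default_rng(seed)``: the same
seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .single_channel import CLOSED, OPEN, DwellEvent
from .spectra import skewed_gaussian

__all__ = [
    "SimulatedTrace",
    "DoseResponseDataset",
    "SyntheticSpectrum",
    "MutantSeriesSpec",
    "simulate_two_state_trace",
    "simulate_macroscopic_patch",
    "simulate_dose_response",
    "simulate_mutant_series",
    "simulate_emission_spectrum",
    "gaussian_filter_sigma",
    "render_events",
]

# Default recording conditions: 10 kHz sampling, 2.9 kHz low-pass.
DEFAULT_SAMPLING_RATE = 10_000.0  # Hz
DEFAULT_FILTER_CUTOFF = 2_900.0  # Hz


@dataclass
class SimulatedTrace:
    samples: np.ndarray  # pA
    sampling_rate: float  # Hz
    true_events: list[DwellEvent]
    params: dict


@dataclass
class DoseResponseDataset:
    ligand: str
    genotype: str
    concentrations: np.ndarray  # µM, sorted, > 0
    responses: np.ndarray  # shape (n_replicates, n_concentrations)
    truth: dict


@dataclass
class SyntheticSpectrum:
    wavelengths: np.ndarray  # nm
    intensities: np.ndarray  # a.u.
    truth: dict


@dataclass
class MutantSeriesSpec:
    site: str
    members: list[tuple[str, float, float]]  # (label, opening_rate, closing_rate)
    phi_true: float
    seed: int | None = None


def gaussian_filter_sigma(sampling_rate: float, cutoff: float) -> float:
    """Gaussian-kernel sigma (in samples) whose -3 dB point is ``cutoff``.

    The Gaussian filter's magnitude response is exp(-(2*pi*f*sigma_t)^2/2);
    setting it to 1/sqrt(2) at f = cutoff gives
    sigma_t = sqrt(ln 2)/(2*pi*cutoff).
    """
    return sampling_rate * np.sqrt(np.log(2.0)) / (2.0 * np.pi * cutoff)


def render_events(
    events: list[DwellEvent],
    sampling_rate: float,
    open_current: float = 1.0,
    baseline_current: float = 0.0,
    duration: float | None = None,
) -> np.ndarray:
    """Point-sample an event list to a noise-free piecewise-constant trace.

    The state at each sampling instant is the state occupied at that
    instant; an event wholly between two sampling instants leaves no
    sample behind.
    """
    if not events:
        raise ValueError("empty event list")
    if duration is None:
        duration = events[-1].end
    n_samples = int(round(duration * sampling_rate))
    t_samples = np.arange(n_samples) / sampling_rate
    starts = np.array([e.start for e in events])
    idx = np.searchsorted(starts, t_samples, side="right") - 1
    is_open = np.array([e.state == OPEN for e in events])[idx]
    return np.where(is_open, baseline_current + open_current, baseline_current).astype(float)


def simulate_two_state_trace(
    opening_rate: float,
    closing_rate: float,
    duration: float,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    open_current: float = 1.0,
    noise_sd: float = 0.0,
    filter_cutoff: float | None = DEFAULT_FILTER_CUTOFF,
    seed: int | None = None,
    baseline_current: float = 0.0,
    start_state: str = CLOSED,
) -> SimulatedTrace:
    """Gillespie simulation of the two-state C <-> O channel, rendered to a
    noisy, optionally low-pass-filtered current trace.

    Dwell times are exponential with rate ``opening_rate`` while closed
    and ``closing_rate`` while open; the chain starts closed (a resting
    channel before agonist) unless ``start_state`` says otherwise.  A
    zero rate makes that state absorbing.  The state at each sampling
    instant is the state occupied at that instant (point sampling), so
    sub-sample dwells may be invisible in ``samples`` while still listed
    in ``true_events``.  The low-pass stage is a Gaussian kernel whose
    -3 dB frequency equals ``filter_cutoff``.
    """
    if opening_rate < 0 or closing_rate < 0:
        raise ValueError("rates must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if start_state not in (CLOSED, OPEN):
        raise ValueError("start_state must be 'closed' or 'open'")
    rng = np.random.default_rng(seed)

    events: list[DwellEvent] = []
    t = 0.0
    state = start_state
    while t < duration:
        rate = opening_rate if state == CLOSED else closing_rate
        dwell = duration - t if rate == 0 else rng.exponential(1.0 / rate)
        dwell = min(dwell, duration - t)
        events.append(DwellEvent(state, t, dwell))
        t += dwell
        state = OPEN if state == CLOSED else CLOSED

    samples = render_events(events, sampling_rate, open_current,
                            baseline_current, duration)
    n_samples = samples.size

    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n_samples)
    if filter_cutoff is not None:
        samples = gaussian_filter1d(
            samples, gaussian_filter_sigma(sampling_rate, filter_cutoff), mode="nearest"
        )

    params = dict(
        opening_rate=opening_rate, closing_rate=closing_rate,
        baseline_current=baseline_current, open_current=open_current,
        noise_sd=noise_sd, filter_cutoff=filter_cutoff, seed=seed,
        duration=duration, start_state=start_state,
    )
    return SimulatedTrace(np.asarray(samples, dtype=float), sampling_rate, events, params)


def simulate_macroscopic_patch(
    n_channels: int,
    p_open: float,
    unitary_current: float,
    n_samples: int,
    seed: int | None = None,
) -> np.ndarray:
    """Stationary macroscopic current of N independent two-state channels.

    Each sample is an independent Binomial(N, Po) count of open channels
    times the unitary current, the regime assumed by stationary noise
    analysis: mean N·i·Po and variance N·i²·Po(1-Po).
    """
    if not 0 <= p_open <= 1:
        raise ValueError("p_open must be in [0, 1]")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(n_channels, p_open, n_samples).astype(float) * unitary_current


def simulate_dose_response(
    k_d: float,
    l_eq: float,
    hill_n: float,
    concentrations,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int | None = None,
    ligand: str = "ligand",
    genotype: str = "WT",
) -> DoseResponseDataset:
    """Hill-shaped concentration–response data under the binding/gating scheme.

    The generating mean response at concentration c is
    Po_max * c^nH / (c^nH + EC50^nH) with EC50 = Kd/(1+L) and
    Po_max = L/(1+L).  Replicates add Gaussian noise on the response
    scale, truncated at zero (responses are non-negative by definition).
    """
    if k_d <= 0 or l_eq <= 0 or hill_n <= 0:
        raise ValueError("k_d, l_eq and hill_n must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list is empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    conc = np.sort(conc)
    rng = np.random.default_rng(seed)

    ec50 = k_d / (1.0 + l_eq)
    po_max = l_eq / (1.0 + l_eq)
    mean = po_max * conc**hill_n / (conc**hill_n + ec50**hill_n)
    responses = np.tile(mean, (n_replicates, 1))
    if noise_sd > 0:
        responses = np.clip(
            responses + rng.normal(0.0, noise_sd, responses.shape), 0.0, None
        )
    truth = dict(k_d=k_d, l_eq=l_eq, hill_n=hill_n, ec50=ec50, po_max=po_max,
                 noise_sd=noise_sd, seed=seed)
    return DoseResponseDataset(ligand, genotype, conc, responses, truth)


def simulate_mutant_series(
    wt_opening: float,
    wt_closing: float,
    phi_true: float,
    delta_log10_k,
    seed: int | None = None,
    site: str = "site",
) -> MutantSeriesSpec:
    """Mutant rate series with an exactly linear Brønsted relationship.

    A mutation shifting the equilibrium constant by ΔlogK partitions its
    effect between the two rates according to the site's Φ value:
    log10 β = log10 β_wt + Φ·ΔlogK and log10 α = log10 α_wt - (1-Φ)·ΔlogK,
    i.e. a fraction Φ of the perturbation is already expressed at the
    transition state.  The points are exactly collinear by construction.
    """
    if wt_opening <= 0 or wt_closing <= 0:
        raise ValueError("wild-type rates must be > 0")
    if not 0 <= phi_true <= 1:
        raise ValueError("phi_true must be in [0, 1]")
    dlk = np.asarray(delta_log10_k, dtype=float)
    members = []
    for j, d in enumerate(dlk):
        beta = 10.0 ** (np.log10(wt_opening) + phi_true * d)
        alpha = 10.0 ** (np.log10(wt_closing) - (1.0 - phi_true) * d)
        label = "WT" if d == 0 else f"mut{j}"
        members.append((label, float(beta), float(alpha)))
    return MutantSeriesSpec(site=site, members=members, phi_true=phi_true, seed=seed)


def simulate_emission_spectrum(
    peak: float,
    width: float,
    skew: float,
    amplitude: float,
    baseline: float,
    noise_sd: float,
    grid,
    seed: int | None = None,
) -> SyntheticSpectrum:
    """Skewed-Gaussian emission band with additive Gaussian noise.

    The generating profile is the package's exponentially modified
    Gaussian with its mode at ``peak``, the same form the fitter uses.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    wl = np.asarray(grid, dtype=float)
    if wl.size == 0 or np.any(np.diff(wl) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    rng = np.random.default_rng(seed)
    inten = skewed_gaussian(wl, peak, width, skew, amplitude, baseline)
    if noise_sd > 0:
        inten = inten + rng.normal(0.0, noise_sd, wl.size)
    truth = dict(peak=peak, width=width, skew=skew, amplitude=amplitude,
                 baseline=baseline, noise_sd=noise_sd, seed=seed)
    return SyntheticSpectrum(wl, inten, truth)
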