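"""Hill-curve fitting and decomposition into binding and gating terms.

A partial agonist acting through the scheme

    C0  --Kd-->  C1  --L-->  O

produces a Hill-shaped open-probability curve whose apparent midpoint
and ceiling mix binding and gating:

    EC50   = Kd / (1 + L)
    Po_max = L / (1 + L)

Because Po_max < 1 for a partial agonist, both Kd (the dissociation
constant of the binding step) and L (the equilibrium constant of the
final closed-to-open transition) are identifiable from a single fitted
curve, provided the responses are calibrated to absolute open
probability.  The module fits the Hill equation by multi-start least
squares, inverts the two relations above, and propagates uncertainty by
a nonparametric bootstrap over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ConcentrationResponse",
    "HillFit",
    "GatingDecomposition",
    "HillFitError",
    "fit_hill",
    "decompose_gating",
    "recompose",
    "predict_curve",
    "bootstrap_gating",
]


class HillFitError(RuntimeError):
    """Raised when a concentration–response curve cannot be fitted."""


@dataclass
class ConcentrationResponse:
    """Replicated normalized responses on a shared concentration grid.

    ``responses`` is (n_replicates, n_concentrations); ``po_calibrated``
    states explicitly whether responses are absolute open probabilities
    (required for gating decomposition) or merely normalized currents.
    """

    concentrations: np.ndarray  # µM
    responses: np.ndarray
    ligand: str = "ligand"
    genotype: str = "WT"
    po_calibrated: bool = True

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[1] != self.concentrations.size:
            raise ValueError("responses and concentrations are misaligned")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need at least 4 distinct concentrations")
        if not np.all(np.isfinite(self.responses)) or np.any(self.responses < 0):
            raise ValueError("responses must be finite and >= 0")

    @property
    def mean_responses(self) -> np.ndarray:
        return self.responses.mean(axis=0)


@dataclass
class HillFit:
    ec50: float  # µM
    hill_n: float
    response_max: float  # Po_max when the input was Po-calibrated
    se_ec50: float
    se_hill_n: float
    se_response_max: float
    rss: float
    converged: bool
    n_points: int = 0


@dataclass
class GatingDecomposition:
    k_d: float  # µM
    l_eq: float
    se_k_d: float | None = None
    se_l_eq: float | None = None
    source: HillFit | None = field(default=None, repr=False)


def _hill(c, ec50, n, rmax):
    cn = c**n
    return rmax * cn / (cn + ec50**n)


def fit_hill(data: ConcentrationResponse, max_fixed: float | None = None) -> HillFit:
    """Least-squares Hill fit with multi-start initialization.

    Starts are the crosses of EC50 ∈ {geometric mean of the
    concentrations, concentration nearest half-max} and nH ∈ {1, 2};
    among converged starts the lowest residual sum of squares wins, ties
    broken by the smaller EC50.  ``max_fixed`` pins the plateau (useful
    when Po_max is known independently, e.g. from noise analysis).
    """
    conc = data.concentrations
    mean = data.mean_responses
    if np.all(mean <= 0):
        raise HillFitError("no activation: all responses are zero")
    if np.ptp(mean) < 1e-12 * max(1.0, mean.max()):
        raise HillFitError(
            "no concentration dependence: responses equal at every concentration "
            "(EC50 is unbounded)"
        )

    # fit on all replicate points, not just the means
    c_all = np.tile(conc, data.responses.shape[0])
    r_all = data.responses.ravel()

    rmax0 = mean.max() if max_fixed is None else max_fixed
    half = 0.5 * rmax0
    ec50_starts = [
        float(np.exp(np.mean(np.log(conc)))),
        float(conc[np.argmin(np.abs(mean - half))]),
    ]
    n_starts = [1.0, 2.0]

    c_lo, c_hi = conc.min(), conc.max()
    bounds_free = ([c_lo / 1e4, 0.05, 1e-6], [c_hi * 1e4, 20.0, 2.0])
    bounds_fixed = ([c_lo / 1e4, 0.05], [c_hi * 1e4, 20.0])

    results = []
    for e0 in ec50_starts:
        for n0 in n_starts:
            try:
                if max_fixed is None:
                    popt, pcov = optimize.curve_fit(
                        _hill, c_all, r_all, p0=[e0, n0, max(rmax0, 1e-3)],
                        bounds=bounds_free, maxfev=20000,
                    )
                    pred = _hill(c_all, *popt)
                else:
                    f = lambda c, ec50, n: _hill(c, ec50, n, max_fixed)
                    popt, pcov = optimize.curve_fit(
                        f, c_all, r_all, p0=[e0, n0],
                        bounds=bounds_fixed, maxfev=20000,
                    )
                    pred = f(c_all, *popt)
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((pred - r_all) ** 2))
            results.append((rss, popt, pcov))

    if not results:
        return HillFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                       np.inf, False, r_all.size)

    results.sort(key=lambda r: (r[0], r[1][0]))
    rss, popt, pcov = results[0]
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(popt), np.nan)
    if max_fixed is None:
        ec50, hill_n, rmax = popt
        se_e, se_n, se_r = se
    else:
        (ec50, hill_n), rmax = popt, max_fixed
        (se_e, se_n), se_r = se, 0.0
    return HillFit(float(ec50), float(hill_n), float(rmax),
                   float(se_e), float(se_n), float(se_r),
                   rss, True, r_all.size)


def decompose_gating(
    ec50: float,
    po_max: float,
    se_ec50: float | None = None,
    se_po_max: float | None = None,
    source: HillFit | None = None,
) -> GatingDecomposition:
    """Invert EC50 = Kd/(1+L), Po_max = L/(1+L) to recover Kd and L.

    Requires a partial agonist: Po_max must be strictly below 1,
    otherwise L (and hence Kd) diverges.  When standard errors are
    supplied they are propagated by the delta method assuming
    independence; bootstrap_gating gives the resampling alternative.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be > 0")
    if not 0 < po_max < 1:
        raise ValueError(
            "po_max must lie strictly between 0 and 1: the decomposition is only "
            "defined for a partial agonist whose maximum open probability is "
            "clearly less than unity"
        )
    l_eq = po_max / (1.0 - po_max)
    k_d = ec50 * (1.0 + l_eq)
    se_l = se_k = None
    if se_po_max is not None:
        se_l = se_po_max / (1.0 - po_max) ** 2
    if se_ec50 is not None or se_l is not None:
        v = 0.0
        if se_ec50 is not None:
            v += ((1.0 + l_eq) * se_ec50) ** 2
        if se_l is not None:
            v += (ec50 * se_l) ** 2
        se_k = float(np.sqrt(v))
    return GatingDecomposition(float(k_d), float(l_eq), se_k, se_l, source)


def recompose(k_d: float, l_eq: float) -> tuple[float, float]:
    """Forward map (Kd, L) -> (EC50, Po_max); exact inverse of decompose_gating."""
    if k_d <= 0 or l_eq <= 0:
        raise ValueError("k_d and l_eq must be > 0")
    return k_d / (1.0 + l_eq), l_eq / (1.0 + l_eq)


def predict_curve(g: GatingDecomposition, hill_n: float, concentrations) -> np.ndarray:
    """Hill curve implied by a gating decomposition, evaluated pointwise."""
    if hill_n <= 0:
        raise ValueError("hill_n must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    ec50, po_max = recompose(g.k_d, g.l_eq)
    return _hill(conc, ec50, hill_n, po_max)


def bootstrap_gating(
    data: ConcentrationResponse,
    n_boot: int = 1000,
    seed: int | None = None,
    max_fixed: float | None = None,
) -> dict:
    """Nonparametric bootstrap of (EC50, nH, Po_max, Kd, L) over replicates.

    Replicate rows are resampled with replacement ``n_boot`` times and
    the full fit + decomposition repeated; standard errors are the
    standard deviations across successful resamples.
    """
    rng = np.random.default_rng(seed)
    n_rep = data.responses.shape[0]
    draws = {k: [] for k in ("ec50", "hill_n", "po_max", "k_d", "l_eq")}
    for _ in range(n_boot):
        idx = rng.integers(0, n_rep, n_rep)
        boot = ConcentrationResponse(
            data.concentrations, data.responses[idx], data.ligand,
            data.genotype, data.po_calibrated,
        )
        try:
            fit = fit_hill(boot, max_fixed=max_fixed)
            if not fit.converged or not 0 < fit.response_max < 1:
                continue
            g = decompose_gating(fit.ec50, fit.response_max)
        except (HillFitError, ValueError):
            continue
        draws["ec50"].append(fit.ec50)
        draws["hill_n"].append(fit.hill_n)
        draws["po_max"].append(fit.response_max)
        draws["k_d"].append(g.k_d)
        draws["l_eq"].append(g.l_eq)
    out = {}
    for k, v in draws.items():
        arr = np.asarray(v)
        out[f"se_{k}"] = float(arr.std(ddof=1)) if arr.size > 1 else np.nan
        out[f"n_{k}"] = int(arr.size)
    out["n_boot"] = n_boot
    return out
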