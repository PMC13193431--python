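"""Band-deposition periodicity from monthly vertebral edge types.

The outermost (edge) band of each centrum is opaque or translucent at
capture; the monthly proportion of opaque edges carries the seasonal signal
of band deposition. Three nested hypotheses are fitted to the monthly
opaque counts by maximum binomial likelihood and compared with AIC:

* ``zero_peak``  no seasonal cycle — constant opaque probability p (1 param)
* ``one_peak``   one deposition season per year — opaque probability follows
  a peak-normalized von Mises curve, π(m) = A·exp(κ·(cos(θ_m − μ) − 1))
  (3 params: μ, κ, A)
* ``two_peak``   two deposition seasons per year — a two-component von Mises
  mixture with shared concentration, normalized by its maximum (5 params:
  μ1 < μ2, κ, mixing weight w, A)

Months are mapped to mid-month angles θ_m = 2π(m − 0.5)/12. The hypotheses
are nested (κ → 0 flattens one_peak to zero_peak; w → 1 collapses two_peak
to one_peak), so the maximized log-likelihoods are ordered; the fitters
enforce this by seeding each model's optimization with the embedded
solution of its simpler neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

HYPOTHESES = ("zero_peak", "one_peak", "two_peak")
_N_PARAMS = {"zero_peak": 1, "one_peak": 3, "two_peak": 5}
_EPS = 1e-9
_MONTHS = np.arange(1, 13)


def month_angle(month) -> np.ndarray:
    """Mid-month angle in radians, θ_m = 2π(m − 0.5)/12."""
    return 2.0 * np.pi * (np.asarray(month, dtype=float) - 0.5) / 12.0


@dataclass
class EdgeMonthlyTable:
    """Opaque-edge counts per calendar month: n trials, k opaque."""

    n: np.ndarray  # (12,) readable edges per month 1..12
    k: np.ndarray  # (12,) opaque edges per month

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=int)
        self.k = np.asarray(self.k, dtype=int)
        if self.n.shape != (12,) or self.k.shape != (12,):
            raise ValueError("monthly table needs 12 entries (Jan..Dec)")
        if np.any(self.k > self.n) or np.any(self.k < 0) or np.any(self.n < 0):
            raise ValueError("need 0 <= k_m <= n_m")
        if self.n.sum() < 1:
            raise ValueError("empty edge table: no readable edges")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": _MONTHS, "n": self.n, "k": self.k})


def aggregate_edges(df: pd.DataFrame) -> EdgeMonthlyTable:
    """Build the monthly opaque-edge table from an ageing table.

    Expects ``capture_month`` and ``edge_type`` columns; rows with
    unreadable or birthmark-only edges are dropped (fish showing only the
    birthmark carry no post-birth deposition signal). Counts pool calendar
    months across years.
    """
    keep = df[df["edge_type"].isin(["opaque", "translucent"])]
    if keep.empty:
        raise ValueError("no readable edges after filtering")
    n = np.zeros(12, dtype=int)
    k = np.zeros(12, dtype=int)
    for m, grp in keep.groupby("capture_month"):
        n[int(m) - 1] = len(grp)
        k[int(m) - 1] = int((grp["edge_type"] == "opaque").sum())
    return EdgeMonthlyTable(n=n, k=k)


@dataclass
class EdgeModelFit:
    hypothesis: str
    params: dict[str, float]
    loglik: float
    n_params: int = field(init=False)
    aic: float = field(init=False)

    def __post_init__(self):
        self.n_params = _N_PARAMS[self.hypothesis]
        self.aic = 2.0 * self.n_params - 2.0 * self.loglik


def edge_probability(month, fit: EdgeModelFit) -> np.ndarray:
    """Opaque-edge probability π(m) under a fitted hypothesis."""
    return _edge_prob(fit.hypothesis, _param_vector(fit), month_angle(month))


def _param_vector(fit: EdgeModelFit) -> np.ndarray:
    p = fit.params
    if fit.hypothesis == "zero_peak":
        return np.array([p["p"]])
    if fit.hypothesis == "one_peak":
        return np.array([p["mu"], p["kappa"], p["amplitude"]])
    return np.array([p["mu1"], p["mu2"], p["kappa"], p["w"], p["amplitude"]])


def _edge_prob(hypothesis: str, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    theta = np.atleast_1d(theta)
    if hypothesis == "zero_peak":
        return np.full_like(theta, x[0], dtype=float)
    if hypothesis == "one_peak":
        mu, kappa, amp = x
        if kappa < 0:
            raise ValueError("von Mises concentration must be >= 0")
        # density ratio f(θ)/f(μ) = exp(κ(cos(θ−μ) − 1)); peak value is A
        return amp * np.exp(kappa * (np.cos(theta - mu) - 1.0))
    mu1, mu2, kappa, w, amp = x
    if kappa < 0:
        raise ValueError("von Mises concentration must be >= 0")
    g = lambda th: (w * np.exp(kappa * np.cos(th - mu1))
                    + (1 - w) * np.exp(kappa * np.cos(th - mu2)))
    grid = np.linspace(0, 2 * np.pi, 1441)
    gmax = g(grid).max()
    return amp * g(theta) / gmax


def _binom_loglik(pi: np.ndarray, n: np.ndarray, k: np.ndarray) -> float:
    pi = np.clip(pi, _EPS, 1.0 - _EPS)
    return float(np.sum(k * np.log(pi) + (n - k) * np.log(1.0 - pi)))


def _neg_ll(hypothesis, x, theta, n, k):
    try:
        pi = _edge_prob(hypothesis, x, theta)
    except ValueError:
        return np.inf
    return -_binom_loglik(pi, n, k)


def fit_edge_model(table: EdgeMonthlyTable, hypothesis: str) -> EdgeModelFit:
    """Maximum-likelihood fit of one periodicity hypothesis.

    Multi-start bounded local optimization: μ start points on a monthly
    grid, plus the embedded solution of the nested simpler hypothesis so
    the likelihood ordering zero ≤ one ≤ two is guaranteed.
    """
    if hypothesis not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    theta = month_angle(_MONTHS)
    n, k = table.n, table.k
    p_hat = min(max(k.sum() / n.sum(), _EPS), 1 - _EPS)

    if hypothesis == "zero_peak":
        ll = _binom_loglik(np.full(12, p_hat), n, k)
        return EdgeModelFit("zero_peak", {"p": float(p_hat)}, ll)

    obs_frac = np.where(n > 0, k / np.maximum(n, 1), p_hat)
    amp0 = min(max(obs_frac.max(), 0.1), 1.0)
    starts: list[np.ndarray] = []
    if hypothesis == "one_peak":
        bounds = [(0.0, 2 * np.pi), (0.0, 50.0), (_EPS, 1.0)]
        for mu0 in month_angle(_MONTHS):
            starts.append(np.array([mu0, 2.0, amp0]))
        starts.append(np.array([np.pi, 1e-6, p_hat]))  # embedded zero_peak
    else:
        bounds = [(0.0, 2 * np.pi), (0.0, 2 * np.pi), (0.0, 50.0),
                  (1e-6, 1 - 1e-6), (_EPS, 1.0)]
        mus = month_angle(_MONTHS[::2])
        for i, m1 in enumerate(mus):
            for m2 in mus[i + 1:]:
                starts.append(np.array([m1, m2, 2.0, 0.5, amp0]))
        one = fit_edge_model(table, "one_peak")  # embedded one_peak
        mu_1 = one.params["mu"]
        starts.append(np.array([mu_1, (mu_1 + np.pi) % (2 * np.pi),
                                one.params["kappa"], 1 - 1e-6,
                                one.params["amplitude"]]))

    best_x, best_nll = None, np.inf
    for x0 in starts:
        res = minimize(lambda x: _neg_ll(hypothesis, x, theta, n, k), x0,
                       method="L-BFGS-B", bounds=bounds)
        cand = [(res.x, res.fun), (x0, _neg_ll(hypothesis, x0, theta, n, k))]
        for x, f in cand:
            if np.isfinite(f) and f < best_nll:
                best_x, best_nll = np.array(x), f
    if best_x is None:
        raise RuntimeError(f"{hypothesis} fit failed to converge from "
                           f"{len(starts)} start points")

    if hypothesis == "one_peak":
        mu, kappa, amp = best_x
        params = {"mu": float(mu % (2 * np.pi)), "kappa": float(kappa),
                  "amplitude": float(amp)}
    else:
        mu1, mu2, kappa, w, amp = best_x
        mu1, mu2 = mu1 % (2 * np.pi), mu2 % (2 * np.pi)
        if mu1 > mu2:  # label-switch guard
            mu1, mu2, w = mu2, mu1, 1 - w
        params = {"mu1": float(mu1), "mu2": float(mu2), "kappa": float(kappa),
                  "w": float(w), "amplitude": float(amp)}
    return EdgeModelFit(hypothesis, params, -best_nll)


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(−Δ_i/2) / Σ exp(−Δ/2)."""
    aics = np.asarray(aics, dtype=float)
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    fits: dict[str, EdgeModelFit]
    table: pd.DataFrame
    best: str


def select_edge_model(table: EdgeMonthlyTable) -> ModelComparison:
    """Fit all three hypotheses and rank them by AIC with Akaike weights."""
    fits = {h: fit_edge_model(table, h) for h in HYPOTHESES}
    aics = np.array([fits[h].aic for h in HYPOTHESES])
    weights = akaike_weights(aics)
    df = pd.DataFrame({"hypothesis": HYPOTHESES, "aic": aics,
                       "delta": aics - aics.min(), "weight": weights,
                       "loglik": [fits[h].loglik for h in HYPOTHESES],
                       "n_params": [fits[h].n_params for h in HYPOTHESES]})
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    return ModelComparison(fits=fits, table=df, best=df.loc[0, "hypothesis"])
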