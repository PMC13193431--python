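"""Theoretical longevity and cross-species comparative life-history statistics.

Longevity follows Ricker's convention: the age at which a growth curve
reaches 95% of its asymptote, 5·ln(2)/k, with k taken from the logistic
model. The comparative layer works over a packaged table of published
dasyatid growth parameters (species, region, model, sex, DW0, DW∞, k, t0,
maximum observed age, n); two Aegean Sea rows carry an exclusion flag
because their k and DW0 estimates are biologically unrealistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from importlib import resources
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

_COMPARATIVE_CSV = "dasyatid_growth_parameters.csv"
_REFERENCE_CSV = "hypostigma_growth_estimates.csv"


def ricker_longevity(k: float) -> float:
    """Theoretical age (years) at 95% of asymptotic size: 5·ln(2)/k."""
    if k <= 0:
        raise ValueError("growth coefficient k must be positive")
    return 5.0 * math.log(2.0) / k


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("raygrowth.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_comparative_table() -> pd.DataFrame:
    """Published dasyatid growth-parameter compilation (packaged fixture)."""
    return _load_packaged(_COMPARATIVE_CSV)


def load_reference_growth_estimates() -> pd.DataFrame:
    """Published posterior-mean growth estimates for the groovebelly
    stingray off the Brazilian Meridional Margin (packaged fixture)."""
    return _load_packaged(_REFERENCE_CSV)


def spearman(x, y, *, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    p-value by the t-approximation, or by exact permutation of one
    variable's pairing for small samples (n ≤ 8 when ``method='auto'``;
    forced with ``method='exact'``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p_t = stats.spearmanr(x, y)
    n = len(x)
    if method == "asymptotic" or (method == "auto" and n > 8):
        return float(rho), float(p_t)
    if n > 8:
        raise ValueError("exact permutation p-value limited to n <= 8")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        count += abs(r) >= obs - 1e-12
        total += 1
    return float(rho), count / total


@dataclass
class ComparativeStats:
    n_rows: int
    rho_k_dwinf: float
    p_k_dwinf: float
    quad_coefs: tuple[float, float, float]   # (c0, c1, c2): DW∞ = c0 + c1·k + c2·k²
    rho_dw0frac_dwinf: float
    p_dw0frac_dwinf: float
    line_coefs: tuple[float, float]          # (intercept, slope) for DW0/DW∞ on DW∞

    def to_dict(self) -> dict:
        return asdict(self)


def comparative_stats(records: pd.DataFrame | None = None, *,
                      exclude_flagged: bool = True,
                      drop_pooled_duplicates: bool = False) -> ComparativeStats:
    """Cross-species statistics over the comparative table.

    Computes (i) Spearman ρ between k and DW∞, (ii) a least-squares
    quadratic DW∞ = c0 + c1·k + c2·k², and (iii) the size-at-birth fraction
    DW0/DW∞: its Spearman ρ with DW∞ and least-squares line.

    ``drop_pooled_duplicates`` removes pooled-sex rows from studies that
    also print sexed fits (the published point set is not stated exactly;
    this exposes the alternative convention).
    """
    df = load_comparative_table() if records is None else records.copy()
    if exclude_flagged and "excluded_flag" in df.columns:
        df = df[df["excluded_flag"] != 1]
    if drop_pooled_duplicates:
        sexed = df[df["sex"].isin(["male", "female"])]
        keys = set(zip(sexed["species"], sexed["region"], sexed["source"]))
        dup = df.apply(lambda r: r["sex"] == "pooled" and
                       (r["species"], r["region"], r["source"]) in keys, axis=1)
        df = df[~dup]
    df = df.dropna(subset=["dw0_mm", "dw_inf_mm", "k_per_year"])
    if len(df) < 4:
        raise ValueError("need at least 4 usable comparative records")
    k = df["k_per_year"].to_numpy()
    dwinf = df["dw_inf_mm"].to_numpy()
    frac = df["dw0_mm"].to_numpy() / dwinf
    rho1, p1 = spearman(k, dwinf)
    c2, c1, c0 = np.polyfit(k, dwinf, 2)
    rho2, p2 = spearman(frac, dwinf)
    slope, intercept = np.polyfit(dwinf, frac, 1)
    return ComparativeStats(
        n_rows=len(df),
        rho_k_dwinf=float(rho1), p_k_dwinf=float(p1),
        quad_coefs=(float(c0), float(c1), float(c2)),
        rho_dw0frac_dwinf=float(rho2), p_dw0frac_dwinf=float(p2),
        line_coefs=(float(intercept), float(slope)))


def row_set_sensitivity(records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sensitivity of the comparative correlations to the row-set convention.

    Reports both correlations under: the default stated-exclusions set,
    inclusion of the flagged rows, dropping pooled duplicates, and every
    leave-one-out subset of the default set.
    """
    base = load_comparative_table() if records is None else records
    rows = []

    def add(label, **kw):
        try:
            s = comparative_stats(base, **kw)
        except ValueError:
            return
        rows.append({"convention": label, "n": s.n_rows,
                     "rho_k_dwinf": s.rho_k_dwinf,
                     "rho_dw0frac_dwinf": s.rho_dw0frac_dwinf})

    add("default (flagged rows excluded)")
    add("flagged rows included", exclude_flagged=False)
    add("pooled duplicates dropped", drop_pooled_duplicates=True)
    usable = base[base["excluded_flag"] != 1].reset_index(drop=True)
    for i in range(len(usable)):
        sub = usable.drop(index=i)
        try:
            s = comparative_stats(sub)
        except ValueError:
            continue
        rows.append({"convention": f"leave-one-out: {usable.loc[i, 'species']} "
                                   f"{usable.loc[i, 'sex']} ({usable.loc[i, 'region']})",
                     "n": s.n_rows, "rho_k_dwinf": s.rho_k_dwinf,
                     "rho_dw0frac_dwinf": s.rho_dw0frac_dwinf})
    return pd.DataFrame(rows)


@dataclass
class LongevityResult:
    sex: str
    k: float
    t95: float
    observed_max: float | None
    difference: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def longevity_report(k_by_sex: dict[str, float],
                     observed_max: dict[str, float] | None = None
                     ) -> list[LongevityResult]:
    """Theoretical vs observed longevity per sex from logistic-model k."""
    out = []
    for sex, k in k_by_sex.items():
        t95 = ricker_longevity(k)
        obs = None if observed_max is None else observed_max.get(sex)
        diff = None if obs is None else t95 - obs
        out.append(LongevityResult(sex=sex, k=k, t95=t95,
                                   observed_max=obs, difference=diff))
    return out
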