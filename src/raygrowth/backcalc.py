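"""DW–VR proportionality, sex pooling by ANCOVA, and body-proportional
back-calculation of size-at-age.

A linear regression DW = a + b·VR between disc width and vertebral radius
establishes that the centrum tracks somatic growth. Whether the sexes share
one line is tested by ANCOVA (nested F-tests: slope interaction, then
intercept given a common slope). Size at earlier ages is reconstructed from
interior band radii under the body-proportional hypothesis (BPH):

    DW_t = DW_c · (a + b·VR_t) / (a + b·VR_c)

with DW_c, VR_c the size and centrum radius at capture and VR_t the radius
of the band laid down at age t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class RegressionFit:
    a: float            # intercept, mm
    b: float            # slope, mm DW per mm VR
    r2: float
    n: int
    residual_sd: float  # mm

    def predict(self, vr) -> np.ndarray:
        return self.a + self.b * np.asarray(vr, dtype=float)


def fit_dw_vr(specimens: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares of disc width on vertebral radius."""
    df = specimens.dropna(subset=["dw_mm", "vr_mm"])
    if len(df) < 3:
        raise ValueError("need at least 3 fish with DW and VR")
    if np.ptp(df["vr_mm"].to_numpy()) == 0:
        raise ValueError("vertebral radius has no variance")
    X = sm.add_constant(df["vr_mm"].to_numpy())
    res = sm.OLS(df["dw_mm"].to_numpy(), X).fit()
    return RegressionFit(a=float(res.params[0]), b=float(res.params[1]),
                         r2=float(res.rsquared), n=int(res.nobs),
                         residual_sd=float(np.sqrt(res.mse_resid)))


@dataclass
class AncovaResult:
    p_slope_interaction: float
    p_intercept_given_common_slope: float
    alpha: float
    pooled: bool
    forced: bool = False  # one sex absent → pooling forced


def ancova_sex(specimens: pd.DataFrame, alpha: float = 0.05) -> AncovaResult:
    """Test whether the sexes share the DW–VR line.

    Nested F-tests: (i) sex×VR interaction against a common slope;
    (ii) sex intercept against a single line, given the common slope.
    ``pooled`` is true iff both p-values exceed ``alpha``.
    """
    df = specimens.dropna(subset=["dw_mm", "vr_mm", "sex"]).copy()
    counts = df["sex"].value_counts()
    if len(counts) < 2 or counts.min() < 3:
        logger.warning("one sex absent or n<3: DW-VR pooling forced")
        return AncovaResult(np.nan, np.nan, alpha, pooled=True, forced=True)
    full = smf.ols("dw_mm ~ vr_mm * C(sex)", data=df).fit()
    add = smf.ols("dw_mm ~ vr_mm + C(sex)", data=df).fit()
    single = smf.ols("dw_mm ~ vr_mm", data=df).fit()
    f_int = full.compare_f_test(add)       # (F, p, df_diff)
    f_sex = add.compare_f_test(single)
    p_int, p_sex = float(f_int[1]), float(f_sex[1])
    return AncovaResult(p_slope_interaction=p_int,
                        p_intercept_given_common_slope=p_sex,
                        alpha=alpha, pooled=(p_int > alpha and p_sex > alpha))


def back_calculate(fish: pd.Series | dict, fit: RegressionFit) -> pd.DataFrame:
    """Back-calculate DW at each band age of one fish under the BPH.

    ``fish`` needs ``fish_id``, ``sex``, ``dw_mm``, ``vr_mm`` and
    ``band_radii_mm`` (ascending, birthmark first, one radius per age
    0..band count). At the capture edge (VR_t = VR_c) the back-calculated
    size equals the capture size by construction.
    """
    fish = dict(fish)
    dw_c, vr_c = float(fish["dw_mm"]), float(fish["vr_mm"])
    radii = np.asarray(fish["band_radii_mm"], dtype=float)
    if vr_c <= 0:
        raise ValueError("capture vertebral radius must be positive")
    if np.any(radii > vr_c + 1e-9):
        raise ValueError("band radii exceed the centrum radius")
    denom = fit.a + fit.b * vr_c
    if denom <= 0:
        logger.warning("fish %s: a + b*VR_c <= 0, BPH ratio undefined; skipped",
                       fish.get("fish_id"))
        return pd.DataFrame(columns=["fish_id", "sex", "age", "dw_back"])
    dw_back = dw_c * (fit.a + fit.b * radii) / denom
    return pd.DataFrame({"fish_id": fish.get("fish_id"),
                         "sex": fish.get("sex"),
                         "age": np.arange(len(radii)),
                         "dw_back": dw_back})


def back_calculate_all(specimens: pd.DataFrame, fit: RegressionFit) -> pd.DataFrame:
    """BPH back-calculation over every fish; skipped fish are logged."""
    parts = [back_calculate(row, fit) for _, row in specimens.iterrows()]
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if out.empty:
        raise ValueError("no fish could be back-calculated")
    return out


def summarize_by_age(pairs: pd.DataFrame, observed: pd.DataFrame) -> pd.DataFrame:
    """Observed vs back-calculated mean DW per sex and age.

    ``observed`` needs ``sex``, ``age`` (accepted band count) and ``dw_mm``
    per fish; ``pairs`` is the back-calculation output. Columns: n and mean
    observed DW at each capture age, m and mean back-calculated DW over all
    band readings at that age. m is non-increasing with age within a sex
    because older bands are nested inside older fish.
    """
    if pairs.empty:
        raise ValueError("no back-calculated pairs to summarize")
    obs = (observed.dropna(subset=["age"])
           .groupby(["sex", "age"])
           .agg(n=("dw_mm", "size"), dw_avg=("dw_mm", "mean"))
           .reset_index())
    back = (pairs.groupby(["sex", "age"])
            .agg(m=("dw_back", "size"), dw_back=("dw_back", "mean"))
            .reset_index())
    out = back.merge(obs, on=["sex", "age"], how="outer").sort_values(
        ["sex", "age"]).reset_index(drop=True)
    out["n"] = out["n"].fillna(0).astype(int)
    out["m"] = out["m"].fillna(0).astype(int)
    return out[["sex", "age", "n", "dw_avg", "m", "dw_back"]]
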