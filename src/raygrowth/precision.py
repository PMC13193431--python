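"""Between-reading ageing precision statistics.

Vertebral band counts are repeated in R ≥ 2 blind reading sessions per fish.
Precision is summarized by the average percentage error (APE), the
coefficient of variation (CV), percent agreement at a tolerance, and an
age-bias table comparing the first (non-reference) against the second
(reference) reading with per-reference-age one-sample t-tests.

For two reading sessions CV = √2·APE exactly, which the test suite uses as
an algebraic cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _as_read_array(reads) -> np.ndarray:
    """Coerce reads to an (n_fish, R) integer array.

    Accepts an ndarray, a DataFrame with ``read1..readR`` columns, or a
    sequence of per-fish tuples.
    """
    if isinstance(reads, pd.DataFrame):
        cols = sorted(c for c in reads.columns if c.startswith("read"))
        if len(cols) < 2:
            raise ValueError("need at least two read columns (read1, read2, ...)")
        arr = reads[cols].to_numpy()
    else:
        arr = np.asarray(reads)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("reads must be (n_fish, R>=2)")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("band counts must be non-negative integers")
    return arr.astype(float)


def _per_fish_ape_cv(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-fish APE and CV terms; fish with zero mean read are masked."""
    xbar = arr.mean(axis=1)
    usable = xbar > 0
    if not usable.any():
        raise ValueError("all fish have zero mean read; APE/CV undefined")
    a = arr[usable]
    xb = xbar[usable]
    R = arr.shape[1]
    ape_j = np.abs(a - xb[:, None]).sum(axis=1) / (R * xb)
    cv_j = a.std(axis=1, ddof=1) / xb
    return ape_j, cv_j, usable


def ape(reads) -> float:
    """Average percentage error across fish, in percent."""
    arr = _as_read_array(reads)
    ape_j, _, _ = _per_fish_ape_cv(arr)
    return float(ape_j.mean() * 100.0)


def cv(reads) -> float:
    """Mean per-fish coefficient of variation of reads, in percent."""
    arr = _as_read_array(reads)
    _, cv_j, _ = _per_fish_ape_cv(arr)
    return float(cv_j.mean() * 100.0)


def percent_agreement(reads, tolerance_years: int = 0) -> float:
    """Percent of fish whose first two reads differ by at most ``tolerance_years``."""
    if tolerance_years < 0:
        raise ValueError("tolerance must be >= 0")
    arr = _as_read_array(reads)
    agree = np.abs(arr[:, 0] - arr[:, 1]) <= tolerance_years
    return float(agree.mean() * 100.0)


@dataclass
class PrecisionReport:
    ape_percent: float
    cv_percent: float
    pct_agree_exact: float
    pct_agree_within_1: float
    n_fish: int

    def to_dict(self) -> dict:
        return {"ape_percent": round(self.ape_percent, 2),
                "cv_percent": round(self.cv_percent, 2),
                "pct_agree_exact": round(self.pct_agree_exact, 2),
                "pct_agree_within_1": round(self.pct_agree_within_1, 2),
                "n_fish": self.n_fish}


def precision_report(reads) -> PrecisionReport:
    arr = _as_read_array(reads)
    return PrecisionReport(
        ape_percent=ape(arr), cv_percent=cv(arr),
        pct_agree_exact=percent_agreement(arr, 0),
        pct_agree_within_1=percent_agreement(arr, 1),
        n_fish=arr.shape[0])


def age_bias(reads) -> pd.DataFrame:
    """Age-bias table: mean non-reference (first) read per reference
    (second) read, with 95% CI and a two-sided one-sample t-test of the
    non-reference reads against the reference age.

    Rows with n = 1 or zero variance carry no test; ``p_value`` is NaN and
    ``test_note`` states the reason.
    """
    arr = _as_read_array(reads)
    nonref, ref = arr[:, 0], arr[:, 1]
    rows = []
    for age in np.unique(ref):
        x = nonref[ref == age]
        n = len(x)
        mean = float(x.mean())
        row = {"reference_age": int(age), "n": n, "mean_nonreference_age": mean,
               "ci_low": math.nan, "ci_high": math.nan,
               "t_stat": math.nan, "p_value": math.nan, "test_note": ""}
        if n < 2:
            row["test_note"] = "n=1: no test"
            row["ci_low"] = row["ci_high"] = mean
        elif np.ptp(x) == 0:
            row["test_note"] = "zero variance: t undefined"
            row["ci_low"] = row["ci_high"] = mean
        else:
            sem = x.std(ddof=1) / math.sqrt(n)
            tcrit = stats.t.ppf(0.975, n - 1)
            row["ci_low"] = mean - tcrit * sem
            row["ci_high"] = mean + tcrit * sem
            tres = stats.ttest_1samp(x, popmean=age)
            row["t_stat"] = float(tres.statistic)
            row["p_value"] = float(tres.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def adjudicate_reads(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve disagreements between the first two reads with a third.

    When read1 == read2 the agreed count is accepted. Otherwise, if a third
    read matches either of the first two, that count is accepted; if there
    is no third read or it matches neither, the fish is dropped from age
    analyses. Returns a copy with an ``age`` column for accepted fish only.
    """
    out = df.copy()
    r1, r2 = out["read1"], out["read2"]
    agreed = r1 == r2
    age = pd.Series(np.where(agreed, r1, -1), index=out.index, dtype=float)
    if "read3" in out.columns:
        r3 = out["read3"]
        tie_ok = (~agreed) & r3.notna() & ((r3 == r1) | (r3 == r2))
        age[tie_ok] = r3[tie_ok]
    out["age"] = age.where(age >= 0, other=np.nan)
    return out[out["age"].notna()].assign(age=lambda d: d["age"].astype(int))
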