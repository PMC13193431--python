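"""Synthetic batoid populations with known growth, band and reading truth.

The generator emulates the statistical structure the downstream analyses
assume: two sexes with dimorphic growth, a linear DW–VR relation shared by
the sexes, band radii placed so that exact body-proportional
back-calculation with the true regression returns the true size-at-age,
seasonal (von Mises) opaque-edge deposition, ±1-year reading error, and
optional size-selective retention mimicking gillnet capture.

Every random stage draws from its own labelled stream spawned from one
integer seed, so adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .growth import predict_size

#: labelled substreams of the master seed, in fixed spawn order
_STREAMS = ("demography", "growth", "vr", "edge", "retention", "reads")

_DEFAULT_MONTHS = tuple(
    (y, m) for y in (2022, 2023, 2024) for m in range(1, 13)
    if (2022, 5) <= (y, m) <= (2024, 4)
)


@dataclass(frozen=True)
class Selectivity:
    """Bell-shaped size-selective retention, exp(−(DW−mode)²/(2·spread²))."""

    mode_mm: float = 375.0
    spread_mm: float = 75.0

    def retention(self, dw) -> np.ndarray:
        z = (np.asarray(dw, dtype=float) - self.mode_mm) / self.spread_mm
        return np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic population.

    Defaults mirror the sampled stingray population: ~3:1 male bias,
    sex-dimorphic logistic growth (females larger, slower), residual size
    scatter of 20 mm, annual opaque-band deposition peaking mid-December,
    monthly sampling May 2022–April 2024, and gillnet-like retention
    concentrating catches around 375 mm DW.
    """

    n_fish: int = 272
    sex_ratio: float = 201 / 272  # fraction male
    true_model: str = "logistic"
    true_params: dict = field(default_factory=lambda: {
        "M": (401.70, 0.45, -0.36),
        "F": (512.22, 0.29, 0.82),
    })
    growth_sd: float = 20.0      # mm residual SD around the curve
    vr_slope: float = 90.0       # b in DW = a + b·VR, mm per mm
    vr_intercept: float = 30.0   # a, mm
    vr_sd: float = 0.1           # mm measurement scatter on VR
    deposition_mean_month: float = 12.0
    deposition_concentration: float = 2.0  # von Mises kappa
    edge_amplitude: float = 0.9            # peak opaque probability
    read_error_prob: float = 0.125
    selectivity: Selectivity | None = Selectivity()
    sampling_months: Sequence[tuple[int, int]] = _DEFAULT_MONTHS
    max_age: int = 11
    age_probs: Sequence[float] | None = None  # default uniform 0..max_age
    seed: int = 0

    def validate(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if not 0.0 <= self.read_error_prob <= 1.0:
            raise ValueError("read_error_prob must be in [0, 1]")
        if min(self.growth_sd, self.vr_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.deposition_concentration < 0:
            raise ValueError("deposition_concentration must be >= 0")
        if not 0.0 < self.edge_amplitude <= 1.0:
            raise ValueError("edge_amplitude must be in (0, 1]")
        if not 1 <= self.deposition_mean_month <= 12:
            raise ValueError("deposition_mean_month must be in [1, 12]")
        for sex, (dw_inf, k, t0) in self.true_params.items():
            if dw_inf <= 0 or k <= 0:
                raise ValueError(f"{sex}: need DW_inf > 0 and k > 0")
            if self._curve(sex, 0.0) < 0:
                raise ValueError(
                    f"{sex}: growth curve negative at age 0 "
                    "(inconsistent parameters)")

    def _curve(self, sex: str, t) -> np.ndarray:
        dw_inf, k, t0 = self.true_params[sex]
        return predict_size(self.true_model, t, dw_inf=dw_inf, k=k, t0=t0)


@dataclass
class SyntheticDataset:
    """Generated population with per-fish truth.

    ``data`` holds one row per fish in the ageing-table schema (band radii
    as a list column); ``truth_trajectories`` is long-form
    (fish_id, age, true_dw) over integer ages 0..true age.
    """

    data: pd.DataFrame
    truth_trajectories: pd.DataFrame
    config: SimulationConfig

    @property
    def specimens(self) -> pd.DataFrame:
        return self.data[["fish_id", "sex", "capture_year", "capture_month",
                          "dw_mm", "gear", "region"]]

    @property
    def vertebrae(self) -> pd.DataFrame:
        cols = ["fish_id", "vr_mm", "band_radii_mm", "edge_type", "read1"]
        cols += [c for c in ("read2", "read3") if c in self.data.columns]
        return self.data[cols]

    @property
    def true_ages(self) -> pd.Series:
        return self.data.set_index("fish_id")["true_age"]


def opaque_probability(month, config: SimulationConfig) -> np.ndarray:
    """Seasonal opaque-edge probability: peak-normalized von Mises link."""
    theta = 2.0 * np.pi * (np.asarray(month, dtype=float) - 0.5) / 12.0
    mu = 2.0 * np.pi * (config.deposition_mean_month - 0.5) / 12.0
    kappa = config.deposition_concentration
    return config.edge_amplitude * np.exp(kappa * (np.cos(theta - mu) - 1.0))


def _draw_fish(config: SimulationConfig, rngs: dict, n: int) -> pd.DataFrame:
    """Draw n candidate fish (before selectivity)."""
    rng_d, rng_g = rngs["demography"], rngs["growth"]
    sex = np.where(rng_d.random(n) < config.sex_ratio, "M", "F")
    ages = np.arange(config.max_age + 1)
    probs = (np.asarray(config.age_probs, dtype=float)
             if config.age_probs is not None else None)
    if probs is not None:
        probs = probs / probs.sum()
    age = rng_d.choice(ages, size=n, p=probs)
    months = np.asarray(config.sampling_months)
    im = rng_d.integers(0, len(months), size=n)
    year, month = months[im, 0], months[im, 1]
    # growth continues between band-deposition events: fractional age from
    # months elapsed since the deposition peak
    frac = ((month - config.deposition_mean_month) % 12) / 12.0
    t_cap = age + frac
    true_dw_cap = np.empty(n)
    true_dw_age = np.empty(n)
    for s in ("M", "F"):
        m = sex == s
        if m.any():
            true_dw_cap[m] = config._curve(s, t_cap[m])
            true_dw_age[m] = config._curve(s, age[m])
    # capture size: curve + residual, truncated so the fish has not shrunk
    # since its last completed band (keeps band radii inside the centrum)
    dw = true_dw_cap + config.growth_sd * rng_g.standard_normal(n)
    if config.growth_sd > 0:
        bad = dw <= true_dw_age
        while bad.any():
            dw[bad] = (true_dw_cap[bad]
                       + config.growth_sd * rng_g.standard_normal(bad.sum()))
            bad = dw <= true_dw_age
    return pd.DataFrame({"sex": sex, "true_age": age, "capture_year": year,
                         "capture_month": month, "dw_mm": dw})


def simulate_population(config: SimulationConfig) -> SyntheticDataset:
    """Generate one population; deterministic given ``config.seed``."""
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    rngs = {name: np.random.default_rng(c)
            for name, c in zip(_STREAMS, children)}

    accepted = []
    n_left = config.n_fish
    for _ in range(1000):
        batch = _draw_fish(config, rngs, max(n_left * 2, 32))
        if config.selectivity is not None:
            keep = (rngs["retention"].random(len(batch))
                    < config.selectivity.retention(batch["dw_mm"]))
            batch = batch[keep.to_numpy() if hasattr(keep, "to_numpy") else keep]
        accepted.append(batch)
        n_left = config.n_fish - sum(len(b) for b in accepted)
        if n_left <= 0:
            break
    df = pd.concat(accepted, ignore_index=True).head(config.n_fish)
    if len(df) < config.n_fish:
        raise RuntimeError("selectivity rejected too many fish; "
                           "check selectivity spread vs. size range")
    df.insert(0, "fish_id", [f"F{i:04d}" for i in range(len(df))])

    a, b = config.vr_intercept, config.vr_slope
    n = len(df)
    vr = (df["dw_mm"].to_numpy() - a) / b + config.vr_sd * rngs["vr"].standard_normal(n)
    bad = a + b * vr <= 0
    while bad.any():
        vr[bad] = ((df["dw_mm"].to_numpy()[bad] - a) / b
                   + config.vr_sd * rngs["vr"].standard_normal(bad.sum()))
        bad = a + b * vr <= 0
    df["vr_mm"] = vr

    # place band radii so BPH back-calculation with the true (a, b) is exact:
    # a + b·VR_t = (true DW at age t / DW_c) · (a + b·VR_c)
    radii_col, truth_rows = [], []
    dw_c = df["dw_mm"].to_numpy()
    scale = (a + b * vr) / dw_c
    for i, row in enumerate(df.itertuples()):
        ages = np.arange(row.true_age + 1)
        true_dw = np.asarray(config._curve(row.sex, ages), dtype=float).reshape(-1)
        r = (true_dw * scale[i] - a) / b
        if not (np.all(np.diff(r) > 0) and r[0] > 0
                and r[-1] <= row.vr_mm + 1e-9):
            raise RuntimeError("generated band radii violate centrum geometry")
        radii_col.append(r)
        truth_rows.append(pd.DataFrame({"fish_id": row.fish_id, "age": ages,
                                        "true_dw": true_dw}))
    df["band_radii_mm"] = radii_col

    pi = opaque_probability(df["capture_month"].to_numpy(), config)
    opaque = rngs["edge"].random(n) < pi
    df["edge_type"] = np.where(df["true_age"] == 0, "birthmark_only",
                               np.where(opaque, "opaque", "translucent"))
    df["read1"] = df["true_age"]
    df["gear"] = "gillnet"
    df["region"] = "RJ"

    truth = pd.concat(truth_rows, ignore_index=True)
    return SyntheticDataset(data=df, truth_trajectories=truth, config=config)


def simulate_double_reads(ds: SyntheticDataset, error_prob: float | None = None,
                          seed: int | None = None) -> SyntheticDataset:
    """Add a second blind reading session.

    The added read equals the true band count with probability
    1 − ``error_prob``; otherwise it is off by ±1 with equal probability,
    floored at zero. Defaults come from the dataset's config (its
    ``read_error_prob`` and a dedicated substream of its seed).
    """
    cfg = ds.config
    if error_prob is None:
        error_prob = cfg.read_error_prob
    if not 0.0 <= error_prob <= 1.0:
        raise ValueError("error_prob must be in [0, 1]")
    if seed is None:
        child = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))[
            _STREAMS.index("reads")]
        rng = np.random.default_rng(child)
    else:
        rng = np.random.default_rng(seed)
    df = ds.data.copy()
    truth = df["true_age"].to_numpy()
    err = rng.random(len(df)) < error_prob
    delta = rng.choice([-1, 1], size=len(df))
    df["read2"] = np.maximum(np.where(err, truth + delta, truth), 0)
    return replace(ds, data=df)
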