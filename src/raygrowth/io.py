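"""Ageing-table file schema, validation and run configuration.

One CSV row per fish: identity, sex, capture date, disc width, vertebral
radius, gear/region labels, edge type, band counts per reading session, and
the ordered band radii (";"-delimited, birthmark first). Validation is
row-level: structurally invalid rows are quarantined with a line-numbered
reason, never silently dropped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["fish_id", "sex", "capture_date", "dw_mm", "vr_mm",
                    "gear", "region", "edge_type", "read1", "read2",
                    "band_radii_mm"]
OPTIONAL_COLUMNS = ["read3"]
EDGE_TYPES = {"opaque", "translucent", "unreadable", "birthmark_only"}


def _parse_radii(cell) -> np.ndarray:
    return np.array([float(x) for x in str(cell).split(";") if x != ""])


def _validate_row(row: pd.Series) -> str | None:
    """Return a quarantine reason, or None if the row is valid."""
    if row["sex"] not in ("M", "F"):
        return f"invalid sex {row['sex']!r}"
    if not row["dw_mm"] > 0:
        return "non-positive disc width"
    if not row["vr_mm"] > 0:
        return "non-positive vertebral radius"
    if row["edge_type"] not in EDGE_TYPES:
        return f"unknown edge type {row['edge_type']!r}"
    try:
        radii = _parse_radii(row["band_radii_mm"])
    except ValueError:
        return "unparseable band radii"
    if len(radii) == 0:
        return "no band radii"
    if np.any(np.diff(radii) <= 0):
        return "non-ascending radii"
    if radii[-1] > row["vr_mm"] + 1e-9:
        return "band radius exceeds vertebral radius"
    for c in ("read1", "read2", "read3"):
        if c in row.index and pd.notna(row[c]) and row[c] < 0:
            return f"negative band count in {c}"
    return None


def read_ageing_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate an ageing table.

    Returns ``(dataset, quarantine)``: valid rows with parsed dates
    (``capture_year``/``capture_month`` added) and radii as arrays, and the
    quarantined rows with ``line`` and ``reason`` columns. Raises on a
    missing file, missing columns or an empty table.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty input")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    reasons = df.apply(_validate_row, axis=1)
    bad = reasons.notna()
    quarantine = df[bad].copy()
    quarantine["line"] = quarantine.index + 2  # header is line 1
    quarantine["reason"] = reasons[bad]
    for _, q in quarantine.iterrows():
        logger.warning("quarantined %s line %d: %s", path.name, q["line"],
                       q["reason"])
    good = df[~bad].copy()
    if good.empty:
        raise ValueError(f"{path}: no valid rows after validation")
    good["band_radii_mm"] = good["band_radii_mm"].map(_parse_radii)
    dates = pd.to_datetime(good["capture_date"])
    good["capture_year"] = dates.dt.year
    good["capture_month"] = dates.dt.month
    good["capture_doy"] = dates.dt.dayofyear
    # count/radii consistency is a warning, not a quarantine: reading error
    # legitimately detaches counts from the radii of the accepted reading
    mism = good["read1"] != good["band_radii_mm"].map(len) - 1
    for fid in good.loc[mism, "fish_id"]:
        logger.warning("fish %s: read1 does not match band-radius count", fid)
    return good.reset_index(drop=True), quarantine.reset_index(drop=True)


def write_ageing_csv(df: pd.DataFrame, path) -> None:
    """Write a dataset in the ageing-table schema (radii ";"-joined)."""
    out = df.copy()
    if "capture_date" not in out.columns:
        out["capture_date"] = pd.to_datetime(dict(
            year=out["capture_year"], month=out["capture_month"],
            day=15)).dt.strftime("%Y-%m-%d")
    out["band_radii_mm"] = out["band_radii_mm"].map(
        lambda r: ";".join(f"{x:.6g}" for x in np.asarray(r)))
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in out.columns]
    extra = [c for c in ("true_age",) if c in out.columns]
    out[cols + extra].to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    input_csv: str | None = None       # None → simulate
    outdir: str = "raygrowth_out"
    seed: int = 0
    alpha: float = 0.05
    n_fish: int = 272
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "precision", "edges", "backcalc", "growth",
        "longevity", "comparative"])
    families: list[str] = field(default_factory=lambda: [
        "vbgm2", "vbgm3", "gompertz", "logistic"])
    force_split_sexes: bool = False    # override the ANCOVA pooling decision
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 3000
    contrast_level: float = 0.90

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_chains < 2 or self.n_warmup < 1 or self.n_samples < 1:
            raise ValueError("invalid MCMC settings")
        if not 0 < self.contrast_level < 1:
            raise ValueError("contrast_level must be in (0, 1)")
        unknown = set(self.families) - {"vbgm2", "vbgm3", "gompertz", "logistic"}
        if unknown:
            raise ValueError(f"unknown growth families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
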