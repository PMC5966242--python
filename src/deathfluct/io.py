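"""CSV and JSON interchange for plate-count data, profiles and estimates.

Dialects (UTF-8, header row, period decimal separator):

* growth/segregation CSV, one row per (replicate, timepoint):
  ``replicate,time_h,cfu_total_per_ml,cfu_plasmid_per_ml,volume_ml``
* mutant-count CSV, one row per culture:
  ``culture,mutants,final_cfu_per_ml,volume_ml,plating_fraction``
* profile CSV, one row per timepoint: ``time_h,size,death_rate`` with the
  death rate on the row that closes its interval (first row blank).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FluctuationDataset, GrowthProfile, RateEstimate, SegregationSeries

__all__ = [
    "ParseError",
    "read_growth_csv",
    "read_counts_csv",
    "read_profile_csv",
    "write_profile_csv",
    "write_counts_csv",
    "write_estimate_json",
    "read_estimate_json",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _line(df_index: int) -> int:
    # +2: header line plus 1-based numbering
    return int(df_index) + 2


def read_growth_csv(path) -> dict[str, SegregationSeries]:
    """Segregation series per replicate from a growth CSV.

    Cell numbers are CFU/mL times culture volume in mL.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, ["replicate", "time_h", "cfu_total_per_ml", "cfu_plasmid_per_ml", "volume_ml"], path
    )
    for col in ("cfu_total_per_ml", "cfu_plasmid_per_ml", "volume_ml"):
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            raise ParseError(f"{path}: line {_line(bad[0])}: non-positive {col}")
    dupes = df.duplicated(subset=["replicate", "time_h"])
    if dupes.any():
        raise ParseError(
            f"{path}: line {_line(df.index[dupes][0])}: duplicate (replicate, time) key"
        )
    out: dict[str, SegregationSeries] = {}
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time_h")
        try:
            out[str(rep)] = SegregationSeries(
                times=grp["time_h"].to_numpy(),
                total=(grp["cfu_total_per_ml"] * grp["volume_ml"]).to_numpy(),
                plasmid_bearing=(grp["cfu_plasmid_per_ml"] * grp["volume_ml"]).to_numpy(),
            )
        except ValueError as e:
            raise ParseError(f"{path}: replicate {rep}: {e}") from e
    return out


def read_counts_csv(path, initial_size: float = 1.0) -> FluctuationDataset:
    """One fluctuation dataset from a mutant-count CSV (one row per culture)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(
        df, ["culture", "mutants", "final_cfu_per_ml", "volume_ml", "plating_fraction"], path
    )
    bad = df.index[df["mutants"] < 0]
    if len(bad):
        raise ParseError(f"{path}: line {_line(bad[0])}: negative mutant count")
    pf = df["plating_fraction"].unique()
    if len(pf) != 1:
        raise ParseError(f"{path}: plating_fraction must be constant within one dataset")
    final_size = float((df["final_cfu_per_ml"] * df["volume_ml"]).mean())
    try:
        return FluctuationDataset(
            counts=df["mutants"].to_numpy(dtype=np.int64),
            final_size=final_size,
            initial_size=initial_size,
            plating_fraction=float(pf[0]),
        )
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_counts_csv(path, dataset: FluctuationDataset, volume_ml: float = 1.0) -> None:
    df = pd.DataFrame(
        {
            "culture": np.arange(1, dataset.n_cultures + 1),
            "mutants": dataset.counts,
            "final_cfu_per_ml": dataset.final_size / volume_ml,
            "volume_ml": volume_ml,
            "plating_fraction": dataset.plating_fraction,
        }
    )
    df.to_csv(path, index=False)


def write_profile_csv(path, profile: GrowthProfile) -> None:
    death = [""] + [repr(d) for d in profile.death_rates]
    df = pd.DataFrame(
        {"time_h": profile.times, "size": profile.sizes, "death_rate": death}
    )
    df.to_csv(path, index=False)


def read_profile_csv(path) -> GrowthProfile:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_h", "size", "death_rate"], path)
    death = pd.to_numeric(df["death_rate"], errors="coerce").to_numpy()
    if not np.isnan(death[0]):
        raise ParseError(f"{path}: line 2: first row must leave death_rate blank")
    if np.isnan(death[1:]).any():
        bad = int(np.flatnonzero(np.isnan(death[1:]))[0]) + 1
        raise ParseError(f"{path}: line {_line(bad)}: missing death_rate")
    try:
        return GrowthProfile(
            times=df["time_h"].to_numpy(),
            sizes=df["size"].to_numpy(),
            death_rates=death[1:],
        )
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_estimate_json(path, estimate: RateEstimate, extra: dict | None = None) -> None:
    payload = {
        "rate": estimate.rate,
        "ci_low": estimate.ci_low,
        "ci_high": estimate.ci_high,
        "method": estimate.method,
        "m_hat": estimate.m_hat,
        "diagnostics": _jsonable(estimate.diagnostics),
    }
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=2))


def read_estimate_json(path) -> RateEstimate:
    data = json.loads(Path(path).read_text())
    return RateEstimate(
        rate=data["rate"],
        ci_low=data["ci_low"],
        ci_high=data["ci_high"],
        method=data["method"],
        m_hat=data["m_hat"],
        diagnostics=data.get("diagnostics", {}),
    )
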