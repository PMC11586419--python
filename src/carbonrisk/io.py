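"""Delimited-text readers/writers and structured config serialization.

One tabular dialect throughout: comma-separated, header row, UTF-8, "."
decimal.  Output files carry a metadata header of ``# key: value`` comment
lines (version, seed, config hash) so any artifact can be regenerated from
its recorded configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbon_dynamics import ARFit, CarbonSeries
from .model_core import LogitParams
from .panel_estimation import DisasterPanel

__all__ = [
    "read_carbon_csv",
    "write_carbon_csv",
    "read_panel_csv",
    "write_panel_csv",
    "write_table",
    "read_table",
    "params_to_dict",
    "params_from_dict",
    "arfit_to_dict",
    "arfit_from_dict",
    "dump_yaml",
    "load_yaml",
    "config_hash",
]


class ParseError(ValueError):
    """A table failed to parse or validate; the message names the location."""


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _metadata_lines(metadata: dict | None) -> str:
    meta = {"generator": f"carbonrisk {__version__}"}
    if metadata:
        meta.update(metadata)
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, metadata: dict | None = None, float_format="%.6g"):
    """Write a DataFrame as CSV with a commented metadata header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_metadata_lines(metadata))
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_carbon_csv(series: CarbonSeries, path, metadata: dict | None = None):
    """Write an annual series as (year, ppm, growth_pct)."""
    df = pd.DataFrame({"year": series.years})
    df["ppm"] = series.levels if series.levels is not None else np.nan
    df["growth_pct"] = series.growth
    write_table(df, path, metadata)


def read_carbon_csv(path) -> CarbonSeries:
    """Read (year, ppm, growth_pct); growth derived as 100*dlog(ppm) if absent."""
    df = read_table(path)
    if "year" not in df.columns:
        raise ParseError(f"{path}: missing 'year' column")
    if "growth_pct" in df.columns and df["growth_pct"].notna().all():
        levels = df["ppm"].to_numpy() if "ppm" in df.columns and df["ppm"].notna().all() else None
        return CarbonSeries(
            years=df["year"].to_numpy(), growth=df["growth_pct"].to_numpy(), levels=levels
        )
    if "ppm" not in df.columns:
        raise ParseError(f"{path}: need either growth_pct or ppm")
    return CarbonSeries.from_levels(df["year"].to_numpy(), df["ppm"].to_numpy())


def write_panel_csv(panel: DisasterPanel, path, metadata: dict | None = None):
    """Write a panel as (country, year, events, urban_share)."""
    df = panel.frame
    out = pd.DataFrame(
        {
            "country": df["country"],
            "year": df["year"],
            "events": df["event_count"] if "event_count" in df.columns else df["event"],
            "urban_share": df["urban_share"],
        }
    )
    write_table(out, path, metadata)


def read_panel_csv(path) -> DisasterPanel:
    """Read (country, year, events, urban_share); rejects duplicate keys."""
    df = read_table(path)
    required = {"country", "year", "events", "urban_share"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dupes = df.duplicated(["country", "year"])
    if dupes.any():
        line = int(df.index[dupes][0]) + 2  # header line is 1
        raise ParseError(f"{path}: duplicate (country, year) key near line {line}")
    frame = df.rename(columns={"events": "event_count"})
    try:
        return DisasterPanel.from_counts(frame)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def params_to_dict(params: LogitParams) -> dict:
    d = {
        "intercept": params.intercept,
        "lag_coeffs": list(params.lag_coeffs),
        "control_coeffs": list(params.control_coeffs),
        "persistence": params.persistence,
    }
    if params.country_effects:
        d["country_effects"] = {str(k): float(v) for k, v in params.country_effects.items()}
    if params.time_effects:
        d["time_effects"] = {int(k): float(v) for k, v in params.time_effects.items()}
    if params.calibration_target is not None:
        d["calibration_target"] = params.calibration_target
    return d


def params_from_dict(d: dict) -> LogitParams:
    return LogitParams(
        intercept=float(d["intercept"]),
        lag_coeffs=tuple(d["lag_coeffs"]),
        control_coeffs=tuple(d.get("control_coeffs", ())),
        persistence=float(d.get("persistence", 0.0)),
        country_effects=d.get("country_effects", {}),
        time_effects={int(k): v for k, v in d.get("time_effects", {}).items()},
        calibration_target=d.get("calibration_target"),
    )


def arfit_to_dict(fit: ARFit) -> dict:
    return {
        "order": fit.order,
        "intercept": fit.intercept,
        "coeffs": list(fit.coeffs),
        "innovation_sd": fit.innovation_sd,
        "diagnostics": {k: v for k, v in fit.diagnostics.items()},
    }


def arfit_from_dict(d: dict) -> ARFit:
    return ARFit(
        order=int(d["order"]),
        intercept=float(d["intercept"]),
        coeffs=tuple(d["coeffs"]),
        innovation_sd=float(d["innovation_sd"]),
        diagnostics=d.get("diagnostics", {}),
    )


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def dump_yaml(obj: dict, path):
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_to_builtin(obj), fh, sort_keys=False)


def load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
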