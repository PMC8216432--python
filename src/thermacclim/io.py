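"""CSV schemas, run configuration and report writing.

The on-disk interchange format is a tidy long CSV with columns
``animal_id, group, period, day, variable, value`` (UTF-8, decimal
point, comma separator).  Run configuration is a flat YAML key:value
file; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import FitConfig, FitResult, TrajectoryDataset
from .model import MEAN_PARAM_NAMES

__all__ = [
    "TRAJECTORY_COLUMNS",
    "VARIABLES",
    "RunConfig",
    "load_config",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "extract_trajectory",
    "write_fit_report",
    "write_provenance",
]

TRAJECTORY_COLUMNS = ("animal_id", "group", "period", "day", "variable", "value")
VARIABLES = ("ADFI_g_d", "ADFI_g_d_kg060", "Tcore_C", "BW_kg")
PERIOD_LABELS = ("P1", "P2", "P3")
DAY_RANGE = (-3.0, 12.0)


class SchemaError(ValueError):
    """A trajectory CSV violated the expected schema."""


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read and validate a tidy trajectory CSV; errors cite line numbers."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"animal_id": str, "group": str, "period": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    # +2: one for the header, one for 1-based numbering
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        if row.period not in PERIOD_LABELS:
            raise SchemaError(f"{path}:{i}: unknown period {row.period!r}")
        if row.variable not in VARIABLES:
            raise SchemaError(f"{path}:{i}: unknown variable {row.variable!r}")
        if not np.isfinite(row.day) or not (DAY_RANGE[0] <= row.day <= DAY_RANGE[1]):
            raise SchemaError(f"{path}:{i}: day {row.day!r} outside {DAY_RANGE}")
        if not np.isfinite(row.value):
            raise SchemaError(f"{path}:{i}: non-finite value")
    return frame[list(TRAJECTORY_COLUMNS)]


def write_trajectory_csv(frame: pd.DataFrame, path) -> None:
    """Write a tidy trajectory CSV with a stable column order and format."""
    out = frame[list(TRAJECTORY_COLUMNS)].copy()
    out.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def extract_trajectory(
    frame: pd.DataFrame,
    variable: str,
    period: str | None = None,
    window: tuple[float, float] = (-1.0, 10.0),
) -> TrajectoryDataset:
    """Select one response variable (and optionally period) for fitting."""
    sub = frame[frame["variable"] == variable]
    if period is not None:
        sub = sub[sub["period"] == period]
    sub = sub[(sub["day"] >= window[0]) & (sub["day"] <= window[1])]
    if sub.empty:
        raise SchemaError(f"no rows for variable={variable!r}, period={period!r}")
    return TrajectoryDataset(
        sub[["animal_id", "group", "day", "value"]],
        variable=variable,
        period=period,
        window=window,
    )


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully-echoed run configuration (see docs/methods.md)."""

    r1: float = 0.25
    r2: float = 0.25
    r_profile: tuple[float, ...] | None = None
    tol: float = 1e-8
    max_iter: int = 500
    multistart: int = 5
    seed: int = 0
    ghq_nodes: int = 9
    alpha: float = 0.05
    td_lo: float = -1.0
    td_hi: float = 10.0
    preset: str | None = None
    n_animals: int | None = None

    def fit_config(self) -> FitConfig:
        return FitConfig(
            r1=self.r1,
            r2=self.r2,
            r_profile=tuple(self.r_profile) if self.r_profile else None,
            td_bounds=(self.td_lo, self.td_hi),
            tol=self.tol,
            max_iter=self.max_iter,
            n_multistart=self.multistart,
            seed=self.seed,
            ghq_nodes=self.ghq_nodes,
            alpha=self.alpha,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["r_profile"] is not None:
            d["r_profile"] = list(d["r_profile"])
        return d


def load_config(path) -> RunConfig:
    """Load a flat YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {unknown}")
    if "r_profile" in raw and raw["r_profile"] is not None:
        raw["r_profile"] = tuple(float(v) for v in raw["r_profile"])
    return RunConfig(**raw)


def write_fit_report(fit: FitResult, prefix) -> list[Path]:
    """Write a fit report as CSV and text, one row per group.

    The CSV mirrors the published layout: per group y0 (SE), v1 (SE),
    v2 (SE), td1 (SE), td2 (SE), then the shared variance components
    and the conditional adjusted R^2.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in fit.groups:
        p = fit.params_by_group[g]
        se = (fit.se_by_group or {}).get(g, {})
        row = {"group": g}
        for name in MEAN_PARAM_NAMES:
            row[name] = getattr(p, name)
            row[f"se_{name}"] = se.get(name, np.nan)
        row.update(
            r1=p.r1,
            r2=p.r2,
            sigma_r2=fit.variance.sigma_r2,
            sigma_e2=fit.variance.sigma_e2,
            adj_r2=fit.adjusted_r2,
            loglik=fit.loglik,
            n_obs=fit.n_obs,
            converged=fit.converged,
        )
        rows.append(row)
    csv_path = prefix.with_suffix(".csv")
    txt_path = prefix.with_suffix(".txt")
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.6g")
    txt_path.write_text(fit.summary() + "\n")
    return [csv_path, txt_path]


def write_provenance(path, seed, config: RunConfig, labels=None, extra=None) -> None:
    """JSON sidecar recording how an output file was produced."""
    from . import __version__

    payload = {
        "package": "thermacclim",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "presets": list(labels) if labels else None,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
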