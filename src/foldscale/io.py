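"""Delimited-text I/O and run configuration.

Titration tables are TSV with a header and '#' comment lines; columns:
``mutant_id  denaturant_M  signal  arm  [mimetic]``.  Fit reports are
written as TSV or JSON with at least 8 significant digits so a
write-read round trip reproduces the values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DuplicatePoint, FormatError, ParseError
from .fitting import FitResult
from .models import ThermoThreeState, TitrationCurve

__all__ = [
    "RunConfig",
    "read_titration_table",
    "write_titration_table",
    "write_report",
    "read_report",
]

_REQUIRED = ["mutant_id", "denaturant_M", "signal", "arm"]
_ARMS = {"folding", "unfolding"}


@dataclass
class RunConfig:
    """Analysis configuration; round-trips losslessly through YAML."""

    temperature: float = 298.15
    aicc_margin: float = 10.0
    population_floor: float = 0.20
    dg_selector: str = "auto"
    reference_residue: str = "A"
    excluded_asa: list[str] = field(default_factory=list)
    excluded_scales: list[str] = field(default_factory=list)
    Q_R: float = 1.0
    tol_Cm: float = 0.2
    tol_gap: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature", "aicc_margin", "population_floor",
                     "Q_R", "tol_Cm", "tol_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_titration_table(path: str | Path) -> list[TitrationCurve]:
    """Read titration curves, grouped by (mutant_id, arm, mimetic).

    Rows are sorted ascending in denaturant; duplicate (mutant, arm,
    concentration) rows are an error, as are missing columns or
    non-numeric cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty titration table") from None
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty titration table")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "mimetic" not in df.columns:
        df["mimetic"] = ""
    for col in ("denaturant_M", "signal"):
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric value in {col!r}: {exc}")
    bad = set(df["arm"]) - _ARMS
    if bad:
        raise FormatError(f"{path}: unknown arm labels {sorted(bad)}")

    curves = []
    for (mid, arm, mim), grp in df.groupby(["mutant_id", "arm", "mimetic"],
                                           sort=True):
        grp = grp.sort_values("denaturant_M")
        dups = grp["denaturant_M"].duplicated()
        if dups.any():
            d = grp.loc[dups, "denaturant_M"].iloc[0]
            raise DuplicatePoint(
                f"{path}: duplicate point ({mid}, {arm}, {d} M)")
        curves.append(TitrationCurve(
            mutant_id=str(mid), denaturant=grp["denaturant_M"].to_numpy(),
            signal=grp["signal"].to_numpy(), arm=str(arm), mimetic=str(mim)))
    return curves


def write_titration_table(curves: Sequence[TitrationCurve],
                          path: str | Path) -> None:
    """Write curves in the same TSV format :func:`read_titration_table` reads."""
    rows = []
    for c in curves:
        for d, s in zip(c.denaturant, c.signal):
            rows.append((c.mutant_id, f"{d:.10g}", f"{s:.10g}", c.arm,
                         c.mimetic))
    df = pd.DataFrame(rows, columns=_REQUIRED + ["mimetic"])
    df.to_csv(path, sep="\t", index=False)


# field order is fixed for diff-ability
_REPORT_FIELDS = [
    "mutant_id", "model", "dG0", "dG1", "m1", "dG2", "m2", "dG_total",
    "m", "Cm", "dG_err", "m_err", "residual_sum", "n_points", "aicc",
    "apparent", "max_intermediate_population",
]


def _result_row(res: FitResult) -> dict:
    row: dict = {k: None for k in _REPORT_FIELDS}
    row["mutant_id"] = res.mutant_id
    row["model"] = res.model
    row["residual_sum"] = res.residual_sum
    row["n_points"] = res.n_points
    row["aicc"] = res.aicc
    row["apparent"] = bool(res.apparent)
    row["max_intermediate_population"] = res.max_intermediate_population
    if isinstance(res.thermo, ThermoThreeState):
        t = res.thermo
        row.update(dG1=t.dG1, m1=t.m1, dG2=t.dG2, m2=t.m2,
                   dG_total=t.dG_total,
                   Cm=max(t.midpoint1, t.midpoint2),
                   dG_err=res.param_errors.get("dG_total"))
    else:
        t = res.thermo
        row.update(dG0=t.dG0, dG_total=t.dG0, m=t.m, Cm=t.Cm,
                   dG_err=res.param_errors.get("dG0"),
                   m_err=res.param_errors.get("m"))
    return row


def write_report(results: Sequence[FitResult], path: str | Path,
                 format: str = "tsv") -> None:
    """Write one row per fitted variant (TSV or JSON, >= 8 sig. digits)."""
    if not results:
        raise ValueError("no results to write")
    rows = [_result_row(r) for r in results]
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(rows, columns=_REPORT_FIELDS)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        path.write_text(json.dumps(rows, indent=2, allow_nan=True))
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read a report back as a DataFrame with the canonical field order."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif format == "json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return df.reindex(columns=_REPORT_FIELDS)
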