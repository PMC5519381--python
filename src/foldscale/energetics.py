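"""Per-residue partitioning free-energy scales and regression analyses.

A guest-residue library (one titration fit per amino acid at a host
position) is turned into a water-to-interface partitioning scale

    ddG0_w,i(X) = dG0(reference) - dG0(X)          (reference: alanine)

for a lipid-facing (phi) or protein-facing (pi) interface position.  The
scale is then regressed against side-chain accessible-surface-area changes
(the slope being the atomic solvation parameter, ASP, kcal mol^-1 A^-2)
and against published hydrophobicity scales, optionally on caller-chosen
residue subsets (hydrophobic vs hydrophilic) for conditional correlations.

Exclusion lists are always explicit caller input: published analyses drop
specific outliers (Cys, Ser, Trp...) per figure without an algorithmic
rule, so no automatic outlier rejection is performed here.  Deletion
variants (codes longer than one letter, e.g. ``"dF"``) have no defined
side-chain ASA change and are always excluded from ASA regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateX,
    InsufficientData,
    MissingASA,
    MissingReference,
    SelectorMismatch,
)
from .fitting import FitResult
from .models import ThermoThreeState

__all__ = [
    "PartitioningScale",
    "ASATable",
    "ReferenceScale",
    "RegressionResult",
    "build_partitioning_scale",
    "linear_correlation",
    "atomic_solvation_parameter",
    "conditional_scale_correlation",
    "load_asa_table",
    "load_reference_scale",
    "packaged_scale_names",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

Environment = Literal["phi", "pi"]
DGSelector = Literal["U_to_N_total", "U_to_I", "I_to_N", "auto"]


@dataclass(frozen=True)
class PartitioningScale:
    """Per-residue ddG0_w,i values referenced to one residue (zero there)."""

    environment: Environment
    reference_residue: str
    values: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.get(self.reference_residue) != 0.0:
            raise ValueError("reference residue must map to exactly 0")


@dataclass(frozen=True)
class ASATable:
    """Per-residue side-chain surface-area changes (A^2)."""

    delta_nonpolar: dict[str, float]
    delta_total: dict[str, float]
    avg_buried: dict[str, float]
    source: str = ""

    def field(self, which: str) -> dict[str, float]:
        try:
            return {"nonpolar": self.delta_nonpolar,
                    "total": self.delta_total,
                    "buried": self.avg_buried}[which]
        except KeyError:
            raise ValueError(f"unknown area field {which!r}") from None


@dataclass(frozen=True)
class ReferenceScale:
    """A published per-residue free-energy scale (kcal mol^-1)."""

    name: str
    values: dict[str, float]
    source: str = ""


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line with its Pearson correlation."""

    slope: float
    intercept: float
    r: float
    n_used: int
    excluded: tuple[str, ...] = ()
    slope_err: float = float("nan")
    intercept_err: float = float("nan")


def _select_dG(fit: FitResult, selector: DGSelector) -> tuple[float, str]:
    three = isinstance(fit.thermo, ThermoThreeState)
    if selector == "auto":
        selector = "U_to_I" if three else "U_to_N_total"
    if selector == "U_to_N_total":
        return fit.dG_total, ("dG_U_to_I + dG_I_to_N" if three else "dG_U_to_N")
    if not three:
        raise SelectorMismatch(
            f"{selector} requested but {fit.mutant_id!r} is a two-state fit")
    if selector == "U_to_I":
        return fit.thermo.dG_U_to_I, "dG_U_to_I"
    if selector == "I_to_N":
        return fit.thermo.dG_I_to_N, "dG_I_to_N"
    raise ValueError(f"unknown dg_selector {selector!r}")


def build_partitioning_scale(
    fits: Mapping[str, FitResult],
    environment: Environment,
    reference_residue: str = "A",
    dg_selector: DGSelector = "auto",
) -> PartitioningScale:
    """Build a ddG0_w,i scale from a fitted guest-residue library.

    ``dg_selector`` picks which free energy enters per residue:
    ``U_to_N_total`` (the state-function total), ``U_to_I`` or ``I_to_N``
    (per-transition, three-state fits only), or ``auto`` (total for
    two-state fits, U->I for three-state fits -- the convention used when
    the U->I transition is taken as the better measure of global folding).
    The choice actually used per residue is recorded in ``provenance`` so
    any mixture stays auditable.
    """
    if reference_residue not in fits:
        raise MissingReference(
            f"reference residue {reference_residue!r} absent from the library")
    ref_dG, _ = _select_dG(fits[reference_residue],
                           "U_to_N_total" if dg_selector == "auto" else dg_selector)
    values: dict[str, float] = {}
    prov: dict[str, str] = {}
    for res, fit in fits.items():
        dG, label = _select_dG(fit, dg_selector)
        values[res] = ref_dG - dG
        prov[res] = label
    values[reference_residue] = 0.0
    return PartitioningScale(environment=environment,
                             reference_residue=reference_residue,
                             values=values, provenance=prov)


def linear_correlation(
    x: Mapping[str, float],
    y: Mapping[str, float],
    excluded: Sequence[str] = (),
) -> RegressionResult:
    """OLS of y on x over residues shared by both maps, minus exclusions."""
    excluded = tuple(excluded)
    keys = sorted((set(x) & set(y)) - set(excluded))
    if len(keys) < 3:
        raise InsufficientData(
            f"only {len(keys)} shared residues after exclusions; need >= 3")
    xv = np.array([x[k] for k in keys], dtype=float)
    yv = np.array([y[k] for k in keys], dtype=float)
    if np.ptp(xv) == 0:
        raise DegenerateX("zero variance on the regression abscissa")
    res = stats.linregress(xv, yv)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r=float(res.rvalue), n_used=len(keys),
                            excluded=excluded,
                            slope_err=float(res.stderr),
                            intercept_err=float(res.intercept_stderr))


def atomic_solvation_parameter(
    scale: PartitioningScale,
    asa: ASATable,
    area_field: Literal["nonpolar", "total", "buried"] = "nonpolar",
    excluded: Sequence[str] = (),
) -> RegressionResult:
    """Regress the partitioning scale on an ASA change; slope = ASP.

    For a lipid-facing (phi) scale a direct (positive-slope) relation with
    the non-polar ASA change is expected; for a protein-facing (pi) scale
    an inverse (negative-slope) one.  Deletion variants are excluded
    automatically; residues present in the scale but absent from the ASA
    table raise :class:`MissingASA`.
    """
    area = asa.field(area_field)
    auto_excluded = [r for r in scale.values if r not in STANDARD_RESIDUES]
    missing = [r for r in scale.values
               if r in STANDARD_RESIDUES and r not in area
               and r not in excluded]
    if missing:
        raise MissingASA(f"no ASA entry for residues {missing}")
    return linear_correlation(area, scale.values,
                              excluded=tuple(excluded) + tuple(auto_excluded))


def conditional_scale_correlation(
    scale: PartitioningScale,
    ref: ReferenceScale,
    subset_a: Sequence[str],
    subset_b: Sequence[str],
    excluded: Sequence[str] = (),
) -> tuple[RegressionResult, RegressionResult]:
    """Independent regressions of the scale on a reference scale per subset.

    Subsets (e.g. hydrophobic vs hydrophilic residues) are caller-supplied
    and may overlap; each must leave at least three shared residues.
    """
    def _sub(subset):
        xs = {r: ref.values[r] for r in subset if r in ref.values}
        ys = {r: scale.values[r] for r in subset if r in scale.values}
        return linear_correlation(xs, ys, excluded=excluded)

    return _sub(list(subset_a)), _sub(list(subset_b))


# ----------------------------------------------------------------------
# packaged tables
# ----------------------------------------------------------------------

def _read_packaged(relpath: str) -> pd.DataFrame:
    ref = resources.files("foldscale").joinpath(relpath)
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_asa_table(path: str | None = None) -> ASATable:
    """Load a side-chain ASA table (packaged literature values by default).

    Expected columns: residue, delta_nonpolar, delta_total, avg_buried.
    """
    if path is None:
        df = _read_packaged("data/asa_sidechain.tsv")
        source = "packaged transcription of literature side-chain ASA values"
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        source = str(path)
    need = {"residue", "delta_nonpolar", "delta_total", "avg_buried"}
    if not need <= set(df.columns):
        raise ValueError(f"ASA table needs columns {sorted(need)}")
    df = df.set_index("residue")
    return ASATable(delta_nonpolar=df["delta_nonpolar"].to_dict(),
                    delta_total=df["delta_total"].to_dict(),
                    avg_buried=df["avg_buried"].to_dict(),
                    source=source)


def packaged_scale_names() -> list[str]:
    base = resources.files("foldscale").joinpath("data/scales")
    return sorted(p.name[:-4] for p in base.iterdir() if p.name.endswith(".tsv"))


def load_reference_scale(name_or_path: str) -> ReferenceScale:
    """Load a published hydrophobicity scale by packaged name or TSV path.

    Expected columns: residue, value; citation metadata lives in '#'
    header comments.
    """
    try:
        df = _read_packaged(f"data/scales/{name_or_path}.tsv")
        source = f"packaged scale {name_or_path!r}"
        name = name_or_path
    except FileNotFoundError:
        df = pd.read_csv(name_or_path, sep="\t", comment="#")
        source = str(name_or_path)
        name = str(name_or_path)
    if not {"residue", "value"} <= set(df.columns):
        raise ValueError("reference scale needs columns residue, value")
    return ReferenceScale(name=name,
                          values=df.set_index("residue")["value"].to_dict(),
                          source=source)
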