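"""Synthetic titrations, spectra and whole guest-residue libraries.

The generators reproduce the statistical structure the analysis assumes --
linear baselines, LEM transitions, homoscedastic Gaussian signal noise --
so every pipeline stage is testable without the original raw data.  They
are pure functions of (parameters, seed).

Stated-world defaults: a 0.7-6.6 M GdnHCl grid at 0.1 M increments (the
acquisition protocol of the experiments being emulated), tryptophan-like
descending signal (folded bright, unfolded dim), and library free
energies laid on a linear ddG-vs-nonpolar-dASA relation with slope
magnitude 0.043 kcal mol^-1 A^-2 (the atomic solvation parameter reported
for the lipid-facing interface).  Reference free energies and m values
are chosen once so that every variant's midpoint stays inside the grid:
phi libraries use dG_ref = 11, m = 2.5; pi libraries dG_ref = 9, m = 3.0
(two-state m values in micelles span roughly 1-4 kcal mol^-1 M^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .energetics import ASATable
from .exceptions import MissingASA
from .models import (
    Baselines,
    ThermoThreeState,
    ThermoTwoState,
    TitrationCurve,
    three_state_signal,
    two_state_signal,
)
from .spectral import EmissionSpectrum

__all__ = [
    "NoiseModel",
    "LibrarySpec",
    "LibraryTruth",
    "default_grid",
    "default_baselines",
    "synthetic_asa_table",
    "simulate_two_state_curve",
    "simulate_three_state_curve",
    "simulate_emission_spectra",
    "simulate_mutant_library",
    "HYDROPHOBIC_INTERMEDIATE_SET",
]

#: residues whose substitution at a protein-facing interface position
#: promotes a stable folding intermediate in the emulated study design
HYDROPHOBIC_INTERMEDIATE_SET = frozenset("WYFLIVM")


def default_grid(start: float = 0.7, stop: float = 6.6, step: float = 0.1
                 ) -> np.ndarray:
    """Denaturant grid, 0.7-6.6 M at 0.1 M increments by default."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def default_baselines(three_state: bool = False) -> Baselines:
    """Tryptophan-like baselines: folded bright, unfolded dim, gentle slopes."""
    if three_state:
        return Baselines(yF=1.00, mF=-0.020, yU=0.35, mU=-0.010,
                         yI=0.65, mI=-0.015)
    return Baselines(yF=1.00, mF=-0.020, yU=0.35, mU=-0.010)


@dataclass(frozen=True)
class NoiseModel:
    """Homoscedastic Gaussian signal noise.

    ``sigma_rel`` is the standard deviation as a fraction of the
    folded-signal amplitude at zero denaturant.  A seed is mandatory:
    generators must be reproducible.
    """

    sigma_rel: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be nonnegative")


def _noise(noise: NoiseModel, amplitude: float, n: int) -> np.ndarray:
    rng = np.random.default_rng(noise.seed)
    return rng.normal(0.0, noise.sigma_rel * amplitude, size=n)


def simulate_two_state_curve(
    thermo: ThermoTwoState,
    baselines: Baselines,
    grid: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    mutant_id: str = "",
    arm: str = "folding",
    mimetic: str = "DPC",
) -> TitrationCurve:
    """Forward-simulate a two-state titration with Gaussian signal noise."""
    D = default_grid() if grid is None else np.asarray(grid, dtype=float)
    y = two_state_signal(D, thermo, baselines)
    if noise is not None and noise.sigma_rel > 0:
        amp = abs(baselines.folded(0.0) - baselines.unfolded(0.0))
        y = y + _noise(noise, amp, D.size)
    return TitrationCurve(mutant_id=mutant_id, denaturant=D, signal=y,
                          arm=arm, mimetic=mimetic, temperature=thermo.T)


def simulate_three_state_curve(
    thermo: ThermoThreeState,
    baselines: Baselines,
    grid: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    mutant_id: str = "",
    arm: str = "folding",
    mimetic: str = "DPC",
) -> TitrationCurve:
    """Forward-simulate a three-state titration with Gaussian signal noise."""
    D = default_grid() if grid is None else np.asarray(grid, dtype=float)
    y = three_state_signal(D, thermo, baselines)
    if noise is not None and noise.sigma_rel > 0:
        amp = abs(baselines.folded(0.0) - baselines.unfolded(0.0))
        y = y + _noise(noise, amp, D.size)
    return TitrationCurve(mutant_id=mutant_id, denaturant=D, signal=y,
                          arm=arm, mimetic=mimetic, temperature=thermo.T)


def simulate_emission_spectra(
    f_U: float,
    lam_F: float = 344.0,
    lam_U: float = 352.0,
    yield_ratio: float = 1.0,
    width: float = 25.0,
    grid: Sequence[float] | None = None,
) -> EmissionSpectrum:
    """Two-Gaussian-band emission spectrum of a folded/unfolded mixture.

    The folded band is centered at ``lam_F`` (344 nm, the folded-state
    emission maximum of the emulated protein); the unfolded band center
    (352 nm) and the common FWHM (25 nm) are package defaults, not values
    from any measurement.  Band areas are (1 - f_U) and
    ``yield_ratio * f_U``: the unfolded species may fluoresce with a
    different quantum yield, which is exactly what the Q_R correction of
    :func:`foldscale.spectral.qr_correct` undoes.
    """
    if not 0.0 <= f_U <= 1.0:
        raise ValueError("f_U must lie in [0, 1]")
    lam = (np.arange(320.0, 400.0 + 0.25, 0.5) if grid is None
           else np.asarray(grid, dtype=float))
    sigma = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    bandF = norm * np.exp(-0.5 * ((lam - lam_F) / sigma) ** 2)
    bandU = norm * np.exp(-0.5 * ((lam - lam_U) / sigma) ** 2)
    inten = (1.0 - f_U) * bandF + yield_ratio * f_U * bandU
    return EmissionSpectrum(wavelengths=lam, intensities=inten)


@dataclass(frozen=True)
class LibrarySpec:
    """Design of a synthetic 20-residue guest library.

    ``asp_true`` carries its sign: positive for a lipid-facing (phi)
    library where burying non-polar surface stabilizes, negative for a
    protein-facing (pi) library with the inverse relation.  Free energies
    follow dG(X) = dG_reference - asp_true * (dASA_np(X) - dASA_np(ref)).
    """

    environment: str = "phi"
    reference_residue: str = "A"
    asp_true: float = 0.043
    dG_reference: float | None = None
    m_true: float | None = None
    three_state_residues: frozenset[str] = frozenset()
    asa: ASATable | None = None
    grid: np.ndarray = field(default_factory=default_grid)
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(0.02, 0))

    def resolved(self) -> "LibrarySpec":
        """Fill environment-dependent defaults (see module docstring)."""
        dG = self.dG_reference
        m = self.m_true
        if dG is None:
            dG = 11.0 if self.environment == "phi" else 9.0
        if m is None:
            m = 2.5 if self.environment == "phi" else 3.0
        asa = self.asa if self.asa is not None else synthetic_asa_table()
        return LibrarySpec(environment=self.environment,
                           reference_residue=self.reference_residue,
                           asp_true=self.asp_true, dG_reference=dG, m_true=m,
                           three_state_residues=self.three_state_residues,
                           asa=asa, grid=self.grid, noise=self.noise)


@dataclass(frozen=True)
class LibraryTruth:
    """Ground-truth record accompanying a simulated library."""

    dG_total: dict[str, float]
    thermo: dict[str, ThermoTwoState | ThermoThreeState]
    baselines: dict[str, Baselines]
    spec: LibrarySpec


# Synthetic side-chain nonpolar ASA-change table (A^2).  The values are a
# plausible, deterministic stand-in spanning the real range (small polar
# side chains near or below alanine, large aromatics ~150 A^2 above); they
# are NOT literature values -- tests must not depend on the real tables.
_SYNTH_DELTA_NP = {
    "G": -25.0, "A": 0.0, "S": 5.0, "C": 25.0, "D": 12.0, "P": 40.0,
    "N": 15.0, "T": 30.0, "E": 35.0, "V": 75.0, "Q": 38.0, "H": 55.0,
    "M": 95.0, "I": 100.0, "L": 98.0, "K": 70.0, "R": 60.0, "F": 120.0,
    "Y": 110.0, "W": 150.0,
}


def synthetic_asa_table() -> ASATable:
    """Synthetic stand-in ASA table (labelled synthetic; not literature data)."""
    np_ = dict(_SYNTH_DELTA_NP)
    total = {r: v + 40.0 for r, v in np_.items()}
    buried = {r: 0.8 * v + 30.0 for r, v in np_.items()}
    return ASATable(delta_nonpolar=np_, delta_total=total, avg_buried=buried,
                    source="synthetic stand-in table for tests")


def _split_three_state(total: float, T: float) -> ThermoThreeState:
    """Split a total free energy into two transitions with fixed midpoints.

    Midpoints are pinned at 2.2 M (I<->N) and 4.4 M (U<->I) so the two
    transitions stay resolved inside the default grid; the split preserves
    the total exactly (free energy is a state function).
    """
    cm1, cm2 = 2.2, 4.4
    dG1 = 0.35 * total
    dG2 = 0.65 * total
    return ThermoThreeState(dG1=dG1, m1=dG1 / cm1, dG2=dG2, m2=dG2 / cm2, T=T)


def simulate_mutant_library(
    spec: LibrarySpec,
    temperature: float = 298.15,
) -> tuple[dict[str, TitrationCurve], LibraryTruth]:
    """Simulate a 20-residue guest library and return curves plus truth.

    Each residue X gets a true free energy on the linear ASA relation; the
    residues in ``spec.three_state_residues`` are simulated with an
    equilibrium intermediate whose two transitions sum exactly to the
    two-state total.  Per-residue noise seeds are derived deterministically
    from ``spec.noise.seed``.
    """
    spec = spec.resolved()
    area = spec.asa.delta_nonpolar
    ref = spec.reference_residue
    if ref not in area:
        raise MissingASA(f"reference residue {ref!r} missing from ASA table")
    residues = sorted(area)
    curves: dict[str, TitrationCurve] = {}
    truth_total: dict[str, float] = {}
    truth_thermo: dict[str, ThermoTwoState | ThermoThreeState] = {}
    truth_bl: dict[str, Baselines] = {}
    ss = np.random.SeedSequence(spec.noise.seed)
    child_seeds = ss.generate_state(len(residues)) % (2**31 - 1)
    for res, seed in zip(residues, child_seeds):
        dG = spec.dG_reference - spec.asp_true * (area[res] - area[ref])
        nm = NoiseModel(spec.noise.sigma_rel, int(seed))
        if res in spec.three_state_residues:
            thermo = _split_three_state(dG, temperature)
            bl = default_baselines(three_state=True)
            curve = simulate_three_state_curve(thermo, bl, spec.grid, nm,
                                               mutant_id=res)
        else:
            thermo = ThermoTwoState(dG0=dG, m=spec.m_true, T=temperature)
            bl = default_baselines()
            curve = simulate_two_state_curve(thermo, bl, spec.grid, nm,
                                             mutant_id=res)
        curves[res] = curve
        truth_total[res] = dG
        truth_thermo[res] = thermo
        truth_bl[res] = bl
    return curves, LibraryTruth(dG_total=truth_total, thermo=truth_thermo,
                                baselines=truth_bl, spec=spec)
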