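"""Closed-form thermodynamic models for equilibrium chemical denaturation.

The package analyses guanidine-hydrochloride titrations of a membrane
protein monitored by an optical signal (tryptophan fluorescence).  Under
the linear extrapolation model (LEM) the folding free energy varies
linearly with denaturant concentration,

    dG(D) = dG0 - m * D        (stability convention, dG0 >= 0, m > 0)

so a two-state system populates the unfolded state with probability

    f_U(D) = exp(x) / (1 + exp(x)),   x = -(dG0 - m * D) / (R * T)

and the denaturation midpoint is Cm = dG0 / m.  A three-state system adds
an intermediate with its own linear baseline; the observed signal is the
Boltzmann-weighted average of the three state baselines.

Everything here is a pure function of its inputs; estimation lives in
:mod:`foldscale.fitting` and data generation in :mod:`foldscale.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit, softmax

from .exceptions import BaselineDegenerate, DegenerateSlope

#: gas constant, kcal mol^-1 K^-1
R_KCAL: float = 1.9872e-3

#: default temperature, kelvin (samples equilibrated at 25 degC)
T_DEFAULT: float = 298.15

Arm = Literal["folding", "unfolding"]


@dataclass(frozen=True)
class TitrationCurve:
    """One equilibrium denaturation experiment.

    Parameters
    ----------
    mutant_id : str
        Identifier of the variant, e.g. ``"F"`` for a single guest residue
        or a free-form construct name.
    denaturant : array-like of float
        GdnHCl concentrations in M, strictly increasing.
    signal : array-like of float
        Observed signal (arbitrary fluorescence units), same length.
    arm : {"folding", "unfolding"}
        Direction of the titration.
    mimetic : str
        Membrane mimetic tag (e.g. ``"DPC"``, ``"DLPC-SUV"``).
    temperature : float
        Kelvin; defaults to 298.15 K.
    """

    mutant_id: str
    denaturant: np.ndarray
    signal: np.ndarray
    arm: Arm = "folding"
    mimetic: str = "DPC"
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        d = np.asarray(self.denaturant, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if d.ndim != 1 or y.shape != d.shape:
            raise ValueError("denaturant and signal must be 1-d and equal length")
        if d.size >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("denaturant concentrations must be strictly increasing")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive kelvin")
        if self.arm not in ("folding", "unfolding"):
            raise ValueError(f"unknown arm {self.arm!r}")
        object.__setattr__(self, "denaturant", d)
        object.__setattr__(self, "signal", y)

    def __len__(self) -> int:
        return self.denaturant.size


@dataclass(frozen=True)
class Baselines:
    """Linear pre-/post-transition baselines, signal = intercept + slope * D.

    ``yI``/``mI`` describe the intermediate-state baseline and are present
    only for three-state models.
    """

    yF: float
    mF: float
    yU: float
    mU: float
    yI: float | None = None
    mI: float | None = None

    def __post_init__(self) -> None:
        vals = [self.yF, self.mF, self.yU, self.mU]
        if self.yI is not None or self.mI is not None:
            if self.yI is None or self.mI is None:
                raise ValueError("yI and mI must be given together")
            vals += [self.yI, self.mI]
        if not np.all(np.isfinite(vals)):
            raise ValueError("baseline parameters must be finite")

    @property
    def has_intermediate(self) -> bool:
        return self.yI is not None

    def folded(self, D):
        return self.yF + self.mF * np.asarray(D, dtype=float)

    def unfolded(self, D):
        return self.yU + self.mU * np.asarray(D, dtype=float)

    def intermediate(self, D):
        if not self.has_intermediate:
            raise ValueError("no intermediate baseline present")
        return self.yI + self.mI * np.asarray(D, dtype=float)


@dataclass(frozen=True)
class ThermoTwoState:
    """Two-state LEM parameters in the stability convention.

    ``Cm`` is derived as ``dG0 / m`` and kept consistent by construction.
    """

    dG0: float
    m: float
    T: float = T_DEFAULT
    R: float = field(default=R_KCAL, repr=False)
    Cm: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise ValueError("m value must be positive (stability convention)")
        if not self.T > 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "Cm", self.dG0 / self.m)


@dataclass(frozen=True)
class ThermoThreeState:
    """Three-state LEM parameters.

    ``(dG1, m1)`` governs the transition between the folded state and the
    intermediate (the lower-midpoint transition for a normally ordered
    system) and ``(dG2, m2)`` the transition between the intermediate and
    the unfolded state.  Reporting labels follow midpoint order: the
    higher-[D] transition is U<->I, the lower-[D] one I<->N, matching how
    equilibrium intermediates of beta-barrel folding are usually assigned.
    The total unfolding free energy is a state function, dG1 + dG2,
    regardless of how it is split between the two transitions.
    """

    dG1: float
    m1: float
    dG2: float
    m2: float
    T: float = T_DEFAULT
    R: float = field(default=R_KCAL, repr=False)

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0):
            raise ValueError("m1 and m2 must be positive")
        if not self.T > 0:
            raise ValueError("temperature must be positive")

    @property
    def dG_total(self) -> float:
        return self.dG1 + self.dG2

    @property
    def midpoint1(self) -> float:
        return self.dG1 / self.m1

    @property
    def midpoint2(self) -> float:
        return self.dG2 / self.m2

    # label assignment by midpoint: higher-[D] transition is U<->I
    def _ordered(self) -> tuple[tuple[float, float], tuple[float, float]]:
        lo = (self.dG1, self.m1)
        hi = (self.dG2, self.m2)
        if self.midpoint1 > self.midpoint2:
            lo, hi = hi, lo
        return lo, hi

    @property
    def dG_U_to_I(self) -> float:
        return self._ordered()[1][0]

    @property
    def m_U_to_I(self) -> float:
        return self._ordered()[1][1]

    @property
    def dG_I_to_N(self) -> float:
        return self._ordered()[0][0]

    @property
    def m_I_to_N(self) -> float:
        return self._ordered()[0][1]


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def unfolded_fraction(curve: TitrationCurve, baselines: Baselines) -> np.ndarray:
    """Baseline-corrected unfolded fraction for each titration point.

    f_U = (y_O - B_F(D)) / (B_U(D) - B_F(D)).  Values are *not* clipped to
    [0, 1]: noise legitimately pushes points slightly outside and clipping
    would bias subsequent fits.

    Raises
    ------
    BaselineDegenerate
        If the two baselines come within 1e-12 of each other at any
        measured concentration.
    """
    D = curve.denaturant
    if D.size == 0:
        raise ValueError("empty curve")
    denom = baselines.unfolded(D) - baselines.folded(D)
    if np.any(np.abs(denom) < 1e-12):
        raise BaselineDegenerate(
            "folded and unfolded baselines coincide within the data range"
        )
    return (curve.signal - baselines.folded(D)) / denom


def two_state_fraction(D, params: ThermoTwoState):
    """Unfolded fraction of a two-state system at concentration(s) ``D``.

    Uses the numerically stable logistic form; exact 0.5 at D = Cm and
    strictly increasing in D.
    """
    D = np.asarray(D, dtype=float)
    x = -(params.dG0 - params.m * D) / (params.R * params.T)
    out = expit(x)
    return out if out.ndim else float(out)


def two_state_signal(D, params: ThermoTwoState, baselines: Baselines):
    """Observed signal of a two-state system: baseline-weighted average."""
    f = two_state_fraction(D, params)
    return baselines.folded(D) * (1.0 - f) + baselines.unfolded(D) * f


def state_populations(D, params: ThermoThreeState):
    """Boltzmann populations (f_F, f_I, f_U) of a three-state system.

    Populations are computed with a softmax over log-weights so they sum
    to 1 to machine precision even for extreme free energies.
    """
    D = np.asarray(D, dtype=float)
    rt = params.R * params.T
    w1 = -(params.dG1 - params.m1 * D) / rt          # log K1
    w2 = w1 - (params.dG2 - params.m2 * D) / rt      # log K1*K2
    logw = np.stack([np.zeros_like(w1), w1, w2])
    p = softmax(logw, axis=0)
    if D.ndim == 0:
        return float(p[0]), float(p[1]), float(p[2])
    return p[0], p[1], p[2]


def three_state_signal(D, params: ThermoThreeState, baselines: Baselines):
    """Observed signal of a three-state system.

    y = [B_F + K1*B_I + K1*K2*B_U] / [1 + K1 + K1*K2] with
    K1 = exp(-(dG1 - m1*D)/RT), K2 = exp(-(dG2 - m2*D)/RT).  The printed
    form of such models often carries the baselines on the "fraction"
    side; here the quantity is explicitly the raw signal.
    """
    if not baselines.has_intermediate:
        raise ValueError("three_state_signal requires an intermediate baseline")
    fF, fI, fU = state_populations(D, params)
    return (
        fF * baselines.folded(D)
        + fI * baselines.intermediate(D)
        + fU * baselines.unfolded(D)
    )


def midpoint(dG0: float, m: float) -> float:
    """Denaturation midpoint Cm = dG0 / m (M)."""
    if m == 0:
        raise DegenerateSlope("m value of zero: midpoint undefined")
    return dG0 / m


def total_free_energy(params: ThermoThreeState) -> float:
    """Total unfolding free energy dG1 + dG2 (state function)."""
    return params.dG_total


def reconstruct_signal(
    f_U: Sequence[float], D: Sequence[float], baselines: Baselines
) -> np.ndarray:
    """Inverse of :func:`unfolded_fraction`: signal from fractions and baselines."""
    D = np.asarray(D, dtype=float)
    f = np.asarray(f_U, dtype=float)
    return baselines.folded(D) * (1.0 - f) + baselines.unfolded(D) * f
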