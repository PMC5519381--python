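"""Spectroscopic observables used as structural readouts.

Three families of measurements accompany the titrations:

* intensity-weighted average emission wavelength of tryptophan
  fluorescence spectra, optionally corrected by a quantum-yield ratio
  (Q_R) so that it becomes linear in the unfolded fraction;
* amplitude-weighted average fluorescence lifetime from multi-exponential
  decays;
* circular-dichroism ellipticity converted to mean-residue units and
  normalized across variants to the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateEndpoints,
    DegenerateReference,
    EmptySpectrum,
    InvalidGeometry,
)

__all__ = [
    "EmissionSpectrum",
    "AvgEmission",
    "LifetimeComponents",
    "CDMeasurement",
    "average_emission_wavelength",
    "emission_maximum_intensity",
    "qr_correct",
    "average_lifetime",
    "mean_residue_ellipticity",
    "normalize_theta_to_reference",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Fluorescence emission spectrum (typically 320-400 nm, lex 295 nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    mutant_id: str = ""
    denaturant: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or i.shape != w.shape:
            raise ValueError("wavelengths and intensities must match in shape")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", i)


@dataclass(frozen=True)
class AvgEmission:
    """Average emission wavelength with its Q_R-corrected pseudo-fraction."""

    lam_avg: float
    lam_corrected: float
    Q_R: float


@dataclass(frozen=True)
class LifetimeComponents:
    """Multi-exponential decay components (tau_i in ns, amplitudes alpha_i).

    Amplitudes are normalized to sum to 1 on construction.
    """

    taus: np.ndarray
    amps: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.taus, dtype=float)
        a = np.asarray(self.amps, dtype=float)
        if t.shape != a.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("taus and amps must be 1-d and equal length")
        if np.any(t <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(a < 0) or a.sum() <= 0:
            raise ValueError("amplitudes must be nonnegative with positive sum")
        object.__setattr__(self, "taus", t)
        object.__setattr__(self, "amps", a / a.sum())


@dataclass(frozen=True)
class CDMeasurement:
    """Raw far-UV CD scan with the geometry needed for unit conversion."""

    wavelengths: np.ndarray
    theta_mdeg: np.ndarray
    conc: float          # mg mL^-1
    path: float          # cm
    n_residues: int
    mrw: float | None = None  # mean residue weight, Da

    def __post_init__(self) -> None:
        if self.conc <= 0 or self.path <= 0:
            raise InvalidGeometry("concentration and path length must be positive")
        w = np.asarray(self.wavelengths, dtype=float)
        t = np.asarray(self.theta_mdeg, dtype=float)
        if w.shape != t.shape:
            raise ValueError("wavelengths and theta must match in shape")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "theta_mdeg", t)


def average_emission_wavelength(spec: EmissionSpectrum) -> float:
    """Intensity-weighted mean wavelength, <lam> = sum(I*lam) / sum(I)."""
    total = spec.intensities.sum()
    if total <= 0:
        raise EmptySpectrum("spectrum has no positive intensity")
    return float((spec.intensities * spec.wavelengths).sum() / total)


def emission_maximum_intensity(spec: EmissionSpectrum,
                               reference: EmissionSpectrum | None = None,
                               per_spectrum: bool = False) -> float:
    """Intensity at the emission maximum.

    By default the maximum wavelength of ``reference`` (the folded-state
    spectrum) is located and the intensity of ``spec`` at that fixed
    wavelength is returned, so a whole titration is read at one
    wavelength.  With ``per_spectrum=True`` each spectrum's own maximum
    is used instead.
    """
    if per_spectrum or reference is None:
        return float(spec.intensities.max())
    lam_max = reference.wavelengths[int(np.argmax(reference.intensities))]
    return float(np.interp(lam_max, spec.wavelengths, spec.intensities))


def qr_correct(lam_series, lam_F: float, lam_U: float, Q_R: float = 1.0):
    """Convert average emission wavelengths to unfolded-fraction units.

    With x the linear normalization of <lam> between the folded and
    unfolded endpoints, the corrected value is

        f = x / (x + Q_R * (1 - x))

    where Q_R is the unfolded/folded integrated-intensity (quantum-yield)
    ratio.  For a two-species mixture this undoes the intensity weighting
    of <lam>, making the result equal to the true unfolded fraction;
    Q_R = 1 reduces to the plain linear normalization.
    """
    if lam_F == lam_U:
        raise DegenerateEndpoints("folded and unfolded wavelengths coincide")
    if not Q_R > 0:
        raise ValueError("Q_R must be positive")
    lam = np.asarray(lam_series, dtype=float)
    x = (lam - lam_F) / (lam_U - lam_F)
    out = x / (x + Q_R * (1.0 - x))
    return out if out.ndim else float(out)


def average_lifetime(comp: LifetimeComponents) -> float:
    """Amplitude-weighted average lifetime, <tau> = sum(tau_i * alpha_i) (ns)."""
    return float((comp.taus * comp.amps).sum())


def mean_residue_ellipticity(cd: CDMeasurement) -> np.ndarray:
    """Mean-residue molar ellipticity, deg cm^2 dmol^-1, per wavelength.

    [theta] = theta_mdeg * MRW / (10 * path_cm * conc_mg_per_mL); the mean
    residue weight defaults to 110 Da when not supplied with the scan.
    """
    mrw = cd.mrw if cd.mrw is not None else 110.0
    return cd.theta_mdeg * mrw / (10.0 * cd.path * cd.conc)


def normalize_theta_to_reference(values, reference: float):
    """Divide per-variant ellipticities by the wild-type value."""
    if reference == 0:
        raise DegenerateReference("reference ellipticity is zero")
    out = np.asarray(values, dtype=float) / reference
    return out if out.ndim else float(out)
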