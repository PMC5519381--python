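"""Exception hierarchy.

All package-specific errors derive from :class:`FoldscaleError` so callers can
catch one base class; data-shaped problems additionally derive from
``ValueError`` where that matches user expectations.
"""


class FoldscaleError(Exception):
    """Base class for all foldscale errors."""


# --- model / numerical degeneracies -------------------------------------

class BaselineDegenerate(FoldscaleError, ValueError):
    """Folded and unfolded baselines coincide somewhere on the grid."""


class DegenerateSlope(FoldscaleError, ValueError):
    """m value of zero makes the midpoint undefined."""


# --- fitting ------------------------------------------------------------

class NoTransition(FoldscaleError):
    """No unfolding transition detectable within the data range."""


class FitDidNotConverge(FoldscaleError):
    """Nonlinear least squares failed to converge after multistart."""


class IndistinguishableStates(FoldscaleError):
    """Three-state fit whose intermediate is never appreciably populated."""


class NoOverlap(FoldscaleError, ValueError):
    """Folding and unfolding arms share no denaturant range."""


# --- spectral -----------------------------------------------------------

class EmptySpectrum(FoldscaleError, ValueError):
    """Spectrum with no positive intensity."""


class DegenerateEndpoints(FoldscaleError, ValueError):
    """Folded and unfolded reference wavelengths coincide."""


class InvalidGeometry(FoldscaleError, ValueError):
    """Nonpositive path length or concentration in a CD measurement."""


class DegenerateReference(FoldscaleError, ValueError):
    """Zero reference value in a normalization."""


# --- energetics ---------------------------------------------------------

class MissingReference(FoldscaleError, KeyError):
    """Reference residue absent from the fitted library."""


class SelectorMismatch(FoldscaleError, ValueError):
    """A per-transition free energy was requested from a two-state fit."""


class InsufficientData(FoldscaleError, ValueError):
    """Fewer than three shared points for a regression."""


class DegenerateX(FoldscaleError, ValueError):
    """Zero variance on the regression abscissa."""


class MissingASA(FoldscaleError, KeyError):
    """Residue without a surface-area entry."""


# --- I/O ----------------------------------------------------------------

class FormatError(FoldscaleError, ValueError):
    """Malformed table: missing columns, empty file, unknown labels."""


class ParseError(FoldscaleError, ValueError):
    """Non-numeric cell where a number is required."""


class DuplicatePoint(FoldscaleError, ValueError):
    """Duplicate (mutant, arm, concentration) row in a titration table."""
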