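"""Exception hierarchy shared across the package."""


class KthetaError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(KthetaError, ValueError):
    """Malformed or inconsistent alignment input."""


class NoComparableSitesError(KthetaError, ValueError):
    """A sequence pair shares no site where both residues are unambiguous."""


class SaturationError(KthetaError, ValueError):
    """An observed distance lies outside the correction model's domain."""


class TreeError(KthetaError, ValueError):
    """Invalid tree operation (e.g. non-monophyletic outgroup)."""


class UndecidableError(KthetaError, ValueError):
    """A K/theta comparison cannot be decided (e.g. two singletons, no theta)."""


class SimulationError(KthetaError, ValueError):
    """Invalid coalescent simulation configuration or degenerate outcome."""
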