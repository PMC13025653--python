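"""Exception hierarchy shared across the package."""


class PeptriactError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PeptriactError, ValueError):
    """An argument is outside the mathematically valid domain of a formula."""


class FitError(PeptriactError, ValueError):
    """A least-squares fit cannot be carried out (singular or rank-deficient design)."""


class DesignError(PeptriactError, ValueError):
    """A design table violates the required experimental-design structure."""


class SequenceError(PeptriactError, ValueError):
    """A peptide sequence contains letters outside the 20-residue alphabet."""


class DataError(PeptriactError, ValueError):
    """An input file or record is malformed or missing required fields."""


class ConfigError(PeptriactError, ValueError):
    """A configuration file contains unknown or invalid keys."""
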