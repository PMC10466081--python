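"""Exception hierarchy shared across the package."""


class AmpliscreenError(Exception):
    """Base class for all package errors."""


class AlphabetError(AmpliscreenError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""


class FormatError(AmpliscreenError):
    """An input file is malformed (empty FASTA, bad alphabet, broken table)."""


class EmptyPanelError(AmpliscreenError):
    """No admissible genome remained after loading and level filtering."""


class OfflineError(AmpliscreenError):
    """The download adapter is unavailable; local mode should be used."""


class ValidationError(AmpliscreenError):
    """A parameter fails its contract (identity threshold, primer fields...)."""


class DesignError(AmpliscreenError):
    """A synthetic planted design is infeasible."""
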