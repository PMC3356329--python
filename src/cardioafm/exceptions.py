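"""Exception hierarchy for cardioafm."""


class CardioAFMError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(CardioAFMError, ValueError):
    """Input carries no usable signal (e.g. zero-variance thermal series)."""


class NoContactError(CardioAFMError, ValueError):
    """Approach curve shows no deflection rise; contact point undefined."""


class FitError(CardioAFMError, ValueError):
    """A least-squares fit could not be performed or produced nonsense."""


class UnidentifiableEC50Error(FitError):
    """Dose-response span indistinguishable from noise; EC50 has no meaning."""


class ConfigError(CardioAFMError, ValueError):
    """Invalid or unknown configuration key/value."""


class FileFormatError(CardioAFMError, ValueError):
    """A tabular input file violates the expected dialect."""
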