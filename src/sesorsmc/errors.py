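"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A run configuration is missing entries or violates an invariant."""


class InvalidShiftError(ValueError):
    """A Raman shift is too large for the excitation wavelength."""


class TableLookupError(KeyError):
    """Unknown tissue or wavelength index requested from a property table."""


class AlignmentError(ValueError):
    """Two spectra do not share a wavenumber axis."""
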