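"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class IntegrityError(ValueError):
    """Content is well-formed but violates a structural invariant
    (duplicate sites, inverted region coordinates, ...)."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent or infeasible."""
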