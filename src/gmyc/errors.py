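"""Exception types shared across the package."""


class GMYCError(Exception):
    """Base class for all gmyc errors."""


class TreeValidationError(GMYCError):
    """An input tree violates the ultrametric-tree contract."""


class TreeParseError(GMYCError):
    """A Newick/NEXUS source could not be parsed."""


class DegenerateModelError(GMYCError):
    """A likelihood evaluation was requested for a degenerate configuration."""
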