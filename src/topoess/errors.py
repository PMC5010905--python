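"""Exception hierarchy for topoess.

All library errors derive from :class:`TopoessError` so callers (and the CLI)
can catch one base class. ``UsageError`` signals a caller mistake (bad
parameter); ``ContentError`` signals inconsistent data (leaf-set mismatch,
empty sample); ``TreeParseError`` signals malformed input files.
"""


class TopoessError(Exception):
    """Base class for all topoess errors."""


class UsageError(TopoessError, ValueError):
    """A parameter or call pattern outside the supported contract."""


class ContentError(TopoessError, ValueError):
    """Input data that parses but is internally inconsistent."""


class TreeParseError(TopoessError, ValueError):
    """A tree string or file that could not be parsed."""
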