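"""Exception hierarchy.

All user-facing failures derive from :class:`GhostShiftError` so the CLI can
map them onto exit codes without string matching.
"""


class GhostShiftError(Exception):
    """Base class for all ghostshift errors."""


class TreeError(GhostShiftError):
    """Invalid, unparsable, or non-ultrametric input tree."""


class InputError(GhostShiftError):
    """Missing files, unknown tips, malformed tables or configuration."""


class EmptyBranchSpaceError(GhostShiftError):
    """No donor branch coexists with the acceptor window; simulation impossible."""
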