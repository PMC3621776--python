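"""Exception hierarchy.

``UnclassifiableResidue`` is deliberately separate from ``CollierError`` so
that callers can treat it as a recoverable signal (render the bead in a
default style) rather than a hard failure.
"""


class CollierError(Exception):
    """Base class for hard errors raised by this package."""


class ConfigurationError(CollierError):
    """A packaged or user-supplied configuration table is malformed."""


class NotNumberableError(CollierError):
    """The sequence cannot be assigned IMGT positions by the motif gapper.

    ``anchor`` names the first anchor that could not be placed
    (``1st-CYS``, ``CONSERVED-TRP``, ``2nd-CYS`` or ``J-PHE-or-J-TRP``).
    """

    def __init__(self, message: str, anchor: str | None = None):
        super().__init__(message)
        self.anchor = anchor


class UnclassifiableResidue(Exception):
    """Residue code outside the 20 standard one-letter codes."""

    def __init__(self, residue: str):
        super().__init__(f"unclassifiable residue: {residue!r}")
        self.residue = residue
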