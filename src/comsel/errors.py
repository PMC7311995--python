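"""Exception hierarchy.

All comsel-raised errors derive from :class:`ComselError` so callers (and the
CLI) can distinguish domain errors from programming errors.
"""


class ComselError(Exception):
    """Base class for all comsel errors."""


class InvalidSequenceError(ComselError, ValueError):
    """A sequence contains residues outside {A,C,G,U} (after T->U folding)."""


class InvalidInputError(ComselError, ValueError):
    """Structurally invalid user input (tables, coordinates, flags)."""


class OracleSizeError(ComselError, ValueError):
    """Brute-force enumeration refused: sequences exceed the size guard."""


class PredictionError(ComselError, RuntimeError):
    """An interaction predictor could not serve a required prediction."""


class FixtureError(ComselError, RuntimeError):
    """Synthetic fixture generation failed (e.g. rejection-sampling cap)."""
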