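"""Exception hierarchy for the megastitch pipeline."""


class MegastitchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MegastitchError):
    """A structure or sequence file could not be parsed, or violates the
    target format's constraints on write (e.g. an over-long chain id)."""


class EmptyInputError(MegastitchError):
    """An operation received a structure or sequence with no content."""


class ParameterError(MegastitchError, ValueError):
    """Invalid parameter combination (planner, generator, profiler)."""


class SequenceMismatchError(MegastitchError):
    """Overlapping fragments disagree on residue identity at a shared
    residue number — a symptom of numbering drift between fragments."""


class InsufficientAtomsError(MegastitchError):
    """Too few paired atoms (or residues) for a superposition / axis fit."""


class LookupError_(MegastitchError, KeyError):
    """A requested chain, residue or atom does not exist in the model."""
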