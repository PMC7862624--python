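"""Exception hierarchy for the fscm package.

All package errors derive from :class:`FscmError` so callers (and the CLI)
can distinguish bad inputs (:class:`InputError` subtree) from failures of a
computation (:class:`ComputationError` subtree).
"""


class FscmError(Exception):
    """Base class for all fscm errors."""


class InputError(FscmError):
    """A problem with user-supplied data or parameters."""


class ComputationError(FscmError):
    """A computation could not be carried out on otherwise valid input."""


class FastaParseError(InputError):
    """Malformed FASTA input; message names the offending line or record."""


class SequenceError(InputError):
    """A peptide sequence violates the 20-letter alphabet or length >= 2."""


class SchemaError(InputError):
    """A serialized scorecard or property table violates its schema."""


class ConfigError(InputError):
    """An invalid configuration value (GA, synthetic generator, split)."""


class StratificationError(ComputationError):
    """A label class is too small to stratify a split or fold partition."""


class UnscorableError(ComputationError):
    """A peptide's region slice is too short for the scorecard granularity."""
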