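"""Exception hierarchy shared across the package.

Errors are split by who can fix them: ``ConfigError`` for bad run
configuration, ``SchemaError`` / ``ValidationError`` for malformed input
data, and signal-style exceptions (``NoEffectData``, ``InsufficientData``)
that callers are expected to catch as part of normal control flow.
"""


class MeltriskError(Exception):
    """Base class for all package errors."""


class ConfigError(MeltriskError):
    """Invalid or missing run configuration (exit code 2 in the CLI)."""


class SchemaError(MeltriskError):
    """Input file does not have the required columns."""


class ValidationError(MeltriskError):
    """Input data violates a contract (negative concentration, bad enum...)."""


class UnknownCompoundError(ValidationError):
    """A concentration table references compounds absent from the library."""

    def __init__(self, compound_ids):
        self.compound_ids = sorted(compound_ids)
        super().__init__(
            "compounds not present in library: " + ", ".join(self.compound_ids)
        )


class NoEffectData(MeltriskError):
    """No experimental EC50 records for a compound x BQE; triggers prediction."""


class NoPrediction(MeltriskError):
    """Baseline prediction impossible (log Kow absent); compound excluded."""


class InsufficientData(MeltriskError):
    """Too few observations for an estimate (e.g. < 2 MDL replicates)."""


class UndefinedRemoval(MeltriskError):
    """Removal rate undefined because the influent load is zero."""
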