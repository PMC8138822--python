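"""Exception hierarchy used across the package.

All errors derive from :class:`FibroscreenError` so callers can catch the
package's failures with a single ``except`` clause; the CLI maps them to
exit code 1 with a one-line diagnostic.
"""


class FibroscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(FibroscreenError):
    """A tabular input is missing a required column or has a bad header."""


class IntegrityError(FibroscreenError):
    """A knowledge-base link references an entity that does not exist."""


class SmilesParseError(FibroscreenError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class DimensionError(FibroscreenError):
    """Vector or matrix dimensions are incompatible."""


class InsufficientOverlapError(FibroscreenError):
    """Two profiles share too few gene identifiers to compare."""


class UndefinedCorrelationError(FibroscreenError):
    """A rank vector has zero variance, so correlation is undefined."""


class ConfigurationError(FibroscreenError):
    """An operation was requested with missing or inconsistent configuration."""


class LookupError_(FibroscreenError):
    """An identifier was not found in the knowledge base."""


class AssemblyError(FibroscreenError):
    """A feature matrix could not be assembled (e.g. empty gene overlap)."""


class QCError(FibroscreenError):
    """Sample quality filtering refused to run (e.g. class too small)."""


class StratificationError(FibroscreenError):
    """A train/test split left a class absent from one side."""


class ModalityError(FibroscreenError):
    """Features of one modality were given to a model of the other."""


class MissingFeatureError(FibroscreenError):
    """Candidate features do not cover the model's selected feature IDs."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "candidate features missing required feature IDs: "
            + ", ".join(self.missing[:10])
            + (" ..." if len(self.missing) > 10 else "")
        )
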