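"""Exception hierarchy for the warehouse.

All package errors derive from :class:`GenophenError` so callers can catch
one base class at CLI or pipeline boundaries.
"""


class GenophenError(Exception):
    """Base class for all package errors."""


class StoreError(GenophenError):
    """Schema or constraint problem in the relational store."""


class UpgradeRequiredError(StoreError):
    """The on-disk schema version differs from the library's version."""


class MissingRecordError(StoreError):
    """A record required in `fail` resolution mode does not exist."""


class DuplicateCallError(StoreError):
    """A genotype call with an already-stored key was inserted under the
    `reject` duplicate policy."""


class InvalidFilterError(GenophenError):
    """A matrix filter violates its preconditions."""


class VcfError(GenophenError):
    """Base for VCF validation / import problems."""


class VcfParseError(VcfError):
    """A field could not be parsed (e.g. a non-numeric GT token)."""


class VcfImportError(VcfError):
    """The bulk import aborted; no rows from this import were kept."""


class PhenotypeError(GenophenError):
    """Base for phenotype pipeline problems."""


class PhenotypeLoadError(PhenotypeError):
    """Loading aborted (validation gate, duplicate key, constraint)."""


class TraitDescriptionError(PhenotypeError):
    """A new trait lacks a description, or a locked trait was redefined."""


class MviewRefreshError(GenophenError):
    """A materialized view could not be rebuilt (e.g. a non-numeric value
    inside a quantitative replicate group)."""


class FlankingError(GenophenError):
    """Flanking-sequence annotation failed (no residues, unplaced variant,
    or a non-ACGT allele passed to the IUPAC encoder)."""


class ExportFormatError(GenophenError):
    """An unsupported export format was requested."""
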