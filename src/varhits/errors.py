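"""Exception hierarchy for varhits."""


class VarhitsError(Exception):
    """Base class for all varhits errors."""


class ValidationError(VarhitsError):
    """A value violates a domain invariant (empty allele, bad chromosome, ...)."""


class SchemaError(VarhitsError):
    """The association TSV is missing one or more mandatory columns."""

    def __init__(self, missing_columns):
        self.missing_columns = tuple(missing_columns)
        super().__init__(
            "missing mandatory column(s): " + ", ".join(self.missing_columns)
        )


class MalformedVcfError(VarhitsError):
    """The VCF stream contains neither a header line nor any data line."""


class StoreVersionError(VarhitsError):
    """A compiled store was written by an incompatible format version."""


class StoreIntegrityError(VarhitsError):
    """A compiled store file is truncated or corrupt."""


class SimSpecError(VarhitsError):
    """A simulation specification is internally inconsistent."""
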