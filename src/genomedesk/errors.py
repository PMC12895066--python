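"""Exception hierarchy shared by all genomedesk modules."""


class GenomeDeskError(Exception):
    """Base class for all package errors."""


class StoreError(GenomeDeskError):
    """The store file is invalid, corrupt, or has an unsupported schema."""


class NotFoundError(GenomeDeskError):
    """A referenced entity (genome, gene, operon, ...) does not exist."""


class ValidationError(GenomeDeskError):
    """Input data violates a contract (bad TSV, bad template, bad query)."""


class ParseError(GenomeDeskError):
    """A sequence file could not be parsed."""
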