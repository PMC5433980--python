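"""Exception hierarchy shared across the package."""


class MycoverlapError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(MycoverlapError):
    """A file could not be parsed (bad Newick, non-TSV, wrong header...)."""


class ValidationError(MycoverlapError):
    """Parsed data violate an invariant (duplicate ids, empty host set...)."""


class LookupError_(MycoverlapError):
    """An id was not found where it must resolve (leaf label, plant id)."""


class DomainError(MycoverlapError):
    """An argument is outside its mathematical domain (k out of range...)."""


class ConfigError(MycoverlapError):
    """A synthetic-data configuration is internally inconsistent."""
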