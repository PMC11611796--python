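"""Exception and warning types shared across the package."""


class SdweatError(Exception):
    """Base class for all package-specific errors."""


class BenchmarkParseError(SdweatError):
    """A benchmark file could not be parsed (names the record and field)."""


class BenchmarkValidationError(SdweatError):
    """A benchmark record violates a data-model invariant (names the id)."""


class VectorFormatError(SdweatError):
    """A word-vector file violates its format (names the line)."""


class TermLookupError(SdweatError):
    """Terms could not be resolved against an embedding store."""


class DegenerateTiesWarning(UserWarning):
    """More than 1% of permutation statistics tie the observed statistic."""


class DuplicateTermWarning(UserWarning):
    """A vector file contains repeated terms; the first occurrence wins."""


class UnbalancedTargetsWarning(UserWarning):
    """Target sets have unequal sizes; the exact partition p-value is
    computed over equal halves of the union regardless."""
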