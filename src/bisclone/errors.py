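"""Exception hierarchy shared across the package."""


class BiscloneError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BiscloneError, ValueError):
    """A file does not conform to the expected format."""


class InputError(BiscloneError, ValueError):
    """Input is readable but violates an input contract (empty, duplicates...)."""


class UnalignableReadError(BiscloneError):
    """Neither orientation of a read aligns to the reference above the score floor.

    Not fatal for a run: the pipeline catches this and records the read as
    excluded with reason ``unalignable``.
    """
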