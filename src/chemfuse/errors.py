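"""Exception types shared across the pipeline."""


class ChemfuseError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ChemfuseError):
    """A required option, column role, or parameter is missing or invalid."""


class EmptyDatasetError(ChemfuseError):
    """An input yielded zero usable compound records."""


class AlignmentError(ChemfuseError):
    """Objects that must share a compound order do not."""


class TooFewCompoundsError(ChemfuseError):
    """An operation received fewer compounds than it can handle."""


class StageError(ChemfuseError):
    """A pipeline stage failed; the message names the stage."""
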