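"""Exception hierarchy shared across the package."""


class AtaxmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AtaxmapError):
    """A configuration value is invalid; the message names the field."""


class InputDataError(AtaxmapError):
    """An input file or in-memory table violates its format contract."""


class SampleLookupError(AtaxmapError):
    """A requested sample id is not present in the data."""


class DimensionError(AtaxmapError):
    """Matrix/table shapes are not conformable."""


class PedigreeStructureError(AtaxmapError):
    """The pedigree is not acyclic or parent sexes are inconsistent."""


class ModelError(AtaxmapError):
    """A statistical or transcript model is internally inconsistent."""


class ScoringError(AtaxmapError):
    """A sequence cannot be scored (e.g. ambiguous base)."""
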