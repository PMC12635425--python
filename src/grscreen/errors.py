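"""Exception hierarchy for the screening pipeline.

All pipeline-specific failures derive from :class:`GRScreenError` so callers
can catch one base class at an orchestration boundary (the CLI maps it to a
non-zero exit with the named cause).
"""


class GRScreenError(Exception):
    """Base class for all pipeline errors."""


class RegistryError(GRScreenError):
    """Invalid drug registry (duplicate name, unknown builtin tag, ...)."""


class FormatError(GRScreenError):
    """Malformed input file: missing column, unknown enum token, bad header."""


class ValidationError(GRScreenError):
    """A value violates a domain invariant (negative signal, bad range, ...)."""


class DegenerateControlError(GRScreenError):
    """Negative-control wells are missing or have zero/negative mean signal."""


class MissingDrugError(GRScreenError):
    """A required drug has no wells (or no registry entry) for an organoid."""


class NoGrowthError(GRScreenError):
    """Control did not grow over the assay window: GR is undefined."""


class InsufficientDataError(GRScreenError):
    """Too few concentrations / observations for the requested computation."""
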