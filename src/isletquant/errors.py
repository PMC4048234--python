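"""Exception hierarchy for the islet quantification pipeline."""


class IsletQuantError(Exception):
    """Base class for all package errors."""


class InputError(IsletQuantError):
    """A required input file is missing or unreadable."""


class FormatError(IsletQuantError):
    """An input has the wrong shape, plane count, dtype or value range."""


class EmptyIsletError(IsletQuantError):
    """The islet mask contains no foreground pixels."""


class ParameterError(IsletQuantError):
    """A parameter is outside its documented range."""


class ValidationError(IsletQuantError):
    """A table row violates a closed vocabulary or numeric constraint."""


class GenerationError(IsletQuantError):
    """Synthetic generation is infeasible under the requested parameters."""


class DegenerateDataError(IsletQuantError):
    """A statistic is undefined on this input (constant data, zero variance)."""
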