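"""Exception hierarchy shared across the package."""


class PulloopError(Exception):
    """Base class for all pulloop errors."""


class GFFParseError(PulloopError):
    """A GFF3 line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"GFF3 parse error at line {line_number}: {message}")


class AnnotationValidationError(PulloopError):
    """Annotation tables violated an invariant (e.g. duplicate locus_tag)."""


class CurationError(PulloopError):
    """A curation override referenced an unknown PUL; offenders listed."""

    def __init__(self, unknown_ids):
        self.unknown_ids = sorted(unknown_ids)
        super().__init__(
            "curation overrides reference unknown PUL ids: "
            + ", ".join(self.unknown_ids)
        )


class ParameterError(PulloopError):
    """A numeric parameter is outside its documented range."""


class QuantError(PulloopError):
    """A quantification input is degenerate (zero totals, missing signal)."""
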