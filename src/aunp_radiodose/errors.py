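"""Exception types shared across the package."""


class SingularResonanceError(ValueError):
    """Quasi-static polarizability denominator eps_p + 2*eps_m vanished.

    Raised instead of returning an infinite polarizability at the
    Froehlich resonance of a lossless sphere.
    """


class GeometryError(ValueError):
    """Invalid spatial configuration (overlapping particles, interior point)."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
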