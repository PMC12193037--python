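"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A circuit or parameter file is incomplete or inconsistent."""


class DegenerateGeometryError(ValueError):
    """Body geometry produced a zero-length muscle spring."""


class IntegrationBlowUpError(RuntimeError):
    """The coupled integration produced a non-finite state variable."""

    def __init__(self, variable: str, time: float):
        self.variable = variable
        self.time = time
        super().__init__(
            f"non-finite value in state variable {variable!r} at t = {time:.6g} s"
        )
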