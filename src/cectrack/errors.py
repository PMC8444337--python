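"""Exception hierarchy shared across the package."""


class CectrackError(Exception):
    """Base class for all package-specific errors."""


class TrajectoryParseError(CectrackError):
    """A trajectory or structure file violates its format contract."""

    def __init__(self, message: str, frame: int | None = None, line: int | None = None):
        loc = []
        if frame is not None:
            loc.append(f"frame {frame}")
        if line is not None:
            loc.append(f"line {line}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.frame = frame
        self.line = line


class TopologyError(CectrackError):
    """The frame's bonding topology is outside the supported inputs."""


class GeometryError(CectrackError):
    """A geometric quantity is undefined (coincident atoms, clashes, ...)."""


class ConfigurationError(CectrackError):
    """Missing or inconsistent parameters, charge tables, or config files."""
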