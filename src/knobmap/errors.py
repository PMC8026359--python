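"""Exception hierarchy for knobmap.

All package-raised errors derive from :class:`KnobmapError` so callers can
catch one base class; the subclasses distinguish bad configuration, degenerate
geometry, malformed input data, and analyses that are undefined on the given
data (e.g. a constant column fed to a correlation).
"""


class KnobmapError(Exception):
    """Base class for all knobmap errors."""


class ConfigError(KnobmapError):
    """Invalid generator or pipeline configuration."""


class GeometryError(KnobmapError):
    """Degenerate curve/grid geometry (zero length, undefined normal, ...)."""


class InputError(KnobmapError):
    """Malformed or insufficient input data (short traces, bad indices)."""


class AnalysisError(KnobmapError):
    """Analysis undefined on the given data (all sites flagged, zero variance)."""
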