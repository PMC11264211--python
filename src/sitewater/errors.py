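"""Exception types shared across the package."""


class SitewaterError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SitewaterError, ValueError):
    """A file does not conform to the declared format."""


class ConsistencyError(SitewaterError, ValueError):
    """Trajectory and topology disagree (e.g. atom-count mismatch)."""


class SelectionError(SitewaterError, ValueError):
    """An atom-selection expression is malformed."""


class SiteSpecError(SitewaterError, ValueError):
    """A site-role selector does not resolve as its role requires."""


class ConfigError(SitewaterError, ValueError):
    """A synthetic-data configuration violates its invariants."""


class DegenerateGeometryError(SitewaterError, ValueError):
    """Geometry too degenerate to define the requested quantity."""
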