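"""Exception hierarchy for orgmapkit."""


class OrgMapError(Exception):
    """Base class for all orgmapkit errors."""


class ConfigurationError(OrgMapError):
    """A design/config problem, e.g. a mapped column missing from the input."""


class InputDataError(OrgMapError):
    """Malformed input data (unparsable cells, duplicate ids, conflicts)."""


class SchemaVersionError(OrgMapError):
    """A session archive written by an incompatible schema version."""


class AnalysisError(OrgMapError):
    """An analysis step cannot proceed (singular scatter, too few inputs...)."""
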