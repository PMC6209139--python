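"""Exception hierarchy for the posture-morphometrics toolkit."""


class PostureGMError(Exception):
    """Base class for all toolkit errors."""


class TPSParseError(PostureGMError):
    """Malformed TPS landmark file (bad count, non-numeric coordinate...)."""


class SchemeValidationError(PostureGMError):
    """Point scheme violates its structural invariants."""


class MetadataError(PostureGMError):
    """Covariate table fails validation (vocabulary, duplicates, types)."""


class DegenerateConfigurationError(PostureGMError):
    """A landmark configuration is geometrically degenerate
    (coincident points, zero-length ray, singular TPS system)."""


class ConvergenceWarning(UserWarning):
    """An iterative procedure stopped at max_iter without meeting tol."""
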