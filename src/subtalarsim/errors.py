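"""Exception hierarchy for the subtalar simulation pipeline."""


class SubtalarError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SubtalarError, ValueError):
    """A synthetic specimen specification violates its invariants."""


class DegenerateInputError(SubtalarError, ValueError):
    """Input admits no well-posed solution (coplanar points, coincident centers...)."""


class GeometryError(SubtalarError, RuntimeError):
    """A geometric construction failed (axis misses a bone, non-watertight mesh...)."""


class ConfigError(SubtalarError, ValueError):
    """Run configuration is inconsistent; maps to CLI exit code 2."""


class DataError(SubtalarError, RuntimeError):
    """Input data files are missing or malformed; maps to CLI exit code 3."""
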