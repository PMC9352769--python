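"""Exception types used across the pipeline."""


class MatissError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(MatissError, ValueError):
    """A parameter violates its contract (negative density, coarse pixels...)."""


class FormatError(MatissError, ValueError):
    """Malformed or inconsistent input data (stacks, sidecars, tables)."""


class InputError(MatissError, ValueError):
    """A computation was asked to run on inputs it cannot use (empty stack...)."""


class AllFramesRejectedError(MatissError, RuntimeError):
    """Shadow-frame rejection removed every frame of a stack."""


class UnknownCampaignError(MatissError, KeyError):
    """Requested campaign/timepoint pair has no packaged reference config."""
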