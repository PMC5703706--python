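"""Exception hierarchy for lagflow."""


class LagflowError(Exception):
    """Base class for all lagflow errors."""


class ParameterError(LagflowError, ValueError):
    """A parameter violates a stated bound (e.g. band edge beyond Nyquist)."""


class PipelineOrderError(LagflowError, RuntimeError):
    """A preprocessing stage was called out of its fixed order."""


class GenerationError(LagflowError, RuntimeError):
    """Phantom synthesis cannot honour the requested ground truth."""


class DesignError(LagflowError, ValueError):
    """A cohort design table is inconsistent with the requested analysis."""
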