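"""Exception hierarchy. All user-facing errors derive from PorefluxError."""


class PorefluxError(Exception):
    """Base class for all errors raised by poreflux."""


class CycleError(PorefluxError):
    """Invalid permeation-cycle definition (topology, duplicate transitions, ...)."""


class SchemaError(PorefluxError):
    """Malformed cycle/config file; message names the offending field."""


class SimulationError(PorefluxError):
    """Stochastic simulation cannot proceed (absorbing state, bad duration, ...)."""


class EstimationError(PorefluxError):
    """Rate estimation or fitting failure (no data, corrupt counts, ...)."""


class AnalysisError(PorefluxError):
    """i-V analysis failure (bad curve, missing configuration, ...)."""
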