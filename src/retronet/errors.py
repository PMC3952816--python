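"""Exception hierarchy for retronet."""


class RetronetError(Exception):
    """Base class for all retronet errors."""


class ValidationError(RetronetError):
    """A model file or specification violates the schema."""


class ReferenceError_(RetronetError):
    """A parent or wiring reference does not resolve."""


class ConsistencyError(RetronetError):
    """Binding type and parent list disagree, or production rates are illegal."""


class ConfigurationError(RetronetError):
    """A simulation is missing a required signal or setting."""


class ConditioningError(RetronetError):
    """A retroactivity premultiplier is numerically singular."""


class SolverError(RetronetError):
    """ODE integration or root finding failed."""


class AnalysisError(RetronetError):
    """A trajectory does not support the requested analysis."""


class AssumptionError(RetronetError):
    """A structural assumption required by the requested quantity fails."""


class ContractError(RetronetError):
    """Inputs violate an operation's contract."""


class DomainError(RetronetError):
    """Numeric input outside the physical domain (e.g. negative concentration)."""
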