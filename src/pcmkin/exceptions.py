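"""Exception hierarchy for pcmkin."""


class PcmkinError(Exception):
    """Base class for all pcmkin errors."""


class SchemaError(PcmkinError):
    """A tabular input or manifest does not conform to the documented schema."""


class UnitError(PcmkinError):
    """An unknown or inconsistent unit tag was encountered."""


class ValidationError(PcmkinError):
    """A domain-type invariant was violated."""


class KineticsDomainError(PcmkinError, ValueError):
    """An operation was called outside its mathematical domain
    (zero divisor, exhausted reagent, ...)."""


class FitError(PcmkinError):
    """A regression could not be carried out or produced an inconsistent model."""


class IntegrationError(PcmkinError):
    """The ODE integrator failed; the message carries solver diagnostics."""


class SpeciesDecisionError(PcmkinError):
    """The diagnostic flags supplied to the speciation logic are contradictory."""


class NoReactionError(KineticsDomainError):
    """A stoichiometric determination found no oxidant consumed."""


class ReportError(PcmkinError):
    """An analysis report is empty or cannot be written."""
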