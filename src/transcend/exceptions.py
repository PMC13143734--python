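"""Exception hierarchy for model validation and inference failures."""


class TranscendError(Exception):
    """Base class for all package errors."""


class ModelValidationError(TranscendError, ValueError):
    """A generative-model component violates its invariants.

    The message always names the offending field.
    """


class DegenerateDistributionError(ModelValidationError):
    """A vector that must normalize to a proper distribution cannot."""


class ImpossibleObservationError(TranscendError, ValueError):
    """An observation has zero marginal likelihood under the current prior."""


class ScenarioError(TranscendError, KeyError):
    """Unknown scripted scenario name."""
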