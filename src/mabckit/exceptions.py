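"""Exception hierarchy shared across the toolkit."""


class MabcError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MabcError):
    """A delimited input file is malformed (e.g. a required column is missing)."""


class PanelValidationError(MabcError):
    """A marker panel violates its invariants (duplicate names, bad coordinates)."""


class ConfigurationError(MabcError):
    """A selection configuration refers to markers or settings that do not exist."""


class IntegrityError(MabcError):
    """An in-memory genome object violates its tiling invariants."""


class CampaignHalt(MabcError):
    """A selection campaign stopped because a generation had zero survivors.

    Carries the generation number and the stage (foreground / recombinant /
    background) at which the population emptied.
    """

    def __init__(self, generation: int, stage: str, message: str | None = None):
        self.generation = generation
        self.stage = stage
        super().__init__(
            message
            or f"campaign halted: zero {stage} survivors in backcross generation {generation}"
        )
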