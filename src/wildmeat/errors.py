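"""Exception hierarchy for the wildmeat pipeline."""


class WildmeatError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WildmeatError):
    """Invalid configuration value or file; message lists every violation."""


class AlignmentError(WildmeatError):
    """Grids that must share a lattice do not."""


class ReclassificationError(WildmeatError):
    """Raw taxon labels that do not resolve through the mapping table."""


class EffortError(WildmeatError):
    """Missing or degenerate hunting-effort information."""


class UndefinedTSOPError(WildmeatError):
    """Offtake proportions requested for a locality with zero total harvest."""


class PlacementError(WildmeatError):
    """Synthetic localities cannot be placed on eligible cells."""


class ExtractionError(WildmeatError):
    """A locality falls on a masked cell during feature extraction."""


class EpochLookupError(WildmeatError):
    """Unknown variable tag in an epoch table."""


class TraitError(WildmeatError):
    """A required taxon trait (body mass, density) is missing."""


class DRITableError(WildmeatError):
    """A (group, nutrient) requirement entry is missing from the DRI table."""


class StageError(WildmeatError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
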