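"""Exception hierarchy for the crequant pipeline."""


class CrequantError(Exception):
    """Base class for all crequant-specific errors."""


class AtlasSpecError(CrequantError, ValueError):
    """Invalid toy-atlas specification (non-positive dims or counts)."""


class OntologyError(CrequantError, ValueError):
    """Structurally invalid ontology (duplicate ids, cycles, no root...)."""


class PartitionViolationError(CrequantError, ValueError):
    """A leaf has zero or more than one mid-level ancestor-or-self."""


class InvalidAssignmentError(CrequantError, ValueError):
    """Unknown pattern category or structure id in a ground-truth assignment."""


class InfeasiblePairError(CrequantError, ValueError):
    """A faithfulness category cannot be realized for the given ground truth."""


class NoTissueError(CrequantError, ValueError):
    """A section image contains no in-tissue pixels."""


class RegistrationError(CrequantError, ValueError):
    """Mask and image are not co-registered (shape mismatch)."""


class GridSpecError(CrequantError, ValueError):
    """Grid size is not a positive multiple of the pixel size."""


class EmptySeriesError(CrequantError, ValueError):
    """No grid in the series could be assigned to any structure."""


class UndefinedCorrelationError(CrequantError, ValueError):
    """Spearman rho undefined: fewer than 3 complete pairs or zero rank variance."""


class IncomparableDatasetsError(CrequantError, ValueError):
    """No plane-matched replicate pair exists between two datasets."""


class ConfigError(CrequantError, ValueError):
    """Invalid run configuration."""
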