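"""Exception hierarchy for plantfusion."""


class PlantFusionError(Exception):
    """Base class for all plantfusion errors."""


class ManifestError(PlantFusionError):
    """A dataset manifest is malformed or violates structural invariants."""


class IntegrityError(PlantFusionError):
    """Cross-referenced artifacts are inconsistent (missing rows, mismatched
    species orderings, duplicate keys)."""


class SplitSizeError(PlantFusionError):
    """A requested split or training-set reduction cannot be satisfied by the
    available observations."""


class TrainingError(PlantFusionError):
    """A scorer cannot be fitted (empty training set, missing species)."""


class InputError(PlantFusionError):
    """An operation received a degenerate or out-of-contract input."""
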