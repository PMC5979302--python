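"""Shared state vocabularies used across the pipeline stages.

String-valued enums so that flags survive JSON/TSV round-trips unchanged.
"""

from enum import Enum


class _StrEnum(str, Enum):
    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FaFlag(_StrEnum):
    """Per-amplicon fragment-analysis ratio flag (one per normalization)."""

    IN_RANGE = "IN_RANGE"
    LOW = "LOW"
    HIGH = "HIGH"
    MISSING = "MISSING"


class RcFlag(_StrEnum):
    """Per-amplicon read-count frequency flag against the run CI99%."""

    IN_CI = "IN_CI"
    LOW = "LOW"
    HIGH = "HIGH"
    MISSING = "MISSING"


class CallState(_StrEnum):
    """Integrated per-amplicon copy-number call."""

    LOSS = "LOSS"
    NEUTRAL = "NEUTRAL"
    GAIN = "GAIN"
    NO_CALL = "NO_CALL"


class GeneState(_StrEnum):
    """Gene-level copy-number state."""

    WHOLE_LOSS = "WHOLE_LOSS"
    WHOLE_GAIN = "WHOLE_GAIN"
    PARTIAL_LOSS = "PARTIAL_LOSS"
    PARTIAL_GAIN = "PARTIAL_GAIN"
    NEUTRAL = "NEUTRAL"


class DosageClass(_StrEnum):
    """Dosage-quotient classification against the normal range."""

    DELETED = "DELETED"
    NORMAL = "NORMAL"
    DUPLICATED = "DUPLICATED"
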