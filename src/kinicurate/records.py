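"""Domain types shared across the curation pipeline.

The pipeline moves activity records through four shapes: the raw
:class:`ActivityRecord` parsed from one of the two source dialects, a
qualification outcome attached by :mod:`kinicurate.ingest`, the merged
compound identity from :mod:`kinicurate.standardize`, and the final
per-pair :class:`~kinicurate.aggregate.PairAnnotation`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Source(enum.Enum):
    """Which export dialect a record was parsed from."""

    CHEMBL_DIALECT = "chembl"
    BINDINGDB_DIALECT = "bindingdb"


class Organism(enum.Enum):
    HUMAN = "Homo sapiens"
    MOUSE = "Mus musculus"


class MeasurementType(enum.Enum):
    """Standard activity measurement types.

    Only IC50, Ki and Kd ever qualify.  ``OTHER`` marks records parsed with
    a non-qualifying type (EC50, %inhibition, ...) so they can be counted as
    discards rather than dropped silently at parse time.
    """

    IC50 = "IC50"
    KI = "KI"
    KD = "KD"
    OTHER = "OTHER"


#: measurement types allowed through qualification
QUALIFYING_TYPES = frozenset({MeasurementType.IC50, MeasurementType.KI, MeasurementType.KD})


class Relation(enum.Enum):
    EQ = "="
    GT = ">"
    GTGT = ">>"
    LT = "<"
    OTHER = "~"


@dataclass
class ActivityRecord:
    """One raw measurement of one compound against one kinase."""

    record_id: str
    source: Source
    compound_smiles: str
    kinase_uniprot: str
    organism: Organism | None
    measurement_type: MeasurementType
    relation: Relation
    value_nM: float | None
    units: str | None = None
    target_category: str | None = None
    confidence_score: int | None = None
    activity_comment: str | None = None
    activity_label: str | None = None  # "active" | "inactive" | None
    n_chains: int | None = None
    raw_type: str | None = None

    def __post_init__(self) -> None:
        if self.value_nM is not None:
            if not math.isfinite(self.value_nM) or self.value_nM <= 0:
                # invariant: value, when present, is strictly positive and finite
                self.value_nM = None


@dataclass
class QualificationReport:
    """Bookkeeping for one qualification pass: every row lands exactly once."""

    n_read: int = 0
    n_qualified: int = 0
    discard_counts: dict[str, int] = field(default_factory=dict)

    def discard(self, reason: str) -> None:
        self.discard_counts[reason] = self.discard_counts.get(reason, 0) + 1

    @property
    def n_discarded(self) -> int:
        return sum(self.discard_counts.values())

    def balances(self) -> bool:
        return self.n_read == self.n_qualified + self.n_discarded

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_qualified": self.n_qualified,
            "discard_counts": dict(sorted(self.discard_counts.items())),
        }
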