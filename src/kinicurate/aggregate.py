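"""Per-pair potency aggregation, consistency filtering and classification.

All qualified measurements for one (compound, kinase) pair are collapsed
into a single :class:`PairAnnotation` by the following rules:

1. point measurements (relation "=") are log-transformed
   (``mean_log = 9 − log10(value in nM)``, the negative decadic logarithm of
   the molar potency) and grouped by measurement type, pooling both sources;
2. within a type, the final value is the arithmetic mean of the logs; the
   type's aggregate is invalid when the sample standard deviation of the
   logs exceeds 1 log unit (n = 1 groups are exempt);
3. among valid aggregates, the assay-independent constants take priority
   over IC50, in the fixed order Kd > Ki > IC50;
4. the pair is ACTIVE when the selected mean log potency is ≥ 5.0
   (≤ 10,000 nM), otherwise INACTIVE;
5. a quantitatively ACTIVE pair that also carries any censored ">"/">>"
   record is contradictory and the whole pair is discarded; an EQ-inactive
   aggregate together with censored records is *not* a conflict (both agree
   on inactivity);
6. a pair with only censored records is INACTIVE with no mean log value
   (a qualitative annotation).

A pair whose every type aggregate fails the standard-deviation gate is
dropped entirely (DISCARDED_SD) rather than demoted to qualitative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Sequence

from .records import ActivityRecord, MeasurementType, Organism, Relation

#: classification threshold on the log scale: 10,000 nM == 1e-5 M == 5.0
ACTIVITY_THRESHOLD_LOG = 5.0

#: selection priority of valid per-type aggregates (first wins)
TYPE_PRIORITY: tuple[MeasurementType, ...] = (
    MeasurementType.KD,
    MeasurementType.KI,
    MeasurementType.IC50,
)

SD_LIMIT = 1.0  # log units

QUALITATIVE = "QUALITATIVE"


class PairStatus(enum.Enum):
    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"
    DISCARDED_SD = "DISCARDED_SD"
    DISCARDED_CONFLICT = "DISCARDED_CONFLICT"


@dataclass(frozen=True)
class Measurement:
    """One qualified measurement, reduced to the fields aggregation needs."""

    measurement_type: MeasurementType
    relation: Relation
    value_nM: float | None
    record_id: str = ""

    @classmethod
    def from_record(cls, r: ActivityRecord) -> "Measurement":
        return cls(r.measurement_type, r.relation, r.value_nM, r.record_id)


@dataclass
class PairAnnotation:
    """Final annotation for one (compound, kinase) pair."""

    compound_key: str
    kinase_uniprot: str
    organism: Organism
    selected_type: str  # "KD" | "KI" | "IC50" | "QUALITATIVE"
    mean_log: float | None
    status: PairStatus
    activity_ids: list[str] = field(default_factory=list)
    compound_new_id: int | None = None

    @property
    def selected_stvalue(self) -> str:
        return self.selected_type


def to_log(value_nM: float) -> float:
    """Negative decadic logarithm of the molar potency for a value in nM."""
    if not (value_nM > 0):
        raise ValueError(f"potency value must be positive, got {value_nM!r}")
    return 9.0 - math.log10(value_nM)


def aggregate_measurements(
    measurements: Sequence[Measurement],
) -> tuple[str, float | None, PairStatus]:
    """Apply aggregation rules (1)-(6) to one pair's measurement set.

    Returns ``(selected_type, mean_log, status)``; ``mean_log`` is ``None``
    exactly when no point measurement contributed (qualitative pairs and
    discards).
    """
    if not measurements:
        raise ValueError("aggregate_measurements requires a non-empty measurement set")

    eq = [m for m in measurements if m.relation is Relation.EQ]
    censored = [m for m in measurements if m.relation in (Relation.GT, Relation.GTGT)]
    if len(eq) + len(censored) != len(measurements):
        raise ValueError("only qualified (EQ/GT/GTGT) measurements may be aggregated")

    if not eq:
        # rule 6: censored-only pair is a qualitative inactive
        return QUALITATIVE, None, PairStatus.INACTIVE

    by_type: dict[MeasurementType, list[float]] = {}
    for m in eq:
        by_type.setdefault(m.measurement_type, []).append(to_log(m.value_nM))

    valid: dict[MeasurementType, float] = {}
    for mtype, logs in by_type.items():
        if len(logs) > 1 and stdev(logs) > SD_LIMIT:
            continue  # rule 2: inconsistent replicate set
        valid[mtype] = mean(logs)

    if not valid:
        return QUALITATIVE, None, PairStatus.DISCARDED_SD

    selected = next(t for t in TYPE_PRIORITY if t in valid)
    mean_log = valid[selected]
    status = PairStatus.ACTIVE if mean_log >= ACTIVITY_THRESHOLD_LOG else PairStatus.INACTIVE

    if status is PairStatus.ACTIVE and censored:
        return selected.value, mean_log, PairStatus.DISCARDED_CONFLICT

    return selected.value, mean_log, status


def aggregate_pair(
    compound_key: str,
    kinase_uniprot: str,
    organism: Organism,
    records: Sequence[ActivityRecord],
) -> PairAnnotation:
    """Aggregate all qualified records of one pair into its annotation."""
    measurements = [Measurement.from_record(r) for r in records]
    selected_type, mean_log, status = aggregate_measurements(measurements)
    ids = sorted({r.record_id for r in records})
    return PairAnnotation(
        compound_key=compound_key,
        kinase_uniprot=kinase_uniprot,
        organism=organism,
        selected_type=selected_type,
        mean_log=mean_log,
        status=status,
        activity_ids=ids,
    )


def aggregate_all(
    records: Iterable[ActivityRecord],
    key_of: dict[str, str],
) -> list[PairAnnotation]:
    """Group qualified records by (compound key, kinase) and aggregate each.

    ``key_of`` maps source SMILES to the standardized compound key.  Output
    order is deterministic (sorted by compound key, then kinase).
    """
    groups: dict[tuple[str, str], list[ActivityRecord]] = {}
    for r in records:
        key = key_of[r.compound_smiles]
        groups.setdefault((key, r.kinase_uniprot), []).append(r)
    annotations = []
    for (key, uniprot) in sorted(groups):
        recs = groups[(key, uniprot)]
        organisms = {r.organism for r in recs}
        if len(organisms) != 1:  # kinase table guarantees one organism per accession
            raise ValueError(f"conflicting organisms for kinase {uniprot}")
        annotations.append(aggregate_pair(key, uniprot, recs[0].organism, recs))
    return annotations


def split_datasets(
    annotations: Iterable[PairAnnotation],
) -> dict[tuple[Organism, PairStatus], list[PairAnnotation]]:
    """Partition classified pairs into the four exported data sets.

    Discarded pairs are excluded; a compound may legitimately appear in both
    an active and an inactive set through different kinases.
    """
    sets: dict[tuple[Organism, PairStatus], list[PairAnnotation]] = {
        (org, st): []
        for org in Organism
        for st in (PairStatus.ACTIVE, PairStatus.INACTIVE)
    }
    for ann in annotations:
        if ann.status in (PairStatus.ACTIVE, PairStatus.INACTIVE):
            sets[(ann.organism, ann.status)].append(ann)
    return sets
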