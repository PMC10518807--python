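"""Deposition-schema export and summary statistics.

The curated pairs are written as four TSV files (human/mouse × active/
inactive) with fixed, verbatim column names; the human active file
additionally carries the CPKI covalent-inhibitor flag.  ``summarize``
computes the per-organism statistics reported alongside the deposition:
compound/interaction/kinase counts, the log-potency distribution of active
pairs, analogue-series and core counts, and the warhead histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aggregate import PairAnnotation, PairStatus
from .analog_series import AnalogSeries, Singleton
from .records import Organism
from .warheads import WarheadScan

DEPOSITION_COLUMNS = [
    "Compound_new_ID",
    "nonstereo_aromatic_smile",
    "Uniprot_ID",
    "pref_name",
    "activity_id",
    "mean_log",
    "selected_stvalue",
    "ORGANISM",
]

DATASET_FILES = {
    (Organism.HUMAN, PairStatus.ACTIVE): "human_PKI_active.tsv",
    (Organism.HUMAN, PairStatus.INACTIVE): "human_PKI_inactive.tsv",
    (Organism.MOUSE, PairStatus.ACTIVE): "mouse_PKI_active.tsv",
    (Organism.MOUSE, PairStatus.INACTIVE): "mouse_PKI_inactive.tsv",
}

_README_TEMPLATE = """\
Curated protein kinase inhibitor data sets
==========================================

Files:
  human_PKI_active.tsv    active human PKI-kinase pairs (with CPKI flag)
  human_PKI_inactive.tsv  human pairs classified as inactive (>10,000 nM)
  mouse_PKI_active.tsv    active mouse PKI-kinase pairs
  mouse_PKI_inactive.tsv  mouse pairs classified as inactive

Columns:
  Compound_new_ID          internal ID assigned to each compound
  nonstereo_aromatic_smile standardized compound SMILES
  Uniprot_ID               UniProtKB/Swiss-Prot kinase ID
  pref_name                preferred/full name of the kinase
  activity_id              reference to the source activity records
  mean_log                 mean negative logarithmic potency value
                           (NaN: qualitative measurement)
  selected_stvalue         standard value type used (KD/KI/IC50/QUALITATIVE)
  ORGANISM                 organism of the kinase
  CPKI                     True if the compound contains a covalent warhead
                           (human active file only)
"""


@dataclass
class DistributionSummary:
    """Five-number summary of a log-potency distribution with Tukey fences."""

    n: int
    min: float
    q1: float
    median: float
    q3: float
    max: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)

    @classmethod
    def from_values(cls, values: list[float]) -> "DistributionSummary | None":
        if not values:
            return None
        arr = np.asarray(sorted(values), dtype=float)
        q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # type-7 interpolation
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
        return cls(
            n=len(arr),
            min=float(arr.min()),
            q1=float(q1),
            median=float(med),
            q3=float(q3),
            max=float(arr.max()),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            outliers=[float(x) for x in outliers],
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "min": self.min,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.max,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "n_outliers": len(self.outliers),
        }


def _format_mean_log(value: float | None) -> str:
    return "NaN" if value is None else repr(float(value))


def deposition_rows(
    annotations: list[PairAnnotation],
    id_of_key: dict[str, int],
    kinase_table: dict[str, dict],
    cpki_flags: dict[str, bool] | None = None,
) -> list[dict]:
    """Render annotations as deposition rows, sorted by compound then kinase."""
    rows = []
    for ann in annotations:
        row = {
            "Compound_new_ID": id_of_key[ann.compound_key],
            "nonstereo_aromatic_smile": ann.compound_key,
            "Uniprot_ID": ann.kinase_uniprot,
            "pref_name": kinase_table.get(ann.kinase_uniprot, {}).get("pref_name", ""),
            "activity_id": ";".join(sorted(ann.activity_ids)),
            "mean_log": _format_mean_log(ann.mean_log),
            "selected_stvalue": ann.selected_stvalue,
            "ORGANISM": ann.organism.value,
        }
        if cpki_flags is not None:
            row["CPKI"] = str(cpki_flags.get(ann.compound_key, False))
        rows.append(row)
    rows.sort(key=lambda r: (r["Compound_new_ID"], r["Uniprot_ID"]))
    return rows


def write_datasets(
    datasets: dict[tuple[Organism, PairStatus], list[PairAnnotation]],
    id_of_key: dict[str, int],
    kinase_table: dict[str, dict],
    cpki_flags: dict[str, bool],
    out_dir: Path,
) -> dict[str, Path]:
    """Write the four deposition TSV files plus readme.txt.

    Output is deterministic: stable row order, fixed column order, "NaN"
    for qualitative rows; the CPKI column appears only in the human active
    file.  Reading a written file back and rewriting it is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for (org, status), fname in DATASET_FILES.items():
        with_cpki = org is Organism.HUMAN and status is PairStatus.ACTIVE
        columns = DEPOSITION_COLUMNS + (["CPKI"] if with_cpki else [])
        rows = deposition_rows(
            datasets.get((org, status), []),
            id_of_key,
            kinase_table,
            cpki_flags if with_cpki else None,
        )
        path = out_dir / fname
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in columns) + "\n")
        written[fname] = path
    readme = out_dir / "readme.txt"
    readme.write_text(_README_TEMPLATE, encoding="utf-8")
    written["readme.txt"] = readme
    return written


def summarize(
    annotations: list[PairAnnotation],
    series_by_org: dict[Organism, tuple[list[AnalogSeries], list[Singleton]]]
    | None = None,
    scans_by_org: dict[Organism, WarheadScan] | None = None,
) -> dict:
    """Summary statistics over the curated corpus, per organism.

    Analogue-series results and warhead scans are optional and reported
    under the organism whose active compound set they were computed on.
    """
    report: dict = {"organisms": {}}
    for org in Organism:
        anns = [a for a in annotations if a.organism is org]
        active = [a for a in anns if a.status is PairStatus.ACTIVE]
        inactive = [a for a in anns if a.status is PairStatus.INACTIVE]
        dist = DistributionSummary.from_values(
            [a.mean_log for a in active if a.mean_log is not None]
        )
        block: dict = {
            "active_compounds": len({a.compound_key for a in active}),
            "inactive_compounds": len({a.compound_key for a in inactive}),
            "interactions": len(active) + len(inactive),
            "active_kinases": len({a.kinase_uniprot for a in active}),
            "inactive_kinases": len({a.kinase_uniprot for a in inactive}),
            "discarded_sd_pairs": sum(
                1 for a in anns if a.status is PairStatus.DISCARDED_SD
            ),
            "discarded_conflict_pairs": sum(
                1 for a in anns if a.status is PairStatus.DISCARDED_CONFLICT
            ),
            "potency_distribution": dist.to_dict() if dist else None,
        }
        if series_by_org and org in series_by_org:
            series, singletons = series_by_org[org]
            block["analog_series"] = {
                "n_series": len(series),
                "n_singletons": len(singletons),
                "n_distinct_cores": len(
                    {s.core.capped_smiles for s in series}
                    | {s.core.capped_smiles for s in singletons}
                ),
            }
        if scans_by_org and org in scans_by_org:
            scan = scans_by_org[org]
            block["covalent"] = {
                "n_cpki": sum(1 for v in scan.cpki_flags.values() if v),
                "histogram": dict(sorted(scan.histogram.items())),
            }
        report["organisms"][org.name] = block
    return report


def write_report(report: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
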