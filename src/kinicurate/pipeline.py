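"""End-to-end orchestration: ingest → standardize → aggregate → analogue
series → warheads → export.

``run_pipeline`` is the programmatic equivalent of ``kinicurate run``.  The
analogue-series extraction and the warhead scan follow the deposition
convention: series are extracted per organism from the compounds with at
least one active pair, and the covalent scan is applied to the human
active set (extendable to all sets with ``scan_all_organisms``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import aggregate as agg
from . import analog_series as aser
from . import export_stats, ingest, warheads
from .records import ActivityRecord, Organism, QualificationReport
from .standardize import StandardizationFailure, standardize_smiles, merge_sources


@dataclass
class PipelineResult:
    annotations: list[agg.PairAnnotation]
    datasets: dict
    id_of_key: dict[str, int]
    series_by_org: dict[Organism, tuple[list, list]]
    scans_by_org: dict[Organism, warheads.WarheadScan]
    cpki_flags: dict[str, bool]
    report: dict
    qualification: QualificationReport
    standardization_failures: list[StandardizationFailure] = field(default_factory=list)


def standardize_records(
    records: list[ActivityRecord],
) -> tuple[dict[str, str], list[ActivityRecord], list[StandardizationFailure]]:
    """Standardize every distinct SMILES; drop records that fail to parse.

    Returns (source smiles -> compound key, surviving records, failures).
    """
    key_of: dict[str, str] = {}
    failures: list[StandardizationFailure] = []
    for smiles in sorted({r.compound_smiles for r in records}):
        result = standardize_smiles(smiles)
        if isinstance(result, StandardizationFailure):
            failures.append(result)
        else:
            key_of[smiles] = result.compound_key
    kept = [r for r in records if r.compound_smiles in key_of]
    return key_of, kept, failures


def run_pipeline(
    chembl_path: Path | None,
    bindingdb_path: Path | None,
    kinase_path: Path,
    out_dir: Path | None = None,
    config: ingest.QualifyConfig | None = None,
    fragmenter: aser.FragmenterConfig | None = None,
    registry_path: Path | None = None,
    scan_all_organisms: bool = False,
) -> PipelineResult:
    kinase_table = ingest.load_kinase_table(kinase_path)

    records: list[ActivityRecord] = []
    if chembl_path is not None:
        records.extend(ingest.parse_chembl_dialect(chembl_path, kinase_table))
    if bindingdb_path is not None:
        records.extend(ingest.parse_bindingdb_dialect(bindingdb_path, kinase_table))

    qualified = ingest.qualify_stream(records, config)

    key_of, kept, failures = standardize_records(qualified.records)
    merged = merge_sources(
        {smiles: key for smiles, key in key_of.items()}
    )
    id_of_key = {key: mol.compound_new_id for key, mol in merged.items()}

    annotations = agg.aggregate_all(kept, key_of)
    for ann in annotations:
        ann.compound_new_id = id_of_key[ann.compound_key]
    datasets = agg.split_datasets(annotations)

    series_by_org: dict[Organism, tuple[list, list]] = {}
    for org in Organism:
        active_keys = sorted(
            {a.compound_key for a in datasets[(org, agg.PairStatus.ACTIVE)]}
        )
        series_by_org[org] = aser.assign_series(active_keys, fragmenter)

    registry = warheads.load_registry(registry_path)
    scan_organisms = list(Organism) if scan_all_organisms else [Organism.HUMAN]
    scans_by_org = {}
    for org in scan_organisms:
        active_keys = sorted(
            {a.compound_key for a in datasets[(org, agg.PairStatus.ACTIVE)]}
        )
        scans_by_org[org] = warheads.scan(active_keys, registry)
    cpki_flags = dict(scans_by_org[Organism.HUMAN].cpki_flags)

    report = export_stats.summarize(annotations, series_by_org, scans_by_org)
    report["qualification"] = qualified.report.to_dict()
    report["standardization_failures"] = len(failures)
    report["n_compounds"] = len(merged)

    if out_dir is not None:
        export_stats.write_datasets(
            datasets, id_of_key, kinase_table, cpki_flags, Path(out_dir)
        )
        export_stats.write_report(report, Path(out_dir) / "summary.json")

    return PipelineResult(
        annotations=annotations,
        datasets=datasets,
        id_of_key=id_of_key,
        series_by_org=series_by_org,
        scans_by_org=scans_by_org,
        cpki_flags=cpki_flags,
        report=report,
        qualification=qualified.report,
        standardization_failures=failures,
    )
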