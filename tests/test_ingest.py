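from __future__ import annotations

import random

import pytest

from kinicurate.ingest import (
    ConfigurationError,
    QualifyResult,
    load_kinase_table,
    parse_bindingdb_dialect,
    parse_chembl_dialect,
    qualify,
    qualify_stream,
)
from kinicurate.records import (
    ActivityRecord,
    MeasurementType,
    Organism,
    Relation,
    Source,
)

SMILES = "c1ccc(Nc2ncnc3ccccc23)cc1"


def make_record(**overrides) -> ActivityRecord:
    base = dict(
        record_id="CH1",
        source=Source.CHEMBL_DIALECT,
        compound_smiles=SMILES,
        kinase_uniprot="P10000",
        organism=Organism.HUMAN,
        measurement_type=MeasurementType.IC50,
        relation=Relation.EQ,
        value_nM=50.0,
        units="nM",
        target_category="SINGLE PROTEIN",
        confidence_score=9,
    )
    base.update(overrides)
    return ActivityRecord(**base)


def write_kinase_table(path):
    path.write_text(
        "uniprot_id\tpref_name\torganism\n"
        "P10000\tKinase A\thuman\n"
        "Q20000\tKinase B\tmouse\n"
    )
    return path


class TestParsing:
    def test_chembl_row_maps_fields(self, tmp_path):
        table = tmp_path / "chembl.tsv"
        table.write_text(
            "activity_id\tcanonical_smiles\taccession\ttarget_type\t"
            "confidence_score\tstandard_type\tstandard_relation\tstandard_value\t"
            "standard_units\tactivity_comment\tactivity_label\n"
            f"A1\t{SMILES}\tP10000\tSINGLE PROTEIN\t9\tIC50\t=\t50\tnM\t\t\n"
            f"A2\t{SMILES}\tP10000\tSINGLE PROTEIN\t9\tEC50\t=\t50\tnM\t\t\n"
            f"A3\t{SMILES}\tP10000\tSINGLE PROTEIN\t9\tIC50\t=\tabc\tnM\t\t\n"
        )
        kinases = load_kinase_table(write_kinase_table(tmp_path / "kin.tsv"))
        records = list(parse_chembl_dialect(table, kinases))
        assert len(records) == 3
        assert records[0].measurement_type is MeasurementType.IC50
        assert records[0].relation is Relation.EQ
        assert records[0].value_nM == 50.0
        assert records[0].organism is Organism.HUMAN
        # non-qualifying type is carried through the parser, not dropped
        assert records[1].measurement_type is MeasurementType.OTHER
        assert records[1].raw_type == "EC50"
        # malformed value becomes an absent value
        assert records[2].value_nM is None

    def test_bindingdb_row_maps_fields(self, tmp_path):
        table = tmp_path / "bdb.tsv"
        table.write_text(
            "reactant_set_id\tligand_smiles\tuniprot_id\tmeasurement_type\t"
            "relation\tvalue_nM\tn_protein_chains\n"
            f"B1\t{SMILES}\tQ20000\tKi\t=\t20\t1\n"
            f"B2\t{SMILES}\tQ20000\tKi\t>\t10000\t1\n"
            f"B3\t{SMILES}\tQ20000\tKi\t=\t20\t2\n"
        )
        kinases = load_kinase_table(write_kinase_table(tmp_path / "kin.tsv"))
        records = list(parse_bindingdb_dialect(table, kinases))
        assert records[0].measurement_type is MeasurementType.KI
        assert records[0].value_nM == 20.0
        assert records[0].confidence_score is None  # absent in this dialect
        assert records[1].relation is Relation.GT
        # multi-chain target row parses but is discarded at qualification
        assert qualify(records[2]).reason == "multi_chain_target"

    def test_missing_column_is_fatal(self, tmp_path):
        table = tmp_path / "bad.tsv"
        table.write_text("activity_id\tcanonical_smiles\nA1\tC\n")
        kinases = load_kinase_table(write_kinase_table(tmp_path / "kin.tsv"))
        with pytest.raises(ConfigurationError, match="accession"):
            list(parse_chembl_dialect(table, kinases))

    def test_empty_file_yields_empty_stream(self, tmp_path):
        table = tmp_path / "empty.tsv"
        table.write_text("")
        kinases = load_kinase_table(write_kinase_table(tmp_path / "kin.tsv"))
        with pytest.warns(UserWarning, match="empty"):
            assert list(parse_chembl_dialect(table, kinases)) == []


class TestQualify:
    @pytest.mark.parametrize(
        "relation,value,expected",
        [
            (Relation.EQ, 50.0, QualifyResult.QUALIFIED_ACTIVE_CANDIDATE),
            (Relation.EQ, 12_000.0, QualifyResult.QUALIFIED_INACTIVE_CANDIDATE),
            (Relation.EQ, 10_000.0, QualifyResult.QUALIFIED_ACTIVE_CANDIDATE),
            (Relation.GT, 10_000.0, QualifyResult.QUALIFIED_INACTIVE_CANDIDATE),
            (Relation.GTGT, 50_000.0, QualifyResult.QUALIFIED_INACTIVE_CANDIDATE),
        ],
    )
    def test_threshold_classification(self, relation, value, expected):
        assert qualify(make_record(relation=relation, value_nM=value)).outcome == expected

    @pytest.mark.parametrize(
        "relation,value",
        [(Relation.GT, 5_000.0), (Relation.LT, 50.0), (Relation.OTHER, 50.0)],
    )
    def test_uninformative_relations_discarded(self, relation, value):
        result = qualify(make_record(relation=relation, value_nM=value))
        assert result.reason == "uninformative_relation"

    @pytest.mark.parametrize(
        "comment",
        ["uncertain", "Potential transcription error", "value outside typical range"],
    )
    def test_comment_blacklist(self, comment):
        result = qualify(make_record(activity_comment=comment))
        assert result.reason == "comment_blacklist"

    def test_chembl_only_filters(self):
        assert qualify(make_record(confidence_score=8)).reason == "low_confidence"
        assert (
            qualify(make_record(target_category="PROTEIN FAMILY")).reason
            == "not_single_protein"
        )
        # the same filters pass for the BindingDB dialect where absent
        record = make_record(
            source=Source.BINDINGDB_DIALECT,
            confidence_score=None,
            target_category=None,
            n_chains=1,
        )
        assert qualify(record).qualified

    def test_label_conflict(self):
        r = make_record(value_nM=50.0, activity_label="inactive")
        assert qualify(r).reason == "label_conflict"
        r = make_record(value_nM=50_000.0, activity_label="active")
        assert qualify(r).reason == "label_conflict"
        r = make_record(value_nM=50.0, activity_label="active")
        assert qualify(r).qualified

    def test_excluded_type_never_qualifies(self):
        r = make_record(measurement_type=MeasurementType.OTHER, raw_type="EC50")
        assert qualify(r).reason == "excluded_type"

    def test_micromolar_units_converted(self):
        r = make_record(value_nM=5.0, units="uM")
        assert qualify(r).qualified
        assert r.value_nM == 5_000.0
        assert r.units == "nM"

    def test_unknown_units_discarded(self):
        r = make_record(units="ug/mL")
        assert qualify(r).reason == "bad_units"


class TestQualifyStream:
    def records(self):
        return [
            make_record(record_id="a"),
            make_record(record_id="b", confidence_score=8),
            make_record(record_id="c", relation=Relation.LT),
            make_record(record_id="d", value_nM=20_000.0),
            make_record(record_id="e", measurement_type=MeasurementType.OTHER),
        ]

    def test_report_balances(self):
        out = qualify_stream(self.records())
        assert out.report.n_read == 5
        assert out.report.n_qualified == 2
        assert out.report.balances()
        assert out.report.discard_counts == {
            "low_confidence": 1,
            "uninformative_relation": 1,
            "excluded_type": 1,
        }

    def test_order_independence(self):
        base = self.records()
        reference = sorted(
            zip((r.record_id for r in qualify_stream(base).records),
                qualify_stream(base).outcomes)
        )
        for seed in range(5):
            shuffled = list(base)
            random.Random(seed).shuffle(shuffled)
            out = qualify_stream(shuffled)
            assert sorted(zip((r.record_id for r in out.records), out.outcomes)) == reference
            assert out.report.to_dict() == qualify_stream(base).report.to_dict()
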