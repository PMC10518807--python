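# kinicurate

A curation pipeline for protein kinase inhibitor (PKI) activity data.

Public bioactivity databases report kinase–inhibitor measurements with
heterogeneous assay types, censored relations, unit mixtures, salt forms and
outright contradictions. `kinicurate` turns such raw activity tables into
clean, classified, analysis-ready data sets for cheminformatics and machine
learning: it qualifies records from two export dialects (a ChEMBL-like and a
BindingDB-like schema), merges compounds on a standardized non-stereo
canonical SMILES identity, aggregates potency per compound–kinase pair with
explicit consistency rules, classifies activity at the 10 µM threshold,
extracts analogue series by retrosynthetic compound–core relationships,
flags covalent warheads, and writes a fixed four-file deposition schema with
summary statistics.

## The rules at the core

**Potency aggregation.** All point measurements (relation `=`) of a
compound–kinase pair are converted to the negative decadic logarithm of the
molar potency, pPot = 9 − log₁₀(value in nM), and pooled by measurement
type across both sources. Then:

1. within a type, the final value is the arithmetic mean of the logs;
2. a type's aggregate is discarded when the sample standard deviation of
   its logs exceeds 1 log unit;
3. assay-independent constants beat IC50: selection priority K_d > K_i > IC50;
4. the pair is **active** when the selected mean pPot ≥ 5.0 (≤ 10,000 nM),
   otherwise **inactive**;
5. a quantitatively active pair that also carries a censored `>`/`>>`
   record is contradictory and dropped entirely;
6. a pair with only censored records is a *qualitative* inactive
   (`mean_log = NaN`).

**Analogue series.** Compounds are cut at up to two acyclic single bonds
matching retrosynthetic environments (amide, ester, amine, ether,
sulfonamide, biaryl, ...); for each cut set the largest fragment is a
candidate core. Compounds sharing a core form a series; cores are chosen
greedily by coverage, every compound ends in exactly one series or as a
singleton, and each member's R-groups reattach to the core to rebuild the
member exactly.

**Covalent warheads.** A registry of 14 SMARTS patterns (acrylamide,
heterocyclic urea, vinyl sulfone, ...) flags potential covalent inhibitors
(`CPKI: True` in the human active file).

## Worked example

```python
from kinicurate import aggregate_measurements, Measurement, MeasurementType, Relation

ms = [
    Measurement(MeasurementType.IC50, Relation.EQ, 50.0),
    Measurement(MeasurementType.IC50, Relation.EQ, 120.0),
    Measurement(MeasurementType.KI, Relation.EQ, 20.0),
]
print(aggregate_measurements(ms))
```

prints

```
('KI', 7.698970004336019, <PairStatus.ACTIVE: 'ACTIVE'>)
```

— the K_i measurement wins over the two IC50 replicates, its mean log
potency is 9 − log₁₀(20) ≈ 7.70 (20 nM), and the pair is active.

```python
from kinicurate import standardize_smiles, assign_series

print(standardize_smiles("C[C@H](N)C(=O)[O-].[Na+]").compound_key)
# -> CC(N)C(=O)O            (salt stripped, neutralized, stereo removed)

series, singletons = assign_series([
    "COc1ccc(Nc2ncnc3ccccc23)cc1",
    "CCOc1ccc(Nc2ncnc3ccccc23)cc1",
    "CN(C)c1ccc(Nc2ncnc3ccccc23)cc1",
])
s = series[0]
print(s.core.core_smiles)     # c1ccc2c(Nc3ccc([*:1])cc3)ncnc2c1
print(s.rgroup_table)         # {..., 'COc1ccc(...)cc1': {1: '*OC'}, ...}
```

The three 4-anilinoquinazolines form one series on the shared core with a
single substitution site carrying `*OC`, `*OCC` and `*N(C)C`.

### Command line

```bash
kinicurate fixtures --seed 1 --out-dir corpus/       # synthetic test corpus
kinicurate ingest --dialect chembl --kinases corpus/kinases.tsv \
    --in corpus/chembl.tsv --out qualified.tsv
kinicurate analogs --in compounds.smi --out-prefix series
kinicurate warheads --in compounds.smi --out hits.tsv
kinicurate run --config run.yaml                     # full pipeline
```

`kinicurate run` writes `human_PKI_active.tsv`, `human_PKI_inactive.tsv`,
`mouse_PKI_active.tsv`, `mouse_PKI_inactive.tsv` (fixed columns
`Compound_new_ID`, `nonstereo_aromatic_smile`, `Uniprot_ID`, `pref_name`,
`activity_id`, `mean_log`, `selected_stvalue`, `ORGANISM`, plus `CPKI` in
the human active file), a `readme.txt`, and a JSON summary report.

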