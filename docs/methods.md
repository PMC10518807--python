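# Methods

## Scope and data model

`kinicurate` curates kinase–inhibitor activity records into classified
compound–kinase pair annotations. A record is one measurement (IC50, K_i or
K_d, in nM) of one compound against one kinase, carried with its relation
(`=`, `>`, `>>`, `<`), source metadata and provenance ID. Two input
dialects are supported through column-mapping presets
(`src/kinicurate/data/dialects.yaml`): a ChEMBL-like schema with target
category, confidence score, activity comments and active/inactive labels,
and a BindingDB-like schema with UniProt accession, chain count and values
already in nM. The presets are data, not code, because real exports differ
between installations.

## Record qualification

Qualification is a total function over parsed records; every input row is
counted exactly once, either as an active/inactive candidate or under a
named discard reason (the report invariant `n_read = n_qualified +
Σ discards` is asserted in tests). Filters:

* measurement type must be IC50, K_i or K_d — EC50, %inhibition and similar
  types are parsed but always discarded (`excluded_type`);
* ChEMBL-dialect records need target category `SINGLE PROTEIN`, confidence
  score 9, no blacklisted comment (case-insensitive substring match against
  a configurable list shipped with "uncertain", "potential transcription
  error", "outside typical range"), and no active/inactive label that
  contradicts the threshold classification;
* BindingDB-dialect records must come from single-chain targets;
* units must normalize to nM. µM/mM/M values are converted rather than
  discarded — this maximizes recall without changing semantics; unknown
  units are discarded;
* relation `=` yields an active candidate at ≤ 10,000 nM and an inactive
  candidate above; `>`/`>>` with value ≥ 10,000 nM yields a qualitative
  inactive candidate. `>` below the threshold, `<` anywhere, and any other
  relation are uninformative: a `<`-censored value cannot give a point
  potency and its activity class could not be verified.

The threshold boundary is deliberate: a point value of exactly 10,000 nM is
*active* (inactivity requires "larger than" the threshold), while `>` at
exactly 10,000 nM is *inactive*.

## Standardization and merging

Compound identity is the non-stereo canonical SMILES produced by:
parse → keep largest organic fragment → neutralize → strip stereo →
canonical aromatic SMILES. Fragment selection prefers carbon-containing
fragments, then more heavy atoms, with molecular weight and lexicographic
SMILES as tie-breaks, so the choice is total. Neutralization uses the
standard acid/base uncharger (quaternary ammonium and other
non-neutralizable charges are kept). Neutralization order (before stereo
stripping, after salt stripping) is fixed; the protocol is idempotent and
re-running it on its own output is the identity. Records from both dialects
whose SMILES collapse to one key merge into one compound; internal IDs are
assigned in lexicographic key order so reruns are bit-identical.

Tautomer canonicalization is *not* performed: distinct tautomers of one
compound remain distinct merge keys. This is a known limitation of the
identity definition.

## Aggregation

Point measurements are log-transformed (pPot = 9 − log₁₀ nM) and pooled by
type across sources before averaging; the mean is computed in log units,
consistent with the standard-deviation gate being stated in log units. The
gate uses the sample SD (n−1 denominator); single measurements are exempt.
Among surviving type aggregates the fixed priority is K_d > K_i > IC50
(assay-independent constants first; the K_d/K_i order is a convention of
this package and configurable in principle through the selection list). A
pair whose every type aggregate fails the SD gate is dropped entirely
rather than demoted to a qualitative annotation; a quantitatively active
pair coexisting with censored `>`/`>>` records is dropped as contradictory,
whereas an EQ-inactive aggregate plus censored records is consistent and
kept. When a valid K_i aggregate is active and a valid IC50 aggregate would
be inactive, the type priority decides and no flag is raised.

## Analogue series

Series are found by compound–core relationships. Each compound is cut at
1..k acyclic single bonds (default k = 2) whose environment matches a
retrosynthetic rule set shipped as data (amide, ester, aliphatic amine,
aryl–N, ether, sulfonamide, biaryl, aromatic-N–aliphatic-C). For each cut
set the largest fragment is the candidate core, subject to: star topology
(every removed fragment attaches directly to the core), substituents of at
most 13 heavy atoms, and a core at least twice as large as all substituents
combined. These size constraints are conventional and configurable. The
uncut molecule is always a candidate with no substituents.

Candidate cores are identified by their **hydrogen-capped** canonical
SMILES. This makes the compound that *is* the bare core a member of its
series through the trivial candidate, with an all-hydrogen R-group row —
without it, a parent compound would be orphaned from its own analogues.
Cores are selected greedily: most still-unassigned compounds covered first,
ties broken by larger core, then lexicographic SMILES. The result is a
deterministic, order-independent partition: every compound lands in exactly
one series (≥ 2 members) or becomes a singleton whose core is its own
structure, and distinct cores always equal series + singletons.

R-group decomposition enumerates all substructure embeddings of the core in
a member and keeps the one with the lexicographically smallest
(site-rank, substituent) signature, which makes the table invariant under
core automorphisms (e.g. para-symmetric rings). Sites are numbered by
canonical atom rank of the core; reattaching each member's substituents to
the numbered core must reproduce the member's SMILES exactly — this
round-trip is asserted for every series in the tests.

## Warheads

The registry (`data/warheads.yaml`) ships 14 covalent warhead classes with
SMARTS patterns, targeted residues, and one positive/negative control
molecule per class. Acrylamide uses the plain Michael-acceptor amide
environment with acyclic vinyl carbons (so maleimides count under their own
class, not as acrylamides); heterocyclic urea requires a ring nitrogen on
an exocyclic urea carbonyl. The registry is editable data; the scanner is a
pure function of (compound set, registry) with deterministic output order.
A compound with two distinct warheads appears in both histogram bars but
counts once as a covalent inhibitor. By deposition convention the scan is
applied to the human active set; `scan_all_organisms` (or the CLI) extends
it to any compound list.

## Synthetic corpus and ground truth

The fixture generator emulates the statistical shape of curated kinase
inhibitor data without any database access. Defaults (the reference study
conditions): 20 analogue series of 3–6 members built from a library of 24
drug-like scaffolds and 30 benign substituents, 10 singleton compounds, 8
kinases (25% mouse), 1–3 pairs per compound, and per-pair true log
potencies drawn uniformly from 5.6–9.0 for actives (most mass in the 6–8
range typical of reported inhibitors, median near 7 ≈ 100 nM) and 3.8–4.4
for planted inactives. Each pair emits 1–4 point measurements over 1–2
measurement types with Gaussian log noise (σ = 0.2, clamped at ±0.5 so an
unplanted SD-gate violation is impossible), split between the two dialects
(50/50 by default); 10% of ChEMBL-dialect rows are written in µM to
exercise unit conversion. Decorations applied at configurable rates: salt
forms (protonated amine + chloride or appended counter-components, 20%),
stereo decorations (random stereoisomer of unassigned centres, 20%), and —
at rates of 0 in the clean reference corpus — censored conflicts, SD-gate
violations, blacklisted comments and sub-9 confidence rows. Warhead
substituents are planted on 15% of series members at the first substitution
site.

Scaffold attachment sites are aromatic carbons and every substituent binds
through N, O or an aromatic carbon, so each planted member's site bonds
match the fragmentation rules and the planted partition is recoverable; the
generator also enforces the core-size constraint when sampling R-groups and
rejects infeasible specifications (series larger than the library, sizes
< 2, rates outside [0, 1]) with an explanation.

Ground truth (series membership, per-pair status/mean log/selected type
computed from the exact values written out, planted warhead classes, and
pathology counts) is recorded at construction, before decoration. What
passing recovery tests show is that the pipeline inverts everything the
generator emulates: dialect parsing, unit mixtures, salt/stereo noise,
replicate aggregation, type priority and planted pathologies. What they do
not show: behaviour on tautomer variation, on measurement types outside
IC50/K_i/K_d, on real exports' schema quirks, or on series whose chemistry
falls outside the shipped fragmentation rules.

## Numerical choices

* Log transform: pPot = 9 − log₁₀(value nM); 10,000 nM ↔ 5.0 exactly.
* SD gate: sample SD, strict `> 1.0` comparison, n = 1 exempt.
* Mean in log units via exact-fraction arithmetic (`statistics.mean`);
  ground-truth comparisons in tests use 1e−9 (end-to-end) and 1e−12
  (unit-level) absolute tolerances.
* Quartiles: linear interpolation (type 7); whiskers at 1.5 × IQR Tukey
  fences, values beyond reported as outliers.
* Deposited `mean_log` values are written at full float precision
  (`repr`); qualitative rows carry the literal `NaN`.
* All orderings (compound IDs, row order, greedy tie-breaks, site
  numbering) are made total via lexicographic fallbacks so every stage is
  rerun- and permutation-stable.

## Independent checks

The test suite contains brute-force reference implementations that share no
mechanics with the pipeline: aggregation re-derived with hand-rolled
mean/SD arithmetic over (type, relation, value) tuples, and candidate-core
enumeration over *all* acyclic single bonds using bond removal (no dummy
atoms) with cut-incidence counting. Neutralization is cross-checked against
Open Babel's `--neutralize` on a 50-molecule charged panel. The acceptance
script reruns the full pipeline on a seeded corpus and reports both the
corpus statistics and the measured recovery of the planted truth.

## Known limitations

* No tautomer/protomer canonicalization (distinct tautomers do not merge).
* The fragmentation rule set is a conventional retrosynthetic selection;
  series counts depend on it and on the size constraints, all configurable.
* Warhead SMARTS are pragmatic class definitions, not reactivity models;
  no distinction between reversible and irreversible covalent chemistry.
* No assay-level weighting or error propagation beyond the SD gate.
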