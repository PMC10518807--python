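"""Synthetic input corpora with known ground truth.

The generator plants a fully known structure–activity corpus and then
renders it as the two raw input dialects, so every pipeline stage can be
tested end-to-end without any database access:

* analogue series are built by decorating scaffold templates with R-groups
  from a small fragment library (series structure is known by
  construction); singletons come from a separate library of unrelated
  molecules;
* each (compound, kinase) pair draws a true log potency centred in the
  6–8 range typical of reported kinase inhibitors and emits 1–4 point
  measurements with small, bounded log-normal noise;
* at configurable rates the emitted records are decorated with salt forms,
  stereochemistry, censored ">" records, above-threshold inactive values,
  replicate sets violating the SD gate, quantitative/qualitative conflicts,
  blacklisted comments and sub-9 confidence scores — each planted pathology
  is counted in the ground truth;
* compounds can carry a registry warhead substituent at a substitution
  site (planted covalent inhibitors).

Ground truth (series partition, per-pair status/mean potency/selected
type, CPKI flags, pathology counts) is recorded at construction time,
before any decoration is applied.
"""

from __future__ import annotations

import importlib.resources
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .records import Organism


class InfeasibleSpec(Exception):
    """The requested corpus cannot be built from the shipped library."""


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic corpus."""

    seed: int = 0
    n_series: int = 20
    series_size_range: tuple[int, int] = (3, 6)
    n_singletons: int = 10
    n_kinases: int = 8
    mouse_fraction: float = 0.25
    pairs_per_compound: tuple[int, int] = (1, 3)
    frac_inactive: float = 0.15
    frac_qualitative: float = 0.10
    frac_conflict: float = 0.0
    frac_sd_violation: float = 0.0
    frac_blacklist: float = 0.0
    frac_low_confidence: float = 0.0
    frac_salt: float = 0.2
    frac_stereo: float = 0.2
    frac_offunit: float = 0.1  # ChEMBL rows emitted in µM instead of nM
    warhead_insertion_rate: float = 0.15
    dialect_split: float = 0.5  # probability a record goes to the ChEMBL dialect
    noise_sd: float = 0.2  # log units; bounded at ±0.5 so the SD gate stays quiet

    def validate(self) -> None:
        for name in (
            "frac_inactive",
            "frac_qualitative",
            "frac_conflict",
            "frac_sd_violation",
            "frac_blacklist",
            "frac_low_confidence",
            "frac_salt",
            "frac_stereo",
            "frac_offunit",
            "warhead_insertion_rate",
            "dialect_split",
            "mouse_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InfeasibleSpec(f"{name} must be in [0, 1], got {v}")


@dataclass
class PairTruth:
    status: str  # ACTIVE | INACTIVE | DISCARDED_SD | DISCARDED_CONFLICT
    mean_log: float | None
    selected_type: str  # KD | KI | IC50 | QUALITATIVE


@dataclass
class GroundTruth:
    series: list[set[str]] = field(default_factory=list)  # member compound keys
    singletons: list[str] = field(default_factory=list)
    pair_truth: dict[tuple[str, str], PairTruth] = field(default_factory=dict)
    warheads: dict[str, list[str]] = field(default_factory=dict)  # key -> classes
    decorations: dict[str, list[str]] = field(default_factory=dict)  # record decorations
    pathology_counts: dict[str, int] = field(default_factory=dict)
    organism_of: dict[str, Organism] = field(default_factory=dict)  # uniprot -> org

    @property
    def compound_keys(self) -> list[str]:
        keys = {k for members in self.series for k in members}
        keys.update(self.singletons)
        return sorted(keys)


@dataclass
class FixtureCorpus:
    spec: FixtureSpec
    chembl_rows: list[dict]
    bindingdb_rows: list[dict]
    kinase_rows: list[dict]
    truth: GroundTruth

    def write(self, out_dir: Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, rows, columns in (
            ("chembl.tsv", self.chembl_rows, _CHEMBL_COLUMNS),
            ("bindingdb.tsv", self.bindingdb_rows, _BINDINGDB_COLUMNS),
            ("kinases.tsv", self.kinase_rows, ("uniprot_id", "pref_name", "organism")),
        ):
            path = out_dir / name
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("\t".join(columns) + "\n")
                for row in rows:
                    fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
            paths[name] = path
        return paths


_CHEMBL_COLUMNS = (
    "activity_id",
    "canonical_smiles",
    "accession",
    "target_type",
    "confidence_score",
    "standard_type",
    "standard_relation",
    "standard_value",
    "standard_units",
    "activity_comment",
    "activity_label",
)

_BINDINGDB_COLUMNS = (
    "reactant_set_id",
    "ligand_smiles",
    "uniprot_id",
    "measurement_type",
    "relation",
    "value_nM",
    "n_protein_chains",
)

_TYPE_NAMES = {"KD": "Kd", "KI": "Ki", "IC50": "IC50"}

_COUNTERIONS = ("Cl", "Br", "OC(=O)C(=O)O", "CS(=O)(=O)O")

_BLACKLIST_COMMENTS = (
    "Uncertain",
    "Potential transcription error",
    "Outside typical range",
)


def load_fragment_library(path: Path | None = None) -> dict:
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    ref = importlib.resources.files("kinicurate.data") / "fragment_library.yaml"
    return yaml.safe_load(ref.read_text())


def _heavy_atoms(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def compose(core_template: str, site_subs: dict[int, str]) -> str:
    """Attach substituents to a scaffold template's numbered sites.

    ``site_subs`` maps the template's atom-map numbers to substituent
    SMILES carrying one ``[*]`` attachment atom; the value "H" caps the
    site with hydrogen.  Returns the canonical SMILES of the product.
    """
    core = Chem.MolFromSmiles(core_template)
    combined = core
    h_sites = set()
    for site, sub in site_subs.items():
        if sub == "H":
            h_sites.add(site)
            continue
        frag = Chem.MolFromSmiles(sub)
        if frag is None:
            raise InfeasibleSpec(f"invalid substituent SMILES: {sub!r}")
        for a in frag.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(site)
        combined = Chem.CombineMols(combined, frag)
    zipped = Chem.molzip(combined)
    rw = Chem.RWMol(zipped)
    for idx in sorted(
        (
            a.GetIdx()
            for a in rw.GetAtoms()
            if a.GetAtomicNum() == 0 and a.GetAtomMapNum() in h_sites
        ),
        reverse=True,
    ):
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def _decorate_salt(smiles: str, rng: random.Random) -> str:
    """Write the compound as a salt: protonate a basic amine when one is
    present (emitting the charged form plus chloride), otherwise append a
    neutral counter-component."""
    mol = Chem.MolFromSmiles(smiles)
    basic_n = Chem.MolFromSmarts("[NX3;!$([NX3][CX3]=[OX1]);!$([NX3]c);!$([NX3][SX4])]")
    matches = mol.GetSubstructMatches(basic_n)
    if matches and rng.random() < 0.5:
        rw = Chem.RWMol(mol)
        atom = rw.GetAtomWithIdx(matches[0][0])
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        out = rw.GetMol()
        try:
            Chem.SanitizeMol(out)
            return Chem.MolToSmiles(out) + ".[Cl-]"
        except Exception:
            pass
    return smiles + "." + rng.choice(_COUNTERIONS)


def _decorate_stereo(smiles: str, rng: random.Random) -> str:
    mol = Chem.MolFromSmiles(smiles)
    opts = StereoEnumerationOptions(maxIsomers=4, onlyUnassigned=True)
    isomers = [Chem.MolToSmiles(m) for m in EnumerateStereoisomers(mol, opts)]
    with_stereo = [s for s in isomers if "@" in s or "/" in s or "\\" in s]
    if not with_stereo:
        return smiles
    return rng.choice(with_stereo)


def _to_log(value_nM: float) -> float:
    return 9.0 - math.log10(value_nM)


def _from_log(log_value: float) -> float:
    return 10.0 ** (9.0 - log_value)


class _Emitter:
    """Accumulates raw rows for both dialects with sequential record IDs."""

    def __init__(self, spec: FixtureSpec, rng: random.Random, truth: GroundTruth):
        self.spec = spec
        self.rng = rng
        self.truth = truth
        self.chembl: list[dict] = []
        self.bindingdb: list[dict] = []
        self._n = 0

    def _decorated_smiles(self, smiles: str) -> tuple[str, list[str]]:
        decorations = []
        out = smiles
        if self.rng.random() < self.spec.frac_stereo:
            decorated = _decorate_stereo(out, self.rng)
            if decorated != out:
                decorations.append("stereo")
                out = decorated
        if self.rng.random() < self.spec.frac_salt:
            out = _decorate_salt(out, self.rng)
            decorations.append("salt")
        return out, decorations

    def emit(
        self,
        smiles: str,
        uniprot: str,
        mtype: str,
        relation: str,
        value_nM: float,
        label: str | None = None,
    ) -> str:
        """Emit one record into a randomly chosen dialect; returns record id."""
        self._n += 1
        dec_smiles, decorations = self._decorated_smiles(smiles)
        to_chembl = self.rng.random() < self.spec.dialect_split
        if to_chembl:
            rid = f"CH{self._n}"
            value, units = value_nM, "nM"
            if relation == "=" and self.rng.random() < self.spec.frac_offunit:
                value, units = value_nM / 1e3, "uM"
            self.chembl.append(
                {
                    "activity_id": rid,
                    "canonical_smiles": dec_smiles,
                    "accession": uniprot,
                    "target_type": "SINGLE PROTEIN",
                    "confidence_score": 9,
                    "standard_type": _TYPE_NAMES[mtype] if mtype in _TYPE_NAMES else mtype,
                    "standard_relation": relation,
                    "standard_value": repr(value),
                    "standard_units": units,
                    "activity_comment": "",
                    "activity_label": label or "",
                }
            )
        else:
            rid = f"BD{self._n}"
            self.bindingdb.append(
                {
                    "reactant_set_id": rid,
                    "ligand_smiles": dec_smiles,
                    "uniprot_id": uniprot,
                    "measurement_type": _TYPE_NAMES[mtype] if mtype in _TYPE_NAMES else mtype,
                    "relation": relation,
                    "value_nM": repr(value_nM),
                    "n_protein_chains": 1,
                }
            )
        if decorations:
            self.truth.decorations[rid] = decorations
        return rid

    def emit_poison(self, smiles: str, uniprot: str, kind: str) -> None:
        """Emit a ChEMBL-dialect record that qualification must discard."""
        self._n += 1
        rid = f"CH{self._n}"
        row = {
            "activity_id": rid,
            "canonical_smiles": smiles,
            "accession": uniprot,
            "target_type": "SINGLE PROTEIN",
            "confidence_score": 9,
            "standard_type": "IC50",
            "standard_relation": "=",
            "standard_value": repr(100.0),
            "standard_units": "nM",
            "activity_comment": "",
            "activity_label": "",
        }
        if kind == "blacklist":
            row["activity_comment"] = self.rng.choice(_BLACKLIST_COMMENTS)
        elif kind == "low_confidence":
            row["confidence_score"] = self.rng.randint(5, 8)
        else:
            raise ValueError(kind)
        self.chembl.append(row)
        self.truth.pathology_counts[kind] = self.truth.pathology_counts.get(kind, 0) + 1


def _build_compounds(
    spec: FixtureSpec, rng: random.Random, truth: GroundTruth
) -> list[str]:
    lib = load_fragment_library()
    cores, subs = lib["cores"], lib["substituents"]
    warhead_subs = lib["warhead_substituents"]
    if spec.n_series > len(cores):
        raise InfeasibleSpec(
            f"n_series={spec.n_series} exceeds the scaffold library ({len(cores)})"
        )
    if spec.n_singletons > len(lib["singletons"]):
        raise InfeasibleSpec(
            f"n_singletons={spec.n_singletons} exceeds the singleton library "
            f"({len(lib['singletons'])})"
        )
    lo, hi = spec.series_size_range
    if lo < 2 or hi < lo:
        raise InfeasibleSpec(f"bad series_size_range {spec.series_size_range}")

    # _heavy_atoms already excludes the [*] attachment atom (atomic number 0)
    sub_heavy = {s: (_heavy_atoms(s) if s != "H" else 0) for s in subs}
    wh_heavy = {w["smiles"]: _heavy_atoms(w["smiles"]) for w in warhead_subs}

    all_keys: set[str] = set()
    for i in range(spec.n_series):
        template = cores[i]
        core_mol = Chem.MolFromSmiles(template)
        sites = sorted(
            a.GetAtomMapNum() for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0
        )
        core_heavy = sum(1 for a in core_mol.GetAtoms() if a.GetAtomicNum() > 1)
        size = rng.randint(lo, hi)
        members: set[str] = set()
        warheads_of: dict[str, list[str]] = {}
        attempts = 0
        while len(members) < size:
            attempts += 1
            if attempts > 200:
                raise InfeasibleSpec(
                    f"cannot build {size} unique members for scaffold {i}"
                )
            chosen: dict[int, str] = {}
            planted_warheads = []
            for site in sites:
                if site == sites[0] and rng.random() < spec.warhead_insertion_rate:
                    w = rng.choice(warhead_subs)
                    chosen[site] = w["smiles"]
                    planted_warheads.append(w["warhead"])
                else:
                    chosen[site] = rng.choice(subs)
            total = sum(
                wh_heavy.get(s, sub_heavy.get(s, 0)) for s in chosen.values()
            )
            if 2 * total > core_heavy:
                continue  # would violate the core-size constraint; resample
            key = compose(template, chosen)
            if key in all_keys or key in members:
                continue
            members.add(key)
            if planted_warheads:
                warheads_of[key] = planted_warheads
        all_keys.update(members)
        truth.series.append(members)
        truth.warheads.update(warheads_of)

    for s in lib["singletons"][: spec.n_singletons]:
        key = Chem.MolToSmiles(Chem.MolFromSmiles(s))
        if key in all_keys:
            raise InfeasibleSpec(f"singleton duplicates a series member: {s}")
        all_keys.add(key)
        truth.singletons.append(key)

    return sorted(all_keys)


def _build_kinases(spec: FixtureSpec, truth: GroundTruth) -> list[dict]:
    n_mouse = round(spec.mouse_fraction * spec.n_kinases)
    rows = []
    for i in range(spec.n_kinases):
        is_mouse = i < n_mouse
        uniprot = f"{'Q' if is_mouse else 'P'}{10000 + i}"
        org = Organism.MOUSE if is_mouse else Organism.HUMAN
        rows.append(
            {
                "uniprot_id": uniprot,
                "pref_name": f"Synthetic kinase {i + 1}",
                "organism": "mouse" if is_mouse else "human",
            }
        )
        truth.organism_of[uniprot] = org
    return rows


def _bounded_noise(rng: random.Random, sd: float) -> float:
    return max(-0.5, min(0.5, rng.gauss(0.0, sd)))


def _emit_pair(
    emitter: _Emitter,
    spec: FixtureSpec,
    rng: random.Random,
    key: str,
    uniprot: str,
) -> PairTruth:
    """Plant one (compound, kinase) pair and emit its measurement records."""
    r = rng.random()
    if r < spec.frac_conflict:
        kind = "conflict"
    elif r < spec.frac_conflict + spec.frac_sd_violation:
        kind = "sd_violation"
    elif r < spec.frac_conflict + spec.frac_sd_violation + spec.frac_qualitative:
        kind = "qualitative"
    elif (
        r
        < spec.frac_conflict
        + spec.frac_sd_violation
        + spec.frac_qualitative
        + spec.frac_inactive
    ):
        kind = "inactive"
    else:
        kind = "active"

    if kind == "qualitative":
        for _ in range(rng.randint(1, 2)):
            emitter.emit(key, uniprot, rng.choice(("IC50", "KI", "KD")), ">",
                         float(rng.choice((10_000, 20_000, 50_000))))
        return PairTruth("INACTIVE", None, "QUALITATIVE")

    if kind == "sd_violation":
        centre = rng.uniform(6.0, 8.0)
        mtype = rng.choice(("IC50", "KI", "KD"))
        for delta in (-1.2, 1.2):
            emitter.emit(key, uniprot, mtype, "=", _from_log(centre + delta))
        emitter.truth.pathology_counts["sd_violation"] = (
            emitter.truth.pathology_counts.get("sd_violation", 0) + 1
        )
        return PairTruth("DISCARDED_SD", None, "QUALITATIVE")

    # quantitative pair (active, inactive, or conflict = active + censored)
    if kind == "inactive":
        true_log = rng.uniform(3.8, 4.4)  # 40-160 µM: safely above threshold
    else:
        true_log = rng.uniform(5.6, 9.0)  # well inside the active range
    n_types = rng.randint(1, 2)
    types = rng.sample(("IC50", "KI", "KD"), n_types)
    logs_by_type: dict[str, list[float]] = {}
    for mtype in types:
        for _ in range(rng.randint(1, 3)):
            lv = true_log + _bounded_noise(rng, spec.noise_sd)
            value = _from_log(lv)
            emitter.emit(key, uniprot, mtype, "=", value)
            # ground-truth potency from the value actually written out
            logs_by_type.setdefault(mtype, []).append(_to_log(value))
    selected = next(t for t in ("KD", "KI", "IC50") if t in logs_by_type)
    mean_log = sum(logs_by_type[selected]) / len(logs_by_type[selected])

    if kind == "conflict":
        emitter.emit(key, uniprot, rng.choice(("IC50", "KI")), ">", 10_000.0)
        emitter.truth.pathology_counts["conflict"] = (
            emitter.truth.pathology_counts.get("conflict", 0) + 1
        )
        return PairTruth("DISCARDED_CONFLICT", None, selected)

    status = "ACTIVE" if mean_log >= 5.0 else "INACTIVE"
    return PairTruth(status, mean_log, selected)


def generate(spec: FixtureSpec | None = None) -> FixtureCorpus:
    """Build one synthetic corpus; bit-reproducible for a fixed seed."""
    spec = spec or FixtureSpec()
    spec.validate()
    rng = random.Random(spec.seed)
    truth = GroundTruth()

    keys = _build_compounds(spec, rng, truth)
    kinase_rows = _build_kinases(spec, truth)
    kinases = [r["uniprot_id"] for r in kinase_rows]
    emitter = _Emitter(spec, rng, truth)

    lo_p, hi_p = spec.pairs_per_compound
    for key in keys:
        n_pairs = rng.randint(lo_p, hi_p)
        for uniprot in rng.sample(kinases, min(n_pairs, len(kinases))):
            truth.pair_truth[(key, uniprot)] = _emit_pair(
                emitter, spec, rng, key, uniprot
            )
        if rng.random() < spec.frac_blacklist:
            emitter.emit_poison(key, rng.choice(kinases), "blacklist")
        if rng.random() < spec.frac_low_confidence:
            emitter.emit_poison(key, rng.choice(kinases), "low_confidence")

    return FixtureCorpus(
        spec=spec,
        chembl_rows=emitter.chembl,
        bindingdb_rows=emitter.bindingdb,
        kinase_rows=kinase_rows,
        truth=truth,
    )
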