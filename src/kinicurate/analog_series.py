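"""Analogue-series extraction via compound-core relationships.

An analogue series (AS) is a set of ≥ 2 compounds sharing one core
structure and differing only in substituents (R-groups) at one or more
sites.  Series are found in three steps:

1. **Fragmentation** — every compound is systematically cut at 1..k acyclic
   single bonds whose environment matches a retrosynthetic rule (amide,
   ester, amine, ether, sulfonamide, biaryl, ...).  For each cut set the
   largest remaining fragment is a candidate core and the removed fragments
   are its substituents; candidates violating size constraints are pruned,
   and the uncut molecule itself is always a candidate with no substituents.
2. **Assignment** — the bipartite compound-core map over all candidates is
   intersected: cores are selected greedily (most compounds covered first)
   to form disjoint series; compounds left over become singletons whose
   core is their own uncut structure.
3. **R-group decomposition** — for each series member, the substituent at
   every numbered site is extracted such that reattaching the R-groups to
   the core reconstructs the member exactly.

Candidate cores are identified by their hydrogen-capped canonical SMILES
(attachment points filled with H).  This makes a compound that *is* the
bare core a member of the series through its trivial candidate, with an
all-hydrogen R-group row.
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

DEFAULT_MAX_CUTS = 2
DEFAULT_MAX_SUBSTITUENT_ATOMS = 13
DEFAULT_CORE_FACTOR = 2.0

H_SUBSTITUENT = "[*][H]"


@dataclass(frozen=True)
class FragmentationRule:
    name: str
    smarts: str
    bond: tuple[int, int]

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"rule {self.name!r}: invalid SMARTS {self.smarts!r}")
        return q


def load_fragmentation_rules(path: Path | None = None) -> list[FragmentationRule]:
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
    else:
        ref = importlib.resources.files("kinicurate.data") / "fragmentation_rules.yaml"
        raw = yaml.safe_load(ref.read_text())
    rules = [FragmentationRule(r["name"], r["smarts"], tuple(r["bond"])) for r in raw]
    for r in rules:
        r.query()  # fail fast on invalid SMARTS
    return rules


@dataclass
class FragmenterConfig:
    max_cuts: int = DEFAULT_MAX_CUTS
    max_substituent_atoms: int = DEFAULT_MAX_SUBSTITUENT_ATOMS
    core_factor: float = DEFAULT_CORE_FACTOR
    rules: list[FragmentationRule] = field(default_factory=load_fragmentation_rules)


@dataclass
class CoreStructure:
    """A core with numbered attachment points ([*:1]..[*:n])."""

    core_smiles: str
    n_sites: int
    heavy_atoms: int
    capped_smiles: str = ""  # hydrogen-capped identity key


@dataclass
class AnalogSeries:
    series_id: int
    core: CoreStructure
    members: list[str]  # compound keys
    rgroup_table: dict[str, dict[int, str]] = field(default_factory=dict)


@dataclass
class Singleton:
    compound_key: str
    core: CoreStructure


def cuttable_bonds(mol: Chem.Mol, rules: list[FragmentationRule]) -> list[int]:
    """Bond indices of acyclic single bonds matching any retrosynthetic rule."""
    found: set[int] = set()
    for rule in rules:
        q = rule.query()
        i, j = rule.bond
        # uniquify=False: symmetric patterns (e.g. ether) must yield the cut
        # bond for every ordering of the match, not one per atom set
        for match in mol.GetSubstructMatches(q, uniquify=False, maxMatches=10000):
            bond = mol.GetBondBetweenAtoms(match[i], match[j])
            if bond is None or bond.IsInRing():
                continue
            if bond.GetBondType() != Chem.BondType.SINGLE:
                continue
            found.add(bond.GetIdx())
    return sorted(found)


def _hydrogen_capped(frag: Chem.Mol) -> str | None:
    """Canonical SMILES of a fragment with its dummy atoms replaced by H."""
    rw = Chem.RWMol(frag)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        atom = rw.GetAtomWithIdx(idx)
        for n in atom.GetNeighbors():
            if n.GetIsAromatic() and n.GetAtomicNum() == 7:
                n.SetBoolProp("_lost_substituent", True)
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    # a pyrrole-type aromatic N that lost its exocyclic substituent needs an
    # explicit H before sanitization, or kekulization fails
    for a in mol.GetAtoms():
        if (
            a.HasProp("_lost_substituent")
            and a.GetDegree() == 2
            and a.GetTotalNumHs() == 0
            and a.GetFormalCharge() == 0
        ):
            a.SetNumExplicitHs(1)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _n_dummies(frag: Chem.Mol) -> int:
    return sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() == 0)


def _heavy(frag: Chem.Mol) -> int:
    return sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1)


def fragment_compound(
    compound_key: str, config: FragmenterConfig | None = None
) -> dict[str, int]:
    """Enumerate candidate cores of one standardized compound.

    Returns a map from hydrogen-capped core SMILES to the core's heavy-atom
    count.  Always contains the trivial candidate (the molecule itself);
    molecules without cuttable bonds yield only that.
    """
    cfg = config or FragmenterConfig()
    mol = Chem.MolFromSmiles(compound_key)
    if mol is None:
        raise ValueError(f"invalid compound key: {compound_key!r}")

    candidates: dict[str, int] = {Chem.MolToSmiles(mol): _heavy(mol)}
    bonds = cuttable_bonds(mol, cfg.rules)
    for n_cuts in range(1, cfg.max_cuts + 1):
        for combo in itertools.combinations(bonds, n_cuts):
            pieces = []  # (heavy, capped smiles, n dummies); acyclic cuts
            for f in Chem.GetMolFrags(  # always yield n_cuts + 1 fragments
                Chem.FragmentOnBonds(mol, combo, addDummies=True),
                asMols=True,
                sanitizeFrags=False,
            ):
                capped = _hydrogen_capped(f)
                if capped is None:
                    pieces = None
                    break
                pieces.append((_heavy(f), capped, _n_dummies(f)))
            if pieces is None:
                continue
            # the largest fragment is the candidate core; ties broken by
            # lexicographic hydrogen-capped SMILES so the choice is total
            pieces.sort(key=lambda p: (-p[0], p[1]))
            (core_atoms, core_capped, core_dummies), subs = pieces[0], pieces[1:]
            # star topology only: every substituent hangs off the core itself
            if core_dummies != n_cuts or any(nd != 1 for _, _, nd in subs):
                continue
            if any(n > cfg.max_substituent_atoms for n, _, _ in subs):
                continue
            if core_atoms < cfg.core_factor * sum(n for n, _, _ in subs):
                continue
            candidates.setdefault(core_capped, core_atoms)
    return candidates


def assign_series(
    compound_keys: list[str], config: FragmenterConfig | None = None
) -> tuple[list[AnalogSeries], list[Singleton]]:
    """Partition a compound set into disjoint analogue series and singletons.

    Cores are chosen greedily by the number of still-unassigned compounds
    they cover; ties are broken by larger core heavy-atom count, then by
    lexicographic core SMILES, so assignment is order-independent.
    """
    cfg = config or FragmenterConfig()
    keys = sorted(set(compound_keys))
    coverage: dict[str, set[str]] = {}
    core_size: dict[str, int] = {}
    for key in keys:
        for core, atoms in fragment_compound(key, cfg).items():
            coverage.setdefault(core, set()).add(key)
            core_size[core] = atoms

    unassigned = set(keys)
    series: list[AnalogSeries] = []
    while True:
        best: tuple[int, int, str] | None = None
        for core in coverage:
            n = len(coverage[core] & unassigned)
            if n < 2:
                continue
            cand = (-n, -core_size[core], core)
            if best is None or cand < best:
                best = cand
        if best is None:
            break
        core_key = best[2]
        members = sorted(coverage[core_key] & unassigned)
        unassigned -= set(members)
        series.append(
            AnalogSeries(
                series_id=0,
                core=CoreStructure(core_key, 0, core_size[core_key], core_key),
                members=members,
            )
        )

    series.sort(key=lambda s: s.core.capped_smiles)
    for i, s in enumerate(series, start=1):
        s.series_id = i
        decompose_series(s)

    singletons = [
        Singleton(
            compound_key=key,
            core=CoreStructure(key, 0, _heavy(Chem.MolFromSmiles(key)), key),
        )
        for key in sorted(unassigned)
    ]
    return series, singletons


# ---------------------------------------------------------------------------
# R-group decomposition


def _match_decomposition(
    member: Chem.Mol, core: Chem.Mol, match: tuple[int, ...]
) -> list[tuple[int, str]] | None:
    """Decompose one substructure match into (core atom, substituent) pairs.

    Returns None when the match is not a valid analogue embedding, i.e. when
    some non-core fragment is attached through more than one bond.
    """
    core_atoms = set(match)
    member_to_core = {m: c for c, m in enumerate(match)}
    attach_bonds = []
    for bond in member.GetBonds():
        b, e = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (b in core_atoms) != (e in core_atoms):
            attach_bonds.append(bond.GetIdx())
    if not attach_bonds:
        return []  # member identical to the core: all-H row

    fragmented = Chem.FragmentOnBonds(member, attach_bonds, addDummies=True)
    frag_tuples = Chem.GetMolFrags(fragmented)
    frag_mols = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False)
    n_member_atoms = member.GetNumAtoms()
    pairs: list[tuple[int, str]] = []
    core_frags = 0
    for tup, frag in zip(frag_tuples, frag_mols):
        original = {i for i in tup if i < n_member_atoms}
        if original == core_atoms:
            core_frags += 1
            continue
        dummies = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            return None  # substituent bridging two sites
        # FragmentOnBonds labels each dummy with the index of the atom at the
        # other end of the broken bond — here, the core-side member atom
        core_atom = member_to_core.get(dummies[0].GetIsotope())
        if core_atom is None:
            return None
        for a in frag.GetAtoms():
            a.SetIsotope(0)
            a.SetAtomMapNum(0)
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            return None
        pairs.append((core_atom, Chem.MolToSmiles(frag)))
    if core_frags != 1:
        return None
    return pairs


def decompose_member(
    member_key: str, core_mol: Chem.Mol
) -> list[tuple[int, str]] | None:
    """Best valid decomposition of one member against a core.

    Among all substructure embeddings of the core, the decomposition with
    the lexicographically smallest (site, substituent) signature is chosen,
    which makes the result invariant under core automorphisms.
    """
    member = Chem.MolFromSmiles(member_key)
    ranks = list(Chem.CanonicalRankAtoms(core_mol, breakTies=True))
    best = None
    for match in member.GetSubstructMatches(core_mol, uniquify=False, maxMatches=5000):
        pairs = _match_decomposition(member, core_mol, match)
        if pairs is None:
            continue
        signature = sorted((ranks[core_atom], smi) for core_atom, smi in pairs)
        if best is None or signature < best[0]:
            best = (signature, pairs)
    if best is None:
        return None
    return best[1]


def decompose_series(series: AnalogSeries) -> AnalogSeries:
    """Fill in numbered attachment sites and the per-member R-group table.

    Sites are the union over members of substituted core positions, numbered
    1..n by canonical atom rank; hydrogen substituents are written
    explicitly.  Raises if a member cannot be decomposed — impossible by
    construction for series produced by :func:`assign_series`.
    """
    core_mol = Chem.MolFromSmiles(series.core.capped_smiles)
    ranks = list(Chem.CanonicalRankAtoms(core_mol, breakTies=True))
    per_member: dict[str, list[tuple[int, str]]] = {}
    site_slots: dict[int, int] = {}  # core atom rank -> max simultaneous subs
    for member in series.members:
        pairs = decompose_member(member, core_mol)
        if pairs is None:
            raise RuntimeError(
                f"series member {member!r} does not embed its core "
                f"{series.core.capped_smiles!r}"
            )
        per_member[member] = pairs
        counts: dict[int, int] = {}
        for core_atom, _ in pairs:
            counts[ranks[core_atom]] = counts.get(ranks[core_atom], 0) + 1
        for rank, n in counts.items():
            site_slots[rank] = max(site_slots.get(rank, 0), n)

    # site numbering: 1..n over (rank, occurrence slot)
    slots = [
        (rank, occ) for rank in sorted(site_slots) for occ in range(site_slots[rank])
    ]
    site_of = {slot: i + 1 for i, slot in enumerate(slots)}

    table: dict[str, dict[int, str]] = {}
    for member in series.members:
        row = {site: H_SUBSTITUENT for site in site_of.values()}
        used: dict[int, int] = {}
        for rank, smi in sorted(
            (ranks[core_atom], smi) for core_atom, smi in per_member[member]
        ):
            occ = used.get(rank, 0)
            used[rank] = occ + 1
            row[site_of[(rank, occ)]] = smi
        table[member] = row

    series.rgroup_table = table
    series.core.n_sites = len(slots)
    series.core.core_smiles = _numbered_core_smiles(core_mol, ranks, slots)
    return series


def _numbered_core_smiles(
    core_mol: Chem.Mol, ranks: list[int], slots: list[tuple[int, int]]
) -> str:
    """Attach numbered dummy atoms ([*:i]) at each substitution site."""
    rw = Chem.RWMol(core_mol)
    atom_of_rank = {ranks[a.GetIdx()]: a.GetIdx() for a in core_mol.GetAtoms()}
    for i, (rank, _occ) in enumerate(slots, start=1):
        dummy = Chem.Atom(0)
        dummy.SetAtomMapNum(i)
        d = rw.AddAtom(dummy)
        rw.AddBond(atom_of_rank[rank], d, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def reassemble(series: AnalogSeries, member_key: str) -> str:
    """Rebuild one member from the series core plus its R-group row.

    The round-trip ``reassemble(series, m) == m`` is the structural
    correctness guarantee of the decomposition.
    """
    core = Chem.MolFromSmiles(series.core.core_smiles)
    row = series.rgroup_table[member_key]
    combined = Chem.RWMol(core)
    for site, sub_smiles in sorted(row.items()):
        if sub_smiles == H_SUBSTITUENT:
            continue
        sub = Chem.MolFromSmiles(sub_smiles)
        for a in sub.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(site)
        combined = Chem.RWMol(Chem.CombineMols(combined.GetMol(), sub))
    zipped = Chem.molzip(combined.GetMol())
    # unfilled sites carry H implicitly once their dummies are removed
    rw = Chem.RWMol(zipped)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)
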