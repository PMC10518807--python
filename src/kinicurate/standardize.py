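"""SMILES standardization and cross-source compound merging.

Compound identity throughout the pipeline is the *non-stereo canonical
SMILES* produced by :func:`standardize_smiles`:

    parse -> keep largest organic fragment -> neutralize -> strip stereo
          -> canonical aromatic SMILES

Records from both source dialects whose SMILES collapse onto the same key
are merged into one compound.  The protocol is idempotent, so re-running it
on its own output is the identity; tautomer canonicalization is deliberately
not part of the protocol (distinct tautomers remain distinct compounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import MolWt
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

_UNCHARGER = rdMolStandardize.Uncharger()


@dataclass
class StandardMolecule:
    """A compound after standardization, keyed by its merge identity."""

    compound_key: str
    compound_new_id: int | None = None
    source_smiles: list[str] = field(default_factory=list)


@dataclass
class StandardizationFailure:
    smiles: str
    reason: str


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Pick the retained fragment of a multi-component structure.

    Fragments containing carbon are preferred over purely inorganic ones
    (counterions, water); among those, the fragment with the most heavy
    atoms wins, with ties broken by molecular weight and then by
    lexicographically smallest canonical SMILES so the choice is total.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return frags[0]
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    pool = organic or list(frags)

    def sort_key(f: Chem.Mol):
        return (-f.GetNumHeavyAtoms(), -MolWt(f), Chem.MolToSmiles(f))

    return sorted(pool, key=sort_key)[0]


def standardize_smiles(smiles: str) -> StandardMolecule | StandardizationFailure:
    """Apply the full standardization protocol to one SMILES string.

    Returns a :class:`StandardMolecule` carrying the merge key, or a
    :class:`StandardizationFailure` for unparseable input (a logged discard
    downstream, never an exception).
    """
    if not smiles or not smiles.strip():
        return StandardizationFailure(smiles, "empty_smiles")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationFailure(smiles, "unparseable_smiles")
    try:
        mol = _largest_organic_fragment(mol)
        Chem.SanitizeMol(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        key = Chem.MolToSmiles(mol)  # canonical, aromatic
        # defensive round-trip: the key must itself parse
        if Chem.MolFromSmiles(key) is None:
            return StandardizationFailure(smiles, "canonicalization_failed")
    except Exception:
        return StandardizationFailure(smiles, "sanitization_failed")
    return StandardMolecule(compound_key=key, source_smiles=[smiles])


def merge_sources(keyed_smiles: dict[str, str]) -> dict[str, StandardMolecule]:
    """Merge standardized compounds and assign deterministic internal IDs.

    ``keyed_smiles`` maps each original source SMILES to its compound key.
    Compounds are numbered 1..N in lexicographic order of their key so that
    reruns on the same input are bit-identical.
    """
    by_key: dict[str, StandardMolecule] = {}
    for src, key in sorted(keyed_smiles.items()):
        mol = by_key.setdefault(key, StandardMolecule(compound_key=key))
        mol.source_smiles.append(src)
    for new_id, key in enumerate(sorted(by_key), start=1):
        by_key[key].compound_new_id = new_id
    return by_key
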