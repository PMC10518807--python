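"""Covalent-warhead annotation by SMARTS substructure search.

A compound is flagged as a potential covalent inhibitor (CPKI) when at
least one reactive-group pattern from the registry matches.  The default
registry ships 14 warhead classes; it is plain data and can be replaced
with ``--registry`` on the command line.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml
from rdkit import Chem


class RegistryError(Exception):
    pass


@dataclass(frozen=True)
class WarheadPattern:
    name: str
    smarts: str
    targeted_residues: tuple[str, ...]
    positive_control: str | None = None
    negative_control: str | None = None

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:  # load_registry guarantees this never triggers
            raise RegistryError(f"warhead {self.name!r}: invalid SMARTS")
        return q


@dataclass(frozen=True)
class WarheadHit:
    compound_key: str
    warhead_name: str
    match_count: int


@dataclass
class WarheadScan:
    hits: list[WarheadHit]
    histogram: dict[str, int]  # warhead name -> number of compounds
    cpki_flags: dict[str, bool]  # compound key -> flagged


def load_registry(path: Path | None = None) -> list[WarheadPattern]:
    """Load a warhead registry; validates SMARTS and name uniqueness."""
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
    else:
        ref = importlib.resources.files("kinicurate.data") / "warheads.yaml"
        raw = yaml.safe_load(ref.read_text())
    if not raw:
        raise RegistryError("warhead registry is empty")
    patterns = []
    seen = set()
    for entry in raw:
        name = entry["name"]
        if name in seen:
            raise RegistryError(f"duplicate warhead name: {name!r}")
        seen.add(name)
        if Chem.MolFromSmarts(entry["smarts"]) is None:
            raise RegistryError(f"warhead {name!r}: invalid SMARTS {entry['smarts']!r}")
        patterns.append(
            WarheadPattern(
                name=name,
                smarts=entry["smarts"],
                targeted_residues=tuple(entry.get("residues", ())),
                positive_control=entry.get("positive_control"),
                negative_control=entry.get("negative_control"),
            )
        )
    return patterns


def scan(
    compound_keys: list[str], registry: list[WarheadPattern] | None = None
) -> WarheadScan:
    """Match every compound against every registry pattern.

    Pure function of (compound set, registry): output is sorted by compound
    key and registry order, so reruns are identical.  A compound carrying
    two distinct warheads contributes to both histogram bars but counts
    once as a CPKI.
    """
    patterns = registry if registry is not None else load_registry()
    queries = [(p.name, p.query()) for p in patterns]
    hits: list[WarheadHit] = []
    histogram: dict[str, int] = {}
    flags: dict[str, bool] = {}
    for key in sorted(set(compound_keys)):
        mol = Chem.MolFromSmiles(key)
        if mol is None:
            raise ValueError(f"invalid compound key: {key!r}")
        flagged = False
        for name, q in queries:
            n = len(mol.GetSubstructMatches(q, uniquify=True))
            if n:
                hits.append(WarheadHit(key, name, n))
                histogram[name] = histogram.get(name, 0) + 1
                flagged = True
        flags[key] = flagged
    return WarheadScan(hits=hits, histogram=histogram, cpki_flags=flags)
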