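"""Independent brute-force reference implementations, used only by tests.

These deliberately re-derive the pipeline's two central computations with
different mechanics so they can serve as oracles:

* ``aggregate_oracle`` — per-pair aggregation rules written directly on
  (type, relation, value) tuples with hand-rolled mean/SD arithmetic;
* ``candidate_cores_oracle`` / ``assign_series_oracle`` — exhaustive
  enumeration over *all* acyclic single bonds, filtering by the rule set
  per bond, and fragmenting by bond *removal* (no dummy atoms), with
  cut-incidence counting instead of dummy counting for the star-topology
  check.
"""

from __future__ import annotations

import itertools
import math

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

_PRIORITY = ("KD", "KI", "IC50")


def aggregate_oracle(measurements):
    """measurements: iterable of (type, relation, value_nM) with type in
    {IC50, KI, KD} and relation in {'=', '>', '>>'}.

    Returns (selected_type, mean_log, status) exactly as the pipeline's
    PairAnnotation fields.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("empty measurement set")
    point = [(t, 9.0 - math.log10(v)) for t, rel, v in ms if rel == "="]
    censored = [m for m in ms if m[1] in (">", ">>")]

    if not point:
        return "QUALITATIVE", None, "INACTIVE"

    groups: dict[str, list[float]] = {}
    for t, lg in point:
        groups.setdefault(t, []).append(lg)

    valid: dict[str, float] = {}
    for t, logs in groups.items():
        m = sum(logs) / len(logs)
        if len(logs) > 1:
            sd = math.sqrt(sum((x - m) ** 2 for x in logs) / (len(logs) - 1))
            if sd > 1.0:
                continue
        valid[t] = m
    if not valid:
        return "QUALITATIVE", None, "DISCARDED_SD"

    selected = next(t for t in _PRIORITY if t in valid)
    mean_log = valid[selected]
    if mean_log >= 5.0:
        return (
            selected,
            mean_log,
            "DISCARDED_CONFLICT" if censored else "ACTIVE",
        )
    return selected, mean_log, "INACTIVE"


# ---------------------------------------------------------------------------
# compound-core relationship oracle


def _capped_fragment_smiles(frag: Chem.Mol, touched: set[int], idx_map) -> str | None:
    for local, original in idx_map.items():
        if original in touched:
            a = frag.GetAtomWithIdx(local)
            if (
                a.GetIsAromatic()
                and a.GetAtomicNum() == 7
                and a.GetDegree() == 2
                and a.GetTotalNumHs() == 0
                and a.GetFormalCharge() == 0
            ):
                a.SetNumExplicitHs(1)
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        return None
    return Chem.MolToSmiles(frag)


def candidate_cores_oracle(
    smiles: str, rules, max_cuts=2, max_sub=13, factor=2.0
) -> set[str]:
    """All valid hydrogen-capped candidate cores, by exhaustive enumeration."""
    mol = Chem.MolFromSmiles(smiles)
    rule_pairs: set[frozenset[int]] = set()
    for rule in rules:
        q = Chem.MolFromSmarts(rule.smarts)
        i, j = rule.bond
        for match in mol.GetSubstructMatches(q, uniquify=False, maxMatches=100000):
            rule_pairs.add(frozenset((match[i], match[j])))

    cut_bonds = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        ends = frozenset((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        if ends in rule_pairs:
            cut_bonds.append(tuple(sorted(ends)))

    candidates = {Chem.MolToSmiles(mol)}
    for r in range(1, max_cuts + 1):
        for combo in itertools.combinations(cut_bonds, r):
            rw = Chem.RWMol(mol)
            touched: set[int] = set()
            for a, b in combo:
                rw.RemoveBond(a, b)
                touched.update((a, b))
            frag_tuples = Chem.GetMolFrags(rw)
            frag_mols = Chem.GetMolFrags(rw, asMols=True, sanitizeFrags=False)

            pieces = []
            ok = True
            for tup, frag in zip(frag_tuples, frag_mols):
                idx_map = {local: orig for local, orig in enumerate(tup)}
                capped = _capped_fragment_smiles(frag, touched, idx_map)
                if capped is None:
                    ok = False
                    break
                incident = sum(
                    1 for a, b in combo if a in set(tup) or b in set(tup)
                )
                pieces.append((len(tup), capped, incident))
            if not ok:
                continue
            pieces.sort(key=lambda p: (-p[0], p[1]))
            (core_n, core_capped, _), subs = pieces[0], pieces[1:]
            if any(inc != 1 for _, _, inc in subs):
                continue
            if any(n > max_sub for n, _, _ in subs):
                continue
            if core_n < factor * sum(n for n, _, _ in subs):
                continue
            candidates.add(core_capped)
    return candidates


def assign_series_oracle(
    keys, rules, max_cuts=2, max_sub=13, factor=2.0
) -> tuple[list[tuple[str, ...]], list[str]]:
    """Greedy disjoint series from the exhaustive candidate-core map.

    Returns (sorted member tuples of each series, sorted singleton keys).
    """
    keys = sorted(set(keys))
    cover: dict[str, set[str]] = {}
    size: dict[str, int] = {}
    for key in keys:
        for core in candidate_cores_oracle(key, rules, max_cuts, max_sub, factor):
            cover.setdefault(core, set()).add(key)
            core_mol = Chem.MolFromSmiles(core)
            size[core] = core_mol.GetNumHeavyAtoms()

    unassigned = set(keys)
    series = []
    while True:
        scored = sorted(
            (
                (-len(cover[c] & unassigned), -size[c], c)
                for c in cover
                if len(cover[c] & unassigned) >= 2
            ),
        )
        if not scored:
            break
        core = scored[0][2]
        members = tuple(sorted(cover[core] & unassigned))
        unassigned -= set(members)
        series.append(members)
    return sorted(series), sorted(unassigned)
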