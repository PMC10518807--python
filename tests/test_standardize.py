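from __future__ import annotations

import random
import shutil
import subprocess

import pytest
from rdkit import Chem

from kinicurate.fixtures import _decorate_salt, _decorate_stereo
from kinicurate.standardize import (
    StandardizationFailure,
    StandardMolecule,
    merge_sources,
    standardize_smiles,
)

from conftest import random_library_molecules


def key_of(smiles: str) -> str:
    result = standardize_smiles(smiles)
    assert isinstance(result, StandardMolecule), result
    return result.compound_key


class TestProtocol:
    def test_salt_stripping(self):
        assert key_of("CC(=O)O.[Na+]") == key_of("CC(=O)O")
        assert key_of("c1ccc(Nc2ncnc3ccccc23)cc1.Cl") == key_of(
            "c1ccc(Nc2ncnc3ccccc23)cc1"
        )

    def test_stereo_removal(self):
        assert key_of("C[C@H](N)C(=O)O") == key_of("CC(N)C(=O)O")
        assert key_of("C/C=C/C(=O)Nc1ccccc1") == key_of("CC=CC(=O)Nc1ccccc1")

    def test_neutralization(self):
        assert key_of("C1CC1C(=O)[O-]") == key_of("C1CC1C(=O)O")
        assert key_of("C[NH+](C)Cc1ccccc1.[Cl-]") == key_of("CN(C)Cc1ccccc1")

    def test_key_has_no_stereo_markers_single_fragment(self):
        key = key_of("C[C@H](N)C(=O)[O-].[Na+]")
        assert not any(ch in key for ch in ("@", "/", "\\"))
        assert "." not in key

    def test_unparseable_smiles_is_failure_not_error(self):
        result = standardize_smiles("not_a_smiles((")
        assert isinstance(result, StandardizationFailure)
        assert result.reason == "unparseable_smiles"
        assert isinstance(standardize_smiles(""), StandardizationFailure)

    def test_idempotence_on_decorated_panel(self):
        rng = random.Random(7)
        for smiles in random_library_molecules(rng, 40):
            key = key_of(smiles)
            assert key_of(key) == key
            assert key_of(_decorate_salt(smiles, rng)) == key
            assert key_of(_decorate_stereo(smiles, rng)) == key


class TestMerge:
    def test_variants_unify(self):
        base = "CN(C)c1ccc(Nc2ncnc3ccccc23)cc1"
        variants = {
            base: key_of(base),
            base + ".Cl": key_of(base + ".Cl"),
        }
        merged = merge_sources(variants)
        assert len(merged) == 1
        (mol,) = merged.values()
        assert sorted(mol.source_smiles) == sorted(variants)

    def test_distinct_scaffolds_stay_distinct(self):
        smiles = ["CC(C)Cc1ccc(C(C)C(=O)O)cc1", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"]
        merged = merge_sources({s: key_of(s) for s in smiles})
        assert len(merged) == 2

    def test_ids_deterministic_and_dense(self):
        rng = random.Random(3)
        panel = random_library_molecules(rng, 25)
        mapping = {s: key_of(s) for s in panel}
        merged_a = merge_sources(mapping)
        merged_b = merge_sources(dict(reversed(list(mapping.items()))))
        ids_a = {k: m.compound_new_id for k, m in merged_a.items()}
        ids_b = {k: m.compound_new_id for k, m in merged_b.items()}
        assert ids_a == ids_b
        assert sorted(ids_a.values()) == list(range(1, len(ids_a) + 1))
        # IDs follow lexicographic key order
        ordered = sorted(ids_a)
        assert [ids_a[k] for k in ordered] == list(range(1, len(ordered) + 1))


@pytest.mark.skipif(shutil.which("obabel") is None, reason="Open Babel not on PATH")
class TestNeutralizationCrossCheck:
    """Round-trip the neutralizer against Open Babel on a charged panel."""

    @staticmethod
    def _is_basic_amine(atom: Chem.Atom) -> bool:
        if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
            return False
        if atom.GetDegree() + atom.GetTotalNumHs() != 3 or atom.GetFormalCharge():
            return False
        for nbr in atom.GetNeighbors():
            if nbr.GetAtomicNum() != 6 or nbr.GetIsAromatic():
                return False
            # exclude amide/amidine nitrogens
            if any(b.GetBondTypeAsDouble() > 1.0 for b in nbr.GetBonds()):
                return False
        return True

    def charged_panel(self) -> list[str]:
        rng = random.Random(11)
        panel = []
        for smiles in random_library_molecules(rng, 300):
            mol = Chem.MolFromSmiles(smiles)
            rw = Chem.RWMol(mol)
            changed = False
            for atom in rw.GetAtoms():
                if changed:
                    break
                # deprotonate an acid or protonate a basic aliphatic amine
                if atom.GetAtomicNum() == 8 and atom.GetTotalNumHs() == 1:
                    nbr = atom.GetNeighbors()[0]
                    if any(
                        b.GetBondType() == Chem.BondType.DOUBLE
                        for b in nbr.GetBonds()
                    ):
                        atom.SetFormalCharge(-1)
                        atom.SetNumExplicitHs(0)
                        changed = True
                elif self._is_basic_amine(atom):
                    atom.SetFormalCharge(1)
                    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                    changed = True
            if changed:
                out = rw.GetMol()
                try:
                    Chem.SanitizeMol(out)
                except Exception:
                    continue
                panel.append(Chem.MolToSmiles(out))
            if len(panel) == 50:
                break
        return panel

    def test_agrees_with_openbabel(self):
        panel = self.charged_panel()
        assert len(panel) >= 30
        proc = subprocess.run(
            ["obabel", "-ismi", "-osmi", "--neutralize"],
            input="\n".join(panel) + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        neutralized = [line.split()[0] for line in proc.stdout.splitlines() if line.strip()]
        assert len(neutralized) == len(panel)
        mismatches = []
        for charged, ob_neutral in zip(panel, neutralized):
            # independent route: Open Babel neutralizes, RDKit only
            # canonicalizes (largest fragment + stereo strip, no uncharging)
            mol = Chem.MolFromSmiles(ob_neutral)
            assert mol is not None
            frags = sorted(
                Chem.GetMolFrags(mol, asMols=True),
                key=lambda f: -f.GetNumHeavyAtoms(),
            )
            ref = frags[0]
            Chem.RemoveStereochemistry(ref)
            if Chem.MolToSmiles(ref) != key_of(charged):
                mismatches.append((charged, ob_neutral))
        assert not mismatches, mismatches
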