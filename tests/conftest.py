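from __future__ import annotations

import random

import pytest
from rdkit import Chem

from kinicurate import fixtures, pipeline
from kinicurate.fixtures import FixtureSpec, compose, load_fragment_library


@pytest.fixture(scope="session")
def clean_corpus():
    """The reference clean corpus: 20 series (3-6 members), 10 singletons,
    8 kinases, no planted pathologies."""
    return fixtures.generate(FixtureSpec(seed=101))


@pytest.fixture(scope="session")
def clean_corpus_dir(clean_corpus, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    clean_corpus.write(out)
    return out


@pytest.fixture(scope="session")
def pipeline_result(clean_corpus_dir):
    return pipeline.run_pipeline(
        clean_corpus_dir / "chembl.tsv",
        clean_corpus_dir / "bindingdb.tsv",
        clean_corpus_dir / "kinases.tsv",
        scan_all_organisms=True,
    )


def random_library_molecules(rng: random.Random, n: int) -> list[str]:
    """Sample n distinct standardized molecules from the fixture fragment
    library: decorated scaffolds plus occasional singleton structures."""
    lib = load_fragment_library()
    out: set[str] = set()
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        if rng.random() < 0.2:
            smi = rng.choice(lib["singletons"])
            out.add(Chem.MolToSmiles(Chem.MolFromSmiles(smi)))
            continue
        template = rng.choice(lib["cores"])
        core = Chem.MolFromSmiles(template)
        sites = sorted(
            a.GetAtomMapNum() for a in core.GetAtoms() if a.GetAtomicNum() == 0
        )
        subs = {site: rng.choice(lib["substituents"]) for site in sites}
        out.add(compose(template, subs))
    return sorted(out)
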