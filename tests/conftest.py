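from pathlib import Path

import pytest

import cladehouse as ch
from cladehouse import synthetic
from cladehouse.pipeline import run_build

# Two-genus clade with strains and some alternative splicing: exercises
# every entity type at once.
STANDARD_PARAMS = ch.CorpusParams(
    n_genera=2,
    n_species=2,
    strains_per_species=1,
    genomes_per_organism=1,
    cds_per_genome=4,
    proteins_linked_fraction=0.8,
    isoforms_per_protein_mean=0.8,
    go_terms_pool=25,
    pfam_pool=10,
    pdb_chain_fraction=0.4,
    seed=20_260_928,
)


def build_from_dir(corpus_dir: Path, query: str, db_path: Path, **kwargs):
    config = synthetic.write_config(corpus_dir)
    return run_build(config, query, db_path, **kwargs)


@pytest.fixture(scope="session")
def corpus(tmp_path_factory) -> tuple[Path, ch.CorpusManifest]:
    out = tmp_path_factory.mktemp("corpus")
    manifest = ch.generate_corpus(STANDARD_PARAMS, out)
    return out, manifest


@pytest.fixture(scope="session")
def built(corpus, tmp_path_factory):
    """Warehouse built from the standard corpus with a whole-clade query."""
    corpus_dir, manifest = corpus
    db_path = tmp_path_factory.mktemp("db") / "warehouse.db"
    result = build_from_dir(corpus_dir, manifest.root_name, db_path)
    return manifest, db_path, result
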