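"""Taxdump parsing and subtree resolution against naive traversal oracles."""

import random

import pytest

from cladehouse import (
    IntegrityError,
    OrganismNotFoundError,
    TaxdumpError,
    descendant_taxa,
    parse_taxdump,
    resolve_name,
)
from cladehouse.pipeline import load_taxonomy


def dmp(*fields) -> str:
    return "\t|\t".join(str(f) for f in fields) + "\t|"


def make_taxonomy(nodes, names=None):
    """nodes: (taxid, parent, rank, name) tuples → parsed Taxonomy."""
    node_lines = [dmp(t, p, r) for t, p, r, _ in nodes]
    name_lines = [dmp(t, n, "", "scientific name") for t, _, _, n in nodes]
    for extra in names or ():
        name_lines.append(dmp(*extra))
    return parse_taxdump(name_lines, node_lines)


ROOTED = [
    (1, 1, "no rank", "root"),
    (131567, 1, "no rank", "cellular organisms"),
    (2, 131567, "superkingdom", "Bacteria"),
]


def test_taxdump_field_mapping():
    tax = make_taxonomy(ROOTED)
    node = tax[2]
    assert (node.taxid, node.parent_taxid, node.rank, node.scientific_name) == (
        2,
        131567,
        "superkingdom",
        "Bacteria",
    )


def test_self_parent_root_accepted_and_marked():
    tax = make_taxonomy(ROOTED)
    assert tax[1].is_root and not tax[2].is_root


def test_malformed_line_names_line_number():
    with pytest.raises(TaxdumpError, match="line 2"):
        parse_taxdump(
            [dmp(1, "root", "", "scientific name"), "only-one-field\t|"],
            [dmp(1, 1, "no rank")],
        )


def test_duplicate_taxid_is_integrity_error():
    node_lines = [dmp(1, 1, "no rank"), dmp(1, 1, "no rank")]
    name_lines = [dmp(1, "root", "", "scientific name")]
    with pytest.raises(IntegrityError, match="duplicate taxid"):
        parse_taxdump(name_lines, node_lines)


def test_node_without_scientific_name_rejected():
    node_lines = [dmp(1, 1, "no rank"), dmp(2, 1, "genus")]
    name_lines = [
        dmp(1, "root", "", "scientific name"),
        dmp(2, "only-a-synonym", "", "synonym"),
    ]
    with pytest.raises(TaxdumpError, match="no scientific-name"):
        parse_taxdump(name_lines, node_lines)


GENUS_TREE = [
    (1, 1, "no rank", "root"),
    (10, 1, "genus", "Genusia"),
    (11, 10, "species", "Genusia alpha"),
    (12, 10, "species", "Genusia beta"),
    (13, 10, "species", "Genusia gamma"),
]


def test_genus_query_collects_all_species():
    tax = make_taxonomy(GENUS_TREE)
    ts = resolve_name(tax, "Genusia")
    assert ts.member_taxids == {10, 11, 12, 13}
    assert ts.root_taxids == (10,)


def test_leaf_query_is_singleton():
    tax = make_taxonomy(GENUS_TREE)
    assert resolve_name(tax, "Genusia beta").member_taxids == {12}


def test_matching_is_case_insensitive_exact():
    tax = make_taxonomy(GENUS_TREE)
    assert resolve_name(tax, "gEnUsIa").member_taxids == {10, 11, 12, 13}
    with pytest.raises(OrganismNotFoundError):
        resolve_name(tax, "Genus")  # substring must not match


def test_unknown_name_raises_with_query():
    tax = make_taxonomy(GENUS_TREE)
    with pytest.raises(OrganismNotFoundError, match="zzz-nonexistent"):
        resolve_name(tax, "zzz-nonexistent")


def test_empty_query_is_usage_error():
    tax = make_taxonomy(GENUS_TREE)
    with pytest.raises(ValueError):
        resolve_name(tax, "   ")


def test_synonym_resolves_but_does_not_shadow_scientific_name():
    tax = make_taxonomy(GENUS_TREE, names=[(10, "the genusias", "", "common name")])
    assert resolve_name(tax, "the genusias").member_taxids == {10, 11, 12, 13}
    assert tax[10].scientific_name == "Genusia"


def test_ambiguous_name_resolves_to_all_matches():
    nodes = GENUS_TREE + [(20, 1, "genus", "genusia")]  # same name, other case
    tax = make_taxonomy(nodes)
    ts = resolve_name(tax, "GENUSIA")
    assert set(ts.root_taxids) == {10, 20}
    assert ts.member_taxids == {10, 11, 12, 13, 20}


def test_descendants_chain_and_leaf():
    chain = [
        (1, 1, "no rank", "a"),
        (2, 1, "species", "b"),
        (3, 2, "strain", "c"),
    ]
    tax = make_taxonomy(chain)
    assert descendant_taxa(tax, 1) == {1, 2, 3}
    assert descendant_taxa(tax, 3) == {3}
    with pytest.raises(KeyError):
        descendant_taxa(tax, 99)


def test_parsing_is_insensitive_to_record_order():
    rng = random.Random(5)
    nodes = list(GENUS_TREE)
    rng.shuffle(nodes)
    shuffled = make_taxonomy(nodes)
    reference = make_taxonomy(GENUS_TREE)
    assert {n.taxid: n for n in shuffled} == {n.taxid: n for n in reference}
    assert resolve_name(shuffled, "Genusia").member_taxids == {10, 11, 12, 13}


def oracle_subtree(parents: dict[int, int], root: int) -> set[int]:
    """Naive recursion over the parent table."""
    children: dict[int, list[int]] = {}
    for taxid, parent in parents.items():
        if taxid != parent:
            children.setdefault(parent, []).append(taxid)

    def walk(t: int) -> set[int]:
        out = {t}
        for c in children.get(t, ()):
            out |= walk(c)
        return out

    return walk(root)


def random_tree(rng: random.Random, n: int):
    nodes = [(1, 1, "no rank", "node-1")]
    for i in range(2, n + 1):
        nodes.append((i, rng.randint(1, i - 1), "clade", f"node-{i}"))
    return nodes


def test_random_trees_match_recursive_oracle():
    rng = random.Random(42)
    for _ in range(5):
        n = rng.randint(10, 80)
        nodes = random_tree(rng, n)
        tax = make_taxonomy(nodes)
        parents = {t: p for t, p, _, _ in nodes}
        for root in parents:
            assert descendant_taxa(tax, root) == oracle_subtree(parents, root)


def test_subtree_closure_invariant():
    """No node outside a resolved member set may have its parent inside it."""
    rng = random.Random(7)
    nodes = random_tree(rng, 60)
    tax = make_taxonomy(nodes)
    members = resolve_name(tax, "node-3").member_taxids
    for node in tax:
        if node.taxid not in members and not node.is_root:
            assert node.parent_taxid not in members


def test_generated_corpus_roundtrip(corpus):
    corpus_dir, manifest = corpus
    tax = load_taxonomy(corpus_dir / "names.dmp", corpus_dir / "nodes.dmp")
    assert len(tax) == len(manifest.taxa)
    by_id = {t["taxid"]: t for t in manifest.taxa}
    for node in tax:
        expected = by_id[node.taxid]
        assert node.scientific_name == expected["name"]
        assert node.parent_taxid == expected["parent"]
        assert node.rank == expected["rank"]
    genus = manifest.genera[0]
    ts = resolve_name(tax, genus["name"])
    species = [
        t
        for t in manifest.taxa
        if t["rank"] == "species" and t["taxid"] in ts.member_taxids
    ]
    expected_species = manifest.params["n_species"]
    assert len(species) == expected_species
    # synonym name class is also indexed
    assert (
        resolve_name(tax, f"{genus['name']} group").member_taxids
        == ts.member_taxids
    )
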