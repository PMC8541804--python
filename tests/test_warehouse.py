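"""Schema creation, taxon-filtered loading, statistics and FASTA export."""

import sqlite3

import pytest

import cladehouse as ch
from cladehouse import warehouse
from cladehouse.pipeline import load_taxonomy, parse_sources
from cladehouse.retrieval import grouped_paths, plan_downloads
from cladehouse.synthetic import write_config
from cladehouse.taxonomy import TaxonSet
from cladehouse.warehouse import (
    CORE_TABLES,
    ParsedCorpus,
    compute_stats,
    create_schema,
    export_cds_fasta,
    fk_sweep,
    load_corpus,
)


def fresh_conn() -> sqlite3.Connection:
    conn = sqlite3.connect(":memory:")
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def parse_corpus_dir(corpus_dir):
    taxonomy = load_taxonomy(corpus_dir / "names.dmp", corpus_dir / "nodes.dmp")
    taxa = taxonomy.resolve("Synthetica superclade")
    plan = plan_downloads(taxa, write_config(corpus_dir), corpus_dir)
    corpus, _ = parse_sources(grouped_paths(plan), taxonomy)
    return taxonomy, taxa, corpus


@pytest.fixture(scope="module")
def parsed(corpus):
    corpus_dir, manifest = corpus
    taxonomy, taxa, parsed_corpus = parse_corpus_dir(corpus_dir)
    return manifest, taxonomy, taxa, parsed_corpus


def test_schema_has_all_core_tables_and_active_fks():
    conn = fresh_conn()
    create_schema(conn)
    tables = {
        r[0]
        for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")
    }
    assert set(CORE_TABLES) <= tables
    assert len(CORE_TABLES) == 11
    with pytest.raises(sqlite3.IntegrityError):
        conn.execute(
            "INSERT INTO nucleotide_sequence (accession, oid, length)"
            " VALUES ('NC_1.1', 999, 10)"
        )


def test_create_schema_refuses_populated_store_without_overwrite():
    conn = fresh_conn()
    create_schema(conn)
    with pytest.raises(ch.SchemaError):
        create_schema(conn)
    create_schema(conn, overwrite=True)  # explicit overwrite rebuilds


def test_ddl_replay_is_deterministic():
    dumps = []
    for _ in range(2):
        conn = fresh_conn()
        create_schema(conn)
        dumps.append("\n".join(conn.iterdump()))
    assert dumps[0] == dumps[1]


def test_empty_warehouse_stats_are_all_zero():
    conn = fresh_conn()
    create_schema(conn)
    assert all(v == 0 for v in compute_stats(conn).as_dict().values())


def test_stats_on_missing_table_is_schema_error():
    conn = fresh_conn()
    with pytest.raises(ch.SchemaError):
        compute_stats(conn)


def test_full_load_matches_manifest_counts(parsed):
    manifest, _, taxa, corpus = parsed
    conn = fresh_conn()
    create_schema(conn)
    load_corpus(conn, taxa, corpus)
    assert compute_stats(conn).as_dict() == manifest.counts


def test_load_is_idempotent(parsed):
    manifest, _, taxa, corpus = parsed
    conn = fresh_conn()
    create_schema(conn)
    load_corpus(conn, taxa, corpus)
    first = compute_stats(conn).as_dict()
    report = load_corpus(conn, taxa, corpus)
    assert compute_stats(conn).as_dict() == first == manifest.counts
    assert report.inserted == {}  # second pass inserts nothing


def test_empty_taxon_set_loads_nothing(parsed):
    _, _, _, corpus = parsed
    conn = fresh_conn()
    create_schema(conn)
    empty = TaxonSet(query_name="nothing", root_taxids=(), member_taxids=frozenset())
    load_corpus(conn, empty, corpus)
    assert all(v == 0 for v in compute_stats(conn).as_dict().values())


def test_subclade_filter_excludes_other_genus(parsed):
    manifest, taxonomy, _, corpus = parsed
    genus = manifest.genera[0]
    taxa = taxonomy.resolve(genus["name"])
    conn = fresh_conn()
    create_schema(conn)
    load_corpus(conn, taxa, corpus)
    expected = manifest.stats_for(manifest.member_taxids_for(genus["taxid"]))
    assert compute_stats(conn).as_dict() == expected
    rows = conn.execute(
        "SELECT DISTINCT o.taxid FROM organism o"
        " JOIN nucleotide_sequence n ON n.oid = o.oid"
    ).fetchall()
    assert {r[0] for r in rows} <= taxa.member_taxids


def test_fk_sweep_clean_after_load(parsed):
    _, _, taxa, corpus = parsed
    conn = fresh_conn()
    create_schema(conn)
    load_corpus(conn, taxa, corpus)
    assert fk_sweep(conn) == []


def test_admitted_nucleotide_organism_flagged(parsed):
    _, taxonomy, _, corpus = parsed
    genus_taxa = taxonomy.resolve("Synthetica")
    other = [
        rec
        for rec in corpus.nucleotides
        if rec.taxid not in genus_taxa.member_taxids
    ]
    assert other, "fixture must contain records outside the sub-clade"
    conn = fresh_conn()
    create_schema(conn)
    sub = ParsedCorpus(taxonomy=taxonomy, nucleotides=other)
    report = load_corpus(conn, genus_taxa, sub, admit_nucleotide_organisms=True)
    stats = compute_stats(conn)
    assert stats.organisms_from_nucleotide == len({r.taxid for r in other})
    assert report.nucleotide_organisms_added == len(other)
    assert stats.genomes == len(other)


def test_structures_count_distinct_pdb_ids():
    conn = fresh_conn()
    create_schema(conn)
    conn.execute(
        "INSERT INTO organism (taxid, name, source) VALUES (1, 'x', 'taxonomy')"
    )
    oid = conn.execute("SELECT oid FROM organism").fetchone()[0]
    conn.execute(
        "INSERT INTO protein (uniprot_ac, oid, sequence) VALUES ('P00001', ?, 'M')",
        (oid,),
    )
    for chain, start in (("A", 1), ("B", 1), ("C", 10)):
        conn.execute(
            "INSERT INTO structure_chain (pdb_id, chain, uniprot_ac, sp_start, sp_stop)"
            " VALUES ('1abc', ?, 'P00001', ?, 50)",
            (chain, start),
        )
    assert compute_stats(conn).structures == 1


def test_conflicting_payload_on_same_natural_key_is_integrity_error(parsed):
    _, _, taxa, corpus = parsed
    conn = fresh_conn()
    create_schema(conn)
    load_corpus(conn, taxa, corpus)
    first = next(iter(corpus.proteins))
    clone = ParsedCorpus(
        taxonomy=corpus.taxonomy,
        proteins=[
            ch.ProteinRecord(
                primary_ac=first.primary_ac,
                entry_name=first.entry_name,
                taxid=first.taxid,
                sequence=first.sequence + "X",  # conflicting payload
                description=first.description,
            )
        ],
    )
    with pytest.raises(ch.IntegrityError):
        load_corpus(conn, taxa, clone)


def test_orphan_crossrefs_skipped_and_counted(parsed):
    _, taxonomy, taxa, corpus = parsed
    first = next(iter(corpus.proteins))
    orphan = ch.ProteinRecord(
        primary_ac="P99999",
        entry_name="ORPH_SYN",
        taxid=first.taxid,
        sequence="MKV",
        crossrefs=[
            ch.CrossReference("GO", "GO:7777777"),
            ch.CrossReference("Pfam", "PF77777"),
        ],
    )
    conn = fresh_conn()
    create_schema(conn)
    report = load_corpus(
        conn, taxa, ParsedCorpus(taxonomy=taxonomy, proteins=[orphan])
    )
    assert report.orphan_crossrefs == 2
    assert compute_stats(conn).go_terms == 0
    assert fk_sweep(conn) == []


@pytest.fixture(scope="module")
def loaded(parsed):
    manifest, _, taxa, corpus = parsed
    conn = fresh_conn()
    create_schema(conn)
    load_corpus(conn, taxa, corpus)
    return manifest, conn


def test_export_by_taxid_matches_manifest(loaded):
    manifest, conn = loaded
    prot = next(p for p in manifest.proteins if p["refseq"])
    taxid = prot["taxid"]
    expected = {
        p["refseq"][0] for p in manifest.proteins if p["taxid"] == taxid
    }
    fasta = "".join(export_cds_fasta(conn, f"taxid:{taxid}"))
    headers = [l for l in fasta.splitlines() if l.startswith(">")]
    assert len(headers) == len(expected)
    assert {h.split()[0][1:] for h in headers} == expected


def test_export_is_deterministic_and_ordered(loaded):
    manifest, conn = loaded
    taxid = manifest.proteins[0]["taxid"]
    first = "".join(export_cds_fasta(conn, f"taxid:{taxid}"))
    second = "".join(export_cds_fasta(conn, f"taxid:{taxid}"))
    assert first == second
    accs = [l.split()[0][1:] for l in first.splitlines() if l.startswith(">")]
    assert accs == sorted(accs)


def test_export_by_go_and_pfam_selectors(loaded):
    manifest, conn = loaded
    prot = next(p for p in manifest.proteins if p["go"])
    go_id = prot["go"][0]
    expected = {
        p["refseq"][0] for p in manifest.proteins if go_id in p["go"]
    }
    fasta = "".join(export_cds_fasta(conn, f"go:{go_id}"))
    assert fasta.count(">") == len(expected)
    prot = next(p for p in manifest.proteins if p["pfam"])
    pfam_ac = prot["pfam"][0]["ac"]
    expected = {
        p["refseq"][0]
        for p in manifest.proteins
        if pfam_ac in {l["ac"] for l in p["pfam"]}
    }
    assert "".join(export_cds_fasta(conn, f"pfam:{pfam_ac}")).count(">") == len(expected)


def test_export_no_match_is_empty_success(loaded):
    _, conn = loaded
    assert "".join(export_cds_fasta(conn, "taxid:1")) == ""


def test_export_bad_selector_lists_kinds(loaded):
    _, conn = loaded
    with pytest.raises(ch.SelectorError, match="taxid"):
        list(export_cds_fasta(conn, "go=123"))


def test_exported_sequences_are_the_spliced_cds(loaded):
    manifest, conn = loaded
    taxid = manifest.proteins[0]["taxid"]
    fasta = "".join(export_cds_fasta(conn, f"taxid:{taxid}"))
    blocks = [b for b in fasta.split(">") if b]
    for block in blocks:
        lines = block.splitlines()
        seq = "".join(lines[1:])
        assert set(seq) <= set("ACGT")
        assert len(seq) % 3 == 0
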