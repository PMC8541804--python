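"""The relational warehouse: schema, taxon-filtered load, statistics, export.

The store is an embedded SQLite database created from portable DDL
(``schema.sql``, shipped with the package) so that builds and tests need
no database service; the same DDL runs on a server-grade system.

Loading is organism-centred: a parsed record enters the warehouse only
if its taxon belongs to the resolved member set, and annotation entities
(GO terms, Pfam families, structure chains) are loaded lazily — only
when referenced by at least one retained protein.  Loads are idempotent:
re-running on the same inputs changes no row counts.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import IntegrityError, SchemaError, SelectorError
from .mappings import DomainFamily
from .ontology import GoOntology
from .records import (
    ChainMapping,
    DomainMapping,
    IsoformSequence,
    NucleotideRecord,
    ProteinRecord,
)
from .taxonomy import Taxonomy, TaxonSet

CORE_TABLES = (
    "organism",
    "nucleotide_sequence",
    "cds",
    "protein",
    "isoform",
    "go_term",
    "protein_go",
    "domain_family",
    "protein_domain",
    "structure_chain",
    "refseq_uniprot",
)
ALL_TABLES = CORE_TABLES + ("cds_segment",)

# (child table, child FK column, parent table, parent key column)
_FK_EDGES = (
    ("nucleotide_sequence", "oid", "organism", "oid"),
    ("cds", "nts_id", "nucleotide_sequence", "nts_id"),
    ("cds_segment", "cds_id", "cds", "cds_id"),
    ("protein", "oid", "organism", "oid"),
    ("isoform", "uniprot_ac", "protein", "uniprot_ac"),
    ("protein_go", "uniprot_ac", "protein", "uniprot_ac"),
    ("protein_go", "go_id", "go_term", "go_id"),
    ("protein_domain", "uniprot_ac", "protein", "uniprot_ac"),
    ("protein_domain", "pfam_ac", "domain_family", "pfam_ac"),
    ("structure_chain", "uniprot_ac", "protein", "uniprot_ac"),
    ("refseq_uniprot", "uniprot_ac", "protein", "uniprot_ac"),
)


def ddl() -> str:
    """The portable schema DDL shipped with the package."""
    return resources.files("cladehouse").joinpath("schema.sql").read_text()


def connect(db_path: str | Path) -> sqlite3.Connection:
    conn = sqlite3.connect(str(db_path))
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def _existing_tables(conn: sqlite3.Connection) -> set[str]:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type = 'table'"
    ).fetchall()
    return {r[0] for r in rows}


def create_schema(conn: sqlite3.Connection, overwrite: bool = False) -> None:
    """Create all tables, keys and indexes.

    Refuses to touch a store that already holds warehouse tables unless
    ``overwrite`` is set, in which case those tables are dropped first.
    """
    present = _existing_tables(conn) & set(ALL_TABLES)
    if present:
        if not overwrite:
            raise SchemaError(
                "store already holds warehouse tables "
                f"({', '.join(sorted(present))}); pass overwrite to rebuild"
            )
        conn.execute("PRAGMA foreign_keys = OFF")
        for table in reversed(ALL_TABLES):
            conn.execute(f"DROP TABLE IF EXISTS {table}")
        conn.execute("PRAGMA foreign_keys = ON")
    conn.executescript(ddl())
    conn.commit()


@dataclass
class WarehouseStats:
    """Per-entity row counts, mirroring the warehouse's statistics report."""

    organisms_from_taxonomy: int = 0
    organisms_from_nucleotide: int = 0
    genomes: int = 0
    cds: int = 0
    proteins: int = 0
    isoforms: int = 0
    go_terms: int = 0
    domain_families: int = 0
    structures: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))

    def report_text(self) -> str:
        lines = [
            "No of organisms",
            f"    From Taxonomy                  {self.organisms_from_taxonomy}",
            f"    From Nucleotide                {self.organisms_from_nucleotide}",
            f"No of curated genomes/chromosomes  {self.genomes}",
            f"No of CDSs                         {self.cds}",
            f"No of proteins                     {self.proteins}",
            f"No of protein isoforms             {self.isoforms}",
            f"No of GO terms                     {self.go_terms}",
            f"No of protein domain families      {self.domain_families}",
            f"No of protein 3D structures        {self.structures}",
        ]
        return "\n".join(lines)


@dataclass
class ParsedCorpus:
    """Bundle of parser outputs handed to the loader."""

    taxonomy: Taxonomy
    nucleotides: Iterable[NucleotideRecord] = ()
    proteins: Iterable[ProteinRecord] = ()
    isoforms: Iterable[IsoformSequence] = ()
    ontology: GoOntology = field(default_factory=lambda: GoOntology({}, {}))
    families: Iterable[DomainFamily] = ()
    chain_mappings: Iterable[ChainMapping] = ()
    domain_mappings: Iterable[DomainMapping] = ()


@dataclass
class LoadReport:
    inserted: dict[str, int] = field(default_factory=dict)
    nucleotide_records_skipped: int = 0
    proteins_skipped: int = 0
    isoforms_skipped: int = 0
    orphan_crossrefs: int = 0
    nucleotide_organisms_added: int = 0
    messages: list[str] = field(default_factory=list)

    def count(self, table: str, n: int = 1) -> None:
        self.inserted[table] = self.inserted.get(table, 0) + n


def _ensure_row(
    conn: sqlite3.Connection,
    table: str,
    key: dict[str, object],
    payload: dict[str, object],
    report: LoadReport,
) -> int | None:
    """Insert a row unless an identical one exists; conflicting payload errors.

    Returns the rowid of a newly inserted row, or None when the row was
    already present (idempotent re-load).
    """
    where = " AND ".join(f"{k} IS ?" for k in key)
    select_cols = list(payload) or list(key)
    row = conn.execute(
        f"SELECT {', '.join(select_cols)} FROM {table} WHERE {where}",
        tuple(key.values()),
    ).fetchone()
    if row is not None:
        if payload and tuple(row) != tuple(payload.values()):
            raise IntegrityError(
                f"{table}: key {key} already present with conflicting payload"
            )
        return None
    cols = {**key, **payload}
    placeholders = ", ".join("?" for _ in cols)
    cur = conn.execute(
        f"INSERT INTO {table} ({', '.join(cols)}) VALUES ({placeholders})",
        tuple(cols.values()),
    )
    report.count(table)
    return cur.lastrowid


def load_corpus(
    conn: sqlite3.Connection,
    taxa: TaxonSet,
    corpus: ParsedCorpus,
    admit_nucleotide_organisms: bool = False,
) -> LoadReport:
    """Load parsed records restricted to ``taxa.member_taxids``.

    With ``admit_nucleotide_organisms`` a nucleotide record whose taxid is
    outside the resolved set is still loaded and its organism row flagged
    ``source='nucleotide'`` (an organism discovered only in nucleotide
    data); by default such records are skipped and counted.
    """
    report = LoadReport()
    taxonomy = corpus.taxonomy
    oid_by_taxid: dict[int, int] = {}

    def organism_oid(taxid: int, source: str) -> int:
        if taxid in oid_by_taxid:
            return oid_by_taxid[taxid]
        node = taxonomy.nodes.get(taxid)
        name = node.scientific_name if node else f"taxid:{taxid}"
        rank = node.rank if node else None
        rowid = _ensure_row(
            conn,
            "organism",
            {"taxid": taxid},
            {"name": name, "rank": rank, "source": source},
            report,
        )
        if rowid is None:
            rowid = conn.execute(
                "SELECT oid FROM organism WHERE taxid = ?", (taxid,)
            ).fetchone()[0]
        oid_by_taxid[taxid] = rowid
        return rowid

    for taxid in sorted(taxa.member_taxids):
        organism_oid(taxid, "taxonomy")

    for rec in corpus.nucleotides:
        if rec.taxid in taxa.member_taxids:
            oid = organism_oid(rec.taxid, "taxonomy")
        elif admit_nucleotide_organisms:
            oid = organism_oid(rec.taxid, "nucleotide")
            report.nucleotide_organisms_added += 1
        else:
            report.nucleotide_records_skipped += 1
            continue
        nts_id = _ensure_row(
            conn,
            "nucleotide_sequence",
            {"accession": rec.accession},
            {
                "oid": oid,
                "length": rec.sequence_length,
                "molecule": rec.molecule_label,
                "definition": rec.definition,
            },
            report,
        )
        if nts_id is None:  # re-load: CDS rows below are also already present
            nts_id = conn.execute(
                "SELECT nts_id FROM nucleotide_sequence WHERE accession = ?",
                (rec.accession,),
            ).fetchone()[0]
        for cds in rec.cds_features:
            loc = cds.location
            existing = conn.execute(
                "SELECT cds_id FROM cds WHERE nts_id = ? AND start = ? AND stop = ?"
                " AND strand = ? AND refseq_protein_ac IS ? AND locus_tag IS ?",
                (nts_id, loc.start, loc.stop, loc.strand, cds.refseq_protein_ac, cds.locus_tag),
            ).fetchone()
            if existing is not None:
                continue
            cur = conn.execute(
                "INSERT INTO cds (nts_id, start, stop, strand, gene, locus_tag,"
                " refseq_protein_ac, product, translation, nt_sequence)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    nts_id,
                    loc.start,
                    loc.stop,
                    loc.strand,
                    cds.gene_name,
                    cds.locus_tag,
                    cds.refseq_protein_ac,
                    cds.product,
                    cds.translation,
                    cds.nt_sequence,
                ),
            )
            report.count("cds")
            cds_id = cur.lastrowid
            for ordinal, (start, stop) in enumerate(loc.segments, start=1):
                conn.execute(
                    "INSERT INTO cds_segment (cds_id, ordinal, start, stop)"
                    " VALUES (?, ?, ?, ?)",
                    (cds_id, ordinal, start, stop),
                )
                report.count("cds_segment")

    retained: dict[str, ProteinRecord] = {}
    for prot in corpus.proteins:
        if prot.taxid not in taxa.member_taxids:
            report.proteins_skipped += 1
            continue
        oid = organism_oid(prot.taxid, "taxonomy")
        _ensure_row(
            conn,
            "protein",
            {"uniprot_ac": prot.primary_ac},
            {
                "oid": oid,
                "entry_name": prot.entry_name,
                "name": prot.description,
                "sequence": prot.sequence,
            },
            report,
        )
        retained[prot.primary_ac] = prot

    for iso in corpus.isoforms:
        if iso.parent_ac not in retained:
            report.isoforms_skipped += 1
            continue
        _ensure_row(
            conn,
            "isoform",
            {"isoform_ac": iso.isoform_ac},
            {"uniprot_ac": iso.parent_ac, "sequence": iso.sequence},
            report,
        )

    ontology = corpus.ontology
    for ac, prot in retained.items():
        for xref in prot.crossrefs_to("GO"):
            canonical = ontology.canonical(xref.target_id)
            if canonical is None:
                report.orphan_crossrefs += 1
                report.messages.append(f"{ac}: unknown GO id {xref.target_id}")
                continue
            term = ontology.terms[canonical]
            _ensure_row(
                conn,
                "go_term",
                {"go_id": term.go_id},
                {
                    "name": term.name,
                    "namespace": term.namespace,
                    "obsolete": int(term.obsolete),
                },
                report,
            )
            _ensure_row(
                conn,
                "protein_go",
                {"uniprot_ac": ac, "go_id": term.go_id},
                {},
                report,
            )

    families = {f.pfam_ac: f for f in corpus.families}
    # Pfam placements: SIFTS coordinates win over bare DR references.
    placements: dict[tuple[str, str], tuple[int | None, int | None]] = {}
    for ac, prot in retained.items():
        for xref in prot.crossrefs_to("Pfam"):
            placements.setdefault((ac, xref.target_id), (None, None))
    for dom in corpus.domain_mappings:
        if dom.uniprot_ac in retained:
            placements[(dom.uniprot_ac, dom.pfam_ac)] = (dom.sp_start, dom.sp_stop)
    for (ac, pfam_ac), (sp_start, sp_stop) in sorted(placements.items()):
        family = families.get(pfam_ac)
        if family is None:
            report.orphan_crossrefs += 1
            report.messages.append(f"{ac}: unknown Pfam family {pfam_ac}")
            continue
        _ensure_row(
            conn,
            "domain_family",
            {"pfam_ac": pfam_ac},
            {"family_id": family.family_id, "description": family.description},
            report,
        )
        _ensure_row(
            conn,
            "protein_domain",
            {"uniprot_ac": ac, "pfam_ac": pfam_ac},
            {"sp_start": sp_start, "sp_stop": sp_stop},
            report,
        )

    for chain in corpus.chain_mappings:
        if chain.uniprot_ac not in retained:
            continue
        _ensure_row(
            conn,
            "structure_chain",
            {
                "pdb_id": chain.pdb_id,
                "chain": chain.chain_id,
                "uniprot_ac": chain.uniprot_ac,
                "sp_start": chain.sp_start,
            },
            {
                "sp_stop": chain.sp_stop,
                "pdb_start": chain.pdb_start,
                "pdb_stop": chain.pdb_stop,
            },
            report,
        )

    for ac, prot in retained.items():
        for xref in prot.crossrefs_to("RefSeq"):
            _ensure_row(
                conn,
                "refseq_uniprot",
                {"refseq_protein_ac": xref.target_id, "uniprot_ac": ac},
                {},
                report,
            )

    conn.commit()
    return report


def compute_stats(conn: sqlite3.Connection) -> WarehouseStats:
    """Exact per-entity row counts; structures count distinct PDB ids."""

    def one(sql: str) -> int:
        try:
            return conn.execute(sql).fetchone()[0]
        except sqlite3.DatabaseError as exc:
            raise SchemaError(f"not a readable warehouse: {exc}") from exc

    return WarehouseStats(
        organisms_from_taxonomy=one(
            "SELECT COUNT(*) FROM organism WHERE source = 'taxonomy'"
        ),
        organisms_from_nucleotide=one(
            "SELECT COUNT(*) FROM organism WHERE source = 'nucleotide'"
        ),
        genomes=one("SELECT COUNT(*) FROM nucleotide_sequence"),
        cds=one("SELECT COUNT(*) FROM cds"),
        proteins=one("SELECT COUNT(*) FROM protein"),
        isoforms=one("SELECT COUNT(*) FROM isoform"),
        go_terms=one("SELECT COUNT(*) FROM go_term"),
        domain_families=one("SELECT COUNT(*) FROM domain_family"),
        structures=one("SELECT COUNT(DISTINCT pdb_id) FROM structure_chain"),
    )


def fk_sweep(conn: sqlite3.Connection) -> list[tuple[str, str, object]]:
    """Independent referential-integrity sweep over every FK edge.

    Returns dangling references as (child_table, fk_column, value)
    triples; an empty list means full closure.  This re-derives what the
    declarative constraints should already guarantee.
    """
    dangling: list[tuple[str, str, object]] = []
    for child, fk_col, parent, parent_col in _FK_EDGES:
        rows = conn.execute(
            f"SELECT c.{fk_col} FROM {child} c"
            f" LEFT JOIN {parent} p ON p.{parent_col} = c.{fk_col}"
            f" WHERE c.{fk_col} IS NOT NULL AND p.{parent_col} IS NULL"
        ).fetchall()
        dangling.extend((child, fk_col, r[0]) for r in rows)
    return dangling


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def export_cds_fasta(conn: sqlite3.Connection, selector: str) -> Iterator[str]:
    """Yield FASTA records for CDSs whose linked protein matches ``selector``.

    Selector syntax: ``taxid:N``, ``go:GO:NNNNNNN`` or ``pfam:PFNNNNN``.
    The CDS→protein link goes through the refseq_uniprot mapping; output
    is ordered by RefSeq protein accession, so repeated exports are
    byte-identical.
    """
    kind, _, value = selector.partition(":")
    base = (
        "SELECT DISTINCT c.cds_id, c.refseq_protein_ac, c.gene, o.name,"
        " c.nt_sequence, c.translation"
        " FROM cds c"
        " JOIN refseq_uniprot ru ON ru.refseq_protein_ac = c.refseq_protein_ac"
        " JOIN protein p ON p.uniprot_ac = ru.uniprot_ac"
        " JOIN organism o ON o.oid = p.oid"
    )
    if kind == "taxid" and value.isdigit():
        sql, params = base + " WHERE o.taxid = ?", (int(value),)
    elif kind == "go" and value:
        sql, params = (
            base
            + " WHERE p.uniprot_ac IN (SELECT uniprot_ac FROM protein_go WHERE go_id = ?)",
            (value,),
        )
    elif kind == "pfam" and value:
        sql, params = (
            base
            + " WHERE p.uniprot_ac IN (SELECT uniprot_ac FROM protein_domain WHERE pfam_ac = ?)",
            (value,),
        )
    else:
        raise SelectorError(
            f"bad selector {selector!r}; expected taxid:N, go:GO:NNNNNNN or pfam:PFNNNNN"
        )
    sql += " ORDER BY c.refseq_protein_ac, c.cds_id"
    try:
        rows = conn.execute(sql, params).fetchall()
    except sqlite3.DatabaseError as exc:
        raise SchemaError(f"not a readable warehouse: {exc}") from exc
    for _cds_id, refseq_ac, gene, org_name, nt_seq, translation in rows:
        header_bits = [refseq_ac or "unknown"]
        if gene:
            header_bits.append(gene)
        header_bits.append(f"[{org_name}]")
        seq = nt_seq or translation or ""
        yield ">" + " ".join(header_bits) + "\n" + _wrap(seq) + "\n"
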