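"""End-to-end build: resolve → plan → fetch → parse → load → stats.

This is the library-level pipeline the CLI wraps; tests drive it
directly against generated fixture corpora.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from . import genbank, mappings, retrieval, swissprot, warehouse
from .errors import AcquisitionError, ConfigurationError
from .ontology import OboReport, parse_obo
from .retrieval import DownloadPlan, Transport, grouped_paths
from .taxonomy import Taxonomy, TaxonSet, parse_taxdump
from .warehouse import LoadReport, ParsedCorpus, WarehouseStats


@dataclass
class BuildResult:
    taxa: TaxonSet
    stats: WarehouseStats
    load_report: LoadReport
    parse_reports: dict[str, object] = field(default_factory=dict)


def load_taxonomy(names_path: Path, nodes_path: Path) -> Taxonomy:
    with open(names_path) as names, open(nodes_path) as nodes:
        return parse_taxdump(names, nodes)


def parse_sources(paths: dict[str, list[Path]], taxonomy: Taxonomy) -> tuple[ParsedCorpus, dict]:
    """Run every format reader over the fetched files."""
    reports: dict[str, object] = {
        "genbank": genbank.GenBankReport(),
        "swissprot": swissprot.SwissProtReport(),
        "varsplic": swissprot.VarsplicReport(),
        "obo": OboReport(),
        "sifts_uniprot": mappings.TsvReport(),
        "sifts_pfam": mappings.TsvReport(),
        "pfam": mappings.TsvReport(),
    }

    nucleotides = []
    for path in paths["nucleotide"]:
        with open(path) as handle:
            nucleotides.extend(genbank.parse_genbank(handle, reports["genbank"]))
    proteins = []
    for path in paths["swissprot"]:
        with open(path) as handle:
            proteins.extend(swissprot.parse_swissprot(handle, reports["swissprot"]))
    isoforms = []
    for path in paths["varsplic"]:
        with open(path) as handle:
            isoforms.extend(swissprot.parse_varsplic(handle, reports["varsplic"]))
    (obo_path,) = paths["go"]
    with open(obo_path) as handle:
        ontology = parse_obo(handle, reports["obo"])
    families = []
    for path in paths["pfam"]:
        with open(path) as handle:
            families.extend(mappings.parse_pfam_table(handle, reports["pfam"]))
    chain_mappings, domain_mappings = [], []
    for path in paths["sifts"]:
        mode = "pfam" if "pfam" in path.name else "uniprot"
        with open(path) as handle:
            parsed = list(
                mappings.parse_sifts_chain_tsv(
                    handle, mode, reports[f"sifts_{mode}"]
                )
            )
        if mode == "pfam":
            domain_mappings.extend(parsed)
        else:
            chain_mappings.extend(parsed)

    corpus = ParsedCorpus(
        taxonomy=taxonomy,
        nucleotides=nucleotides,
        proteins=proteins,
        isoforms=isoforms,
        ontology=ontology,
        families=families,
        chain_mappings=chain_mappings,
        domain_mappings=domain_mappings,
    )
    return corpus, reports


def run_build(
    config: dict,
    organism_query: str,
    db_path: str | Path,
    overwrite: bool = False,
    transport: Transport | None = None,
    work_dir: str | Path | None = None,
    admit_nucleotide_organisms: bool = False,
) -> BuildResult:
    """Build a warehouse for ``organism_query`` from the configured sources.

    Offline configurations (every source a local directory) need no
    transport at all; remote sources require one.  The taxonomy dump
    must be locally available or fetchable before name resolution, so it
    is acquired first, then the remaining sources.
    """
    db_path = Path(db_path)
    work_dir = Path(work_dir) if work_dir is not None else db_path.parent / "sources"

    taxonomy_location = (config.get("sources") or {}).get("taxonomy")
    if taxonomy_location is None:
        raise ConfigurationError("configuration missing source(s): taxonomy")

    # Stage 1: taxonomy (gates everything else).
    tax_dir = Path(taxonomy_location)
    if retrieval._is_remote(str(taxonomy_location)):
        if transport is None:
            raise ConfigurationError("remote taxonomy source but no transport")
        tax_dir = work_dir
        plan = DownloadPlan(
            items=[
                retrieval.PlanItem("taxonomy", name, work_dir / name)
                for name in retrieval.SOURCE_FILES["taxonomy"]
            ]
        )
        retrieval.fetch_with_retry(plan, transport)
    names_path, nodes_path = tax_dir / "names.dmp", tax_dir / "nodes.dmp"
    if not names_path.exists() or not nodes_path.exists():
        raise AcquisitionError(
            [p.name for p in (names_path, nodes_path) if not p.exists()]
        )
    taxonomy = load_taxonomy(names_path, nodes_path)
    taxa = taxonomy.resolve(organism_query)

    # Stage 2: everything else.
    plan = retrieval.plan_downloads(taxa, config, work_dir)
    if transport is None:
        transport = _refuse_transport
    retrieval.fetch_with_retry(plan, transport)
    paths = grouped_paths(plan)

    corpus, parse_reports = parse_sources(paths, taxonomy)

    conn = warehouse.connect(db_path)
    try:
        warehouse.create_schema(conn, overwrite=overwrite)
        load_report = warehouse.load_corpus(
            conn, taxa, corpus,
            admit_nucleotide_organisms=admit_nucleotide_organisms,
        )
        stats = warehouse.compute_stats(conn)
    finally:
        conn.close()
    return BuildResult(
        taxa=taxa, stats=stats, load_report=load_report, parse_reports=parse_reports
    )


def _refuse_transport(item, dest) -> None:
    raise AcquisitionError([item.local_name])
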