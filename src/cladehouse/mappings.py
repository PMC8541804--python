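"""Readers for SIFTS-style chain-mapping TSVs and the Pfam family table.

Two tab-separated layouts are understood, following the chain-level
SIFTS exports:

``uniprot`` mode (``pdb_chain_uniprot.tsv``-like)::

    PDB  CHAIN  SP_PRIMARY  RES_BEG  RES_END  PDB_BEG  PDB_END  SP_BEG  SP_END

``pfam`` mode (domain placements with Swiss-Prot coordinates)::

    PDB  CHAIN  SP_PRIMARY  PFAM_ID  SP_BEG  SP_END

Comment lines start with ``#``; one header row is tolerated.  PDB ids are
lower-cased on ingest; PDB residue labels stay opaque strings while
Swiss-Prot coordinates must be integers.  Malformed rows (wrong column
count, non-integer SP coordinates) are tallied and skipped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .records import ChainMapping, DomainFamily, DomainMapping

_UNIPROT_COLS = 9
_PFAM_COLS = 6


@dataclass
class TsvReport:
    rows_parsed: int = 0
    rows_rejected: int = 0
    messages: list[str] = field(default_factory=list)


def _data_rows(
    stream: Iterable[str], expected_cols: int, report: TsvReport
) -> Iterator[tuple[int, list[str]]]:
    header_seen = False
    for lineno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or (row[0].startswith("#")):
            continue
        if not header_seen:
            header_seen = True
            if not row[-1].strip().lstrip("-").isdigit():
                continue  # header row
        if len(row) != expected_cols:
            report.rows_rejected += 1
            report.messages.append(
                f"row {lineno}: expected {expected_cols} columns, got {len(row)}"
            )
            continue
        yield lineno, [f.strip() for f in row]


def parse_sifts_chain_tsv(
    stream: Iterable[str], mode: str, report: TsvReport | None = None
) -> Iterator[ChainMapping | DomainMapping]:
    """Yield one mapping per well-formed data row.

    ``mode`` is ``"uniprot"`` (→ :class:`ChainMapping`) or ``"pfam"``
    (→ :class:`DomainMapping`).  Rows for proteins outside the retained
    set are emitted regardless and filtered downstream.
    """
    if mode not in ("uniprot", "pfam"):
        raise ValueError(f"unknown SIFTS mode {mode!r}")
    report = report if report is not None else TsvReport()
    expected = _UNIPROT_COLS if mode == "uniprot" else _PFAM_COLS
    for lineno, row in _data_rows(stream, expected, report):
        try:
            if mode == "uniprot":
                pdb, chain, ac, _res_beg, _res_end, pdb_beg, pdb_end, sp_beg, sp_end = row
                mapping: ChainMapping | DomainMapping = ChainMapping(
                    pdb_id=pdb.lower(),
                    chain_id=chain,
                    uniprot_ac=ac,
                    sp_start=int(sp_beg),
                    sp_stop=int(sp_end),
                    pdb_start=pdb_beg,
                    pdb_stop=pdb_end,
                )
            else:
                pdb, chain, ac, pfam, sp_beg, sp_end = row
                mapping = DomainMapping(
                    uniprot_ac=ac,
                    pfam_ac=pfam,
                    sp_start=int(sp_beg),
                    sp_stop=int(sp_end),
                )
        except ValueError as exc:
            report.rows_rejected += 1
            report.messages.append(f"row {lineno}: {exc}")
            continue
        report.rows_parsed += 1
        yield mapping


def parse_pfam_table(
    stream: Iterable[str], report: TsvReport | None = None
) -> Iterator[DomainFamily]:
    """Yield Pfam family metadata from a 3-column TSV (accession, id, description)."""
    report = report if report is not None else TsvReport()
    for lineno, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or row[0].startswith("#") or row[0].lower() in ("pfam", "pfam_ac"):
            continue
        if len(row) < 2:
            report.rows_rejected += 1
            report.messages.append(f"row {lineno}: expected ≥2 columns")
            continue
        report.rows_parsed += 1
        yield DomainFamily(
            pfam_ac=row[0].strip(),
            family_id=row[1].strip(),
            description=row[2].strip() if len(row) > 2 else "",
        )
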