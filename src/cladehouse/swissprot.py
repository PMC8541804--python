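"""Readers for UniProtKB/Swiss-Prot DAT entries and the varsplic isoform FASTA.

Entry-level parsing is delegated to :mod:`Bio.SwissProt`; this module
adds the streaming/recovery layer (entries are isolated on the ``//``
terminator so one malformed entry cannot abort the file), restricts
cross-references to the four databases the warehouse links (RefSeq, GO,
Pfam, PDB), and pulls declared isoform accessions out of the
``ALTERNATIVE PRODUCTS`` comment block.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SwissProt

from .records import ISOFORM_AC_RE, CROSSREF_DBS, CrossReference, IsoformSequence, ProteinRecord

_ISOID_RE = re.compile(r"IsoId=([A-Z0-9]+-\d+)")
_ID_LINE_RE = re.compile(r"^ID\s+(\S+)")


@dataclass
class SwissProtReport:
    records_parsed: int = 0
    records_rejected: int = 0
    messages: list[str] = field(default_factory=list)


def _iter_entry_texts(stream: Iterable[str]) -> Iterator[str]:
    buf: list[str] = []
    for line in stream:
        buf.append(line if line.endswith("\n") else line + "\n")
        if line.startswith("//"):
            yield "".join(buf)
            buf = []
    if any(l.strip() for l in buf):
        yield "".join(buf) + "//\n"


def _record_from_entry(entry: SwissProt.Record) -> ProteinRecord:
    crossrefs: list[CrossReference] = []
    for dr in entry.cross_references:
        db = dr[0]
        if db in CROSSREF_DBS and len(dr) > 1 and dr[1]:
            crossrefs.append(
                CrossReference(
                    target_db=db, target_id=dr[1], qualifiers=tuple(dr[2:])
                )
            )
    isoform_ids: list[str] = []
    for comment in entry.comments:
        if comment.startswith("ALTERNATIVE PRODUCTS"):
            isoform_ids.extend(_ISOID_RE.findall(comment))
    return ProteinRecord(
        primary_ac=entry.accessions[0],
        secondary_acs=list(entry.accessions[1:]),
        entry_name=entry.entry_name,
        taxid=int(entry.taxonomy_id[0]),
        description=entry.description,
        sequence=entry.sequence,
        crossrefs=crossrefs,
        isoform_ids=isoform_ids,
    )


def parse_swissprot(
    stream: Iterable[str], report: SwissProtReport | None = None
) -> Iterator[ProteinRecord]:
    """Yield one :class:`ProteinRecord` per reviewed entry.

    An entry without AC, OX or SQ content is rejected and tallied with
    its entry name when the ID line is recoverable.
    """
    report = report if report is not None else SwissProtReport()
    for text in _iter_entry_texts(stream):
        try:
            entry = SwissProt.read(io.StringIO(text))
            if not entry.accessions or not entry.sequence or not entry.taxonomy_id:
                raise ValueError("entry lacks AC, SQ or OX content")
            record = _record_from_entry(entry)
        except Exception as exc:  # noqa: BLE001 - recovery boundary per entry
            report.records_rejected += 1
            m = _ID_LINE_RE.match(text)
            name = m.group(1) if m else "<unknown>"
            report.messages.append(f"entry {name} rejected: {exc}")
            continue
        report.records_parsed += 1
        yield record


@dataclass
class VarsplicReport:
    records_parsed: int = 0
    records_skipped: int = 0
    messages: list[str] = field(default_factory=list)


def parse_varsplic(
    stream, report: VarsplicReport | None = None
) -> Iterator[IsoformSequence]:
    """Yield isoform sequences from a UniProt varsplic-style FASTA.

    Headers must contain an accession of the form ``AC-n`` (either bare
    or in the ``sp|AC-n|NAME`` field layout); anything else is skipped
    with a counted warning.
    """
    from Bio import SeqIO

    report = report if report is not None else VarsplicReport()
    for rec in SeqIO.parse(stream, "fasta"):
        token = rec.id
        if "|" in token:
            parts = token.split("|")
            token = parts[1] if len(parts) > 1 else parts[0]
        m = ISOFORM_AC_RE.match(token)
        if not m:
            report.records_skipped += 1
            report.messages.append(f"header without isoform accession: {rec.id}")
            continue
        report.records_parsed += 1
        yield IsoformSequence(
            isoform_ac=token, parent_ac=m.group(1), sequence=str(rec.seq)
        )
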