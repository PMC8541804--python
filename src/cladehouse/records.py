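"""Typed records emitted by the source-format readers.

These are plain containers: validation that needs cross-file context
(taxon membership, referential closure) happens in the warehouse loader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .locations import GenomicLocation

UNIPROT_AC_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
ISOFORM_AC_RE = re.compile(r"^(\S+)-(\d+)$")
GO_ID_RE = re.compile(r"^GO:\d{7}$")
PFAM_AC_RE = re.compile(r"^PF\d{5}$")
REFSEQ_PREFIX_RE = re.compile(r"^[A-Z]{2}_")

CROSSREF_DBS = frozenset({"RefSeq", "GO", "Pfam", "PDB"})
GO_NAMESPACES = frozenset(
    {"biological_process", "molecular_function", "cellular_component"}
)


@dataclass(frozen=True)
class CrossReference:
    """One typed DR-line cross-reference of a Swiss-Prot entry."""

    target_db: str
    target_id: str
    qualifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target_db not in CROSSREF_DBS:
            raise ValueError(f"unsupported cross-reference database {self.target_db!r}")
        if not self.target_id:
            raise ValueError("empty cross-reference target id")


@dataclass
class CodingSequence:
    """One CDS feature of a nucleotide record."""

    location: GenomicLocation
    gene_name: str | None = None
    locus_tag: str | None = None
    refseq_protein_ac: str | None = None
    product: str | None = None
    translation: str | None = None
    nt_sequence: str | None = None  # spliced, reading-strand nucleotide sequence


@dataclass
class NucleotideRecord:
    """One RefSeq GenBank entry (genome, chromosome, plasmid or segment)."""

    accession: str
    taxid: int
    definition: str = ""
    sequence_length: int = 0
    molecule_label: str = ""
    cds_features: list[CodingSequence] = field(default_factory=list)


@dataclass
class ProteinRecord:
    """One reviewed UniProtKB (Swiss-Prot) entry."""

    primary_ac: str
    entry_name: str
    taxid: int
    sequence: str
    description: str = ""
    secondary_acs: list[str] = field(default_factory=list)
    crossrefs: list[CrossReference] = field(default_factory=list)
    isoform_ids: list[str] = field(default_factory=list)

    def crossrefs_to(self, db: str) -> list[CrossReference]:
        return [x for x in self.crossrefs if x.target_db == db]


@dataclass(frozen=True)
class IsoformSequence:
    """One alternative-splicing isoform sequence from the varsplic FASTA."""

    isoform_ac: str
    parent_ac: str
    sequence: str


@dataclass(frozen=True)
class GoTerm:
    go_id: str
    name: str
    namespace: str
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ChainMapping:
    """Residue-range alignment of one PDB chain onto a Swiss-Prot sequence.

    PDB residue labels stay opaque strings: author numbering may carry
    insertion codes or negatives.  Only the Swiss-Prot coordinates are
    validated as integers.
    """

    pdb_id: str
    chain_id: str
    uniprot_ac: str
    sp_start: int
    sp_stop: int
    pdb_start: str = ""
    pdb_stop: str = ""

    def __post_init__(self) -> None:
        if self.sp_start > self.sp_stop:
            raise ValueError(f"sp_start {self.sp_start} > sp_stop {self.sp_stop}")


@dataclass(frozen=True)
class DomainFamily:
    pfam_ac: str
    family_id: str = ""
    description: str = ""


@dataclass(frozen=True)
class DomainMapping:
    """Pfam domain placed on a Swiss-Prot sequence (SP coordinates)."""

    uniprot_ac: str
    pfam_ac: str
    sp_start: int
    sp_stop: int

    def __post_init__(self) -> None:
        if self.sp_start > self.sp_stop:
            raise ValueError(f"sp_start {self.sp_start} > sp_stop {self.sp_stop}")
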