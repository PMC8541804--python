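"""Synthetic seven-source corpus generator with a ground-truth manifest.

Generates, for a fictional clade, a mutually consistent miniature of
every input the pipeline consumes: taxdump (names.dmp/nodes.dmp), RefSeq
GenBank flat files, a Swiss-Prot DAT, a varsplic isoform FASTA, a GO OBO
document, a Pfam family table and the two SIFTS-style chain TSVs —
plus a JSON manifest recording exactly what was planted, so the whole
pipeline is testable offline against known expected counts.

Consistency guarantees: every DR RefSeq id is a protein_id of some CDS;
every SIFTS accession is a generated protein; every organism taxid is in
the taxdump; CDS translations are genuine 3:1 codon translations of the
spliced nucleotide spans (GenBank records are written through Biopython,
independently of the package's own flat-file reader).  Identifier
namespaces are fictional but format-valid (taxids in a reserved high
range, UniProt-pattern ACs, PF+5-digit, GO:+7-digit, RefSeq-prefixed
accessions) so the pattern validators are exercised for real.

Same seed + params → byte-identical corpus.
"""

from __future__ import annotations

import io
import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

ROOT_TAXID = 9_000_000
DEFECT_TAXID = 8_999_999  # outside the generated clade's taxdump

GENUS_NAMES = ("Synthetica", "Fabricatus", "Imaginarius", "Arteficia", "Simulatus")
EPITHETS = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta")

DEFECT_KINDS = (
    "truncated_entry",
    "bad_location",
    "wrong_column_count",
    "non_refseq_accession",
    "orphan_crossref",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


@dataclass(frozen=True)
class CorpusParams:
    """Shape of the generated clade and its annotation density.

    Defaults describe a small bacteria-like clade: a handful of species
    with one strain each, single-replicon genomes, most CDSs backed by a
    reviewed protein entry, and a modest annotation vocabulary.
    """

    n_genera: int = 1
    n_species: int = 3  # per genus
    strains_per_species: int = 1
    genomes_per_organism: int = 1
    cds_per_genome: int = 4
    proteins_linked_fraction: float = 0.8
    isoforms_per_protein_mean: float = 0.0
    go_terms_pool: int = 30
    pfam_pool: int = 12
    pdb_chain_fraction: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.n_genera <= len(GENUS_NAMES)):
            raise ValueError(f"n_genera must be in 1..{len(GENUS_NAMES)}")
        if not (1 <= self.n_species <= 50):
            raise ValueError("n_species must be in 1..50")
        if not (0 <= self.strains_per_species <= 10):
            raise ValueError("strains_per_species must be in 0..10")
        if not (1 <= self.genomes_per_organism <= 10):
            raise ValueError("genomes_per_organism must be in 1..10")
        if not (1 <= self.cds_per_genome <= 50):
            raise ValueError("cds_per_genome must be in 1..50")
        for name in ("proteins_linked_fraction", "pdb_chain_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.isoforms_per_protein_mean < 0:
            raise ValueError("isoforms_per_protein_mean must be >= 0")
        if not (1 <= self.go_terms_pool <= 5000):
            raise ValueError("go_terms_pool must be in 1..5000")
        if not (1 <= self.pfam_pool <= 5000):
            raise ValueError("pfam_pool must be in 1..5000")

    @classmethod
    def eukaryote_like(cls, seed: int = 0) -> "CorpusParams":
        """Alternative splicing present, richer annotation."""
        return cls(
            n_species=2,
            strains_per_species=0,
            cds_per_genome=6,
            isoforms_per_protein_mean=1.5,
            go_terms_pool=40,
            seed=seed,
        )

    @classmethod
    def prokaryote_like(cls, seed: int = 0) -> "CorpusParams":
        """No isoforms, strain-rich clade."""
        return cls(
            n_species=3,
            strains_per_species=2,
            isoforms_per_protein_mean=0.0,
            seed=seed,
        )

    @classmethod
    def virus_like(cls, seed: int = 0) -> "CorpusParams":
        """Tiny genomes, no isoforms, sparse structures."""
        return cls(
            n_species=2,
            strains_per_species=1,
            cds_per_genome=2,
            isoforms_per_protein_mean=0.0,
            go_terms_pool=8,
            pfam_pool=4,
            pdb_chain_fraction=0.25,
            seed=seed,
        )


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    threshold = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= threshold:
            return k
        k += 1


def _pdb_id(n: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz0123456789"
    s = ""
    m = n
    for _ in range(3):
        s = alphabet[m % 36] + s
        m //= 36
    return "1" + s


@dataclass
class CorpusManifest:
    """Ground truth for a generated corpus.

    ``stats_for`` recomputes expected warehouse counts for any taxid
    member set directly from the planted link lists, independently of
    both the parsers and the SQL path.
    """

    params: dict
    root_name: str
    genera: list[dict]  # {name, taxid}
    taxa: list[dict]  # {taxid, parent, rank, name}
    genomes: list[dict]  # {accession, taxid, length, n_cds}
    cds: list[dict]  # {protein_id, genome, taxid}
    proteins: list[dict]  # {ac, taxid, refseq, go, pfam, chains, isoforms}
    go_pool: list[dict]  # {id, namespace, obsolete, alt_ids}
    pfam_pool: list[dict]  # {ac, id}
    defects: dict = field(default_factory=dict)  # file -> {kind: count}

    def all_taxids(self) -> set[int]:
        return {t["taxid"] for t in self.taxa}

    def member_taxids_for(self, root_taxid: int) -> set[int]:
        """Subtree of ``root_taxid`` by naive parent-table recursion."""
        children: dict[int, list[int]] = {}
        for t in self.taxa:
            if t["taxid"] != t["parent"]:
                children.setdefault(t["parent"], []).append(t["taxid"])

        def walk(taxid: int) -> set[int]:
            out = {taxid}
            for child in children.get(taxid, ()):
                out |= walk(child)
            return out

        return walk(root_taxid)

    def stats_for(self, member_taxids: set[int]) -> dict[str, int]:
        genomes = [g for g in self.genomes if g["taxid"] in member_taxids]
        cds = [c for c in self.cds if c["taxid"] in member_taxids]
        prots = [p for p in self.proteins if p["taxid"] in member_taxids]
        go: set[str] = set()
        pfam: set[str] = set()
        pdb: set[str] = set()
        n_iso = 0
        for p in prots:
            go.update(p["go"])
            pfam.update(x["ac"] for x in p["pfam"])
            pdb.update(c["pdb"] for c in p["chains"])
            n_iso += len(p["isoforms"])
        return {
            "organisms_from_taxonomy": len(member_taxids),
            "organisms_from_nucleotide": 0,
            "genomes": len(genomes),
            "cds": len(cds),
            "proteins": len(prots),
            "isoforms": n_iso,
            "go_terms": len(go),
            "domain_families": len(pfam),
            "structures": len(pdb),
        }

    @property
    def counts(self) -> dict[str, int]:
        """Expected warehouse stats when the whole clade is queried."""
        return self.stats_for(self.all_taxids())

    def defect_count(self, kind: str) -> int:
        return sum(per_file.get(kind, 0) for per_file in self.defects.values())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "CorpusManifest":
        return cls(**json.loads(Path(path).read_text()))


def _normalise_defects(defect_spec) -> dict[str, int]:
    counts: dict[str, int] = {}
    for kind in defect_spec or ():
        if kind not in DEFECT_KINDS:
            raise ValueError(
                f"unknown defect kind {kind!r}; known: {', '.join(DEFECT_KINDS)}"
            )
        counts[kind] = counts.get(kind, 0) + 1
    return counts


class _Generator:
    def __init__(self, params: CorpusParams, defects: dict[str, int]):
        self.p = params
        self.defects = defects
        self.rng = random.Random(params.seed)
        self.taxa: list[dict] = []
        self.genera: list[dict] = []
        self.organisms: list[dict] = []  # taxid + name of genome-bearing taxa
        self.genomes: list[dict] = []
        self.cds: list[dict] = []  # manifest rows
        self._cds_detail: dict[str, dict] = {}  # protein_id -> {aa, taxid, genome}
        self.proteins: list[dict] = []
        self.go_pool: list[dict] = []
        self.pfam_pool: list[dict] = []
        self._gb_records: list[SeqRecord] = []
        self._taxid_counter = ROOT_TAXID
        self._acc_counter = 0
        self._prot_counter = 0
        self._locus_counter = 0
        self._pdb_counter = 0

    # -- identifier mints -------------------------------------------------
    def _next_taxid(self) -> int:
        self._taxid_counter += 1
        return self._taxid_counter

    def _next_genome_ac(self) -> str:
        self._acc_counter += 1
        return f"NC_9{self._acc_counter:06d}.1"

    def _next_protein_id(self) -> str:
        self._locus_counter += 1
        return f"WP_9{self._locus_counter:06d}.1"

    # -- taxonomy ---------------------------------------------------------
    def build_tree(self) -> None:
        root_name = "Synthetica superclade"
        self.taxa.append(
            {"taxid": ROOT_TAXID, "parent": ROOT_TAXID, "rank": "no rank",
             "name": root_name, "synonyms": []}
        )
        self.root_name = root_name
        for g in range(self.p.n_genera):
            genus_name = GENUS_NAMES[g]
            genus_id = self._next_taxid()
            self.taxa.append(
                {"taxid": genus_id, "parent": ROOT_TAXID, "rank": "genus",
                 "name": genus_name, "synonyms": [f"{genus_name} group"]}
            )
            self.genera.append({"name": genus_name, "taxid": genus_id})
            for s in range(self.p.n_species):
                epithet = EPITHETS[s % len(EPITHETS)] + (
                    str(s // len(EPITHETS) + 1) if s >= len(EPITHETS) else ""
                )
                sp_name = f"{genus_name} {epithet}"
                sp_id = self._next_taxid()
                self.taxa.append(
                    {"taxid": sp_id, "parent": genus_id, "rank": "species",
                     "name": sp_name, "synonyms": []}
                )
                self.organisms.append({"taxid": sp_id, "name": sp_name})
                for t in range(self.p.strains_per_species):
                    st_name = f"{sp_name} str. S{t + 1}"
                    st_id = self._next_taxid()
                    self.taxa.append(
                        {"taxid": st_id, "parent": sp_id, "rank": "strain",
                         "name": st_name, "synonyms": []}
                    )
                    self.organisms.append({"taxid": st_id, "name": st_name})

    # -- annotation pools -------------------------------------------------
    def build_pools(self) -> None:
        namespaces = ("biological_process", "molecular_function", "cellular_component")
        for i in range(self.p.go_terms_pool):
            obsolete = i % 7 == 6
            alt_ids = [f"GO:88{i:05d}"] if (not obsolete and i % 5 == 4) else []
            self.go_pool.append(
                {
                    "id": f"GO:9{i:06d}",
                    "name": f"synthetic process {i}",
                    "namespace": namespaces[i % 3],
                    "obsolete": obsolete,
                    "alt_ids": alt_ids,
                }
            )
        for i in range(self.p.pfam_pool):
            self.pfam_pool.append(
                {"ac": f"PF9{i:04d}", "id": f"Fam{i}",
                 "description": f"Synthetic domain family {i}"}
            )

    # -- genomes and CDSs -------------------------------------------------
    def build_genomes(self) -> None:
        rng = self.rng
        for org in self.organisms:
            for rep in range(self.p.genomes_per_organism):
                accession = self._next_genome_ac()
                seq_parts: list[str] = []
                features: list[SeqFeature] = []
                cursor = 0  # 0-based length so far
                n_cds = 0
                for _ in range(self.p.cds_per_genome):
                    cursor += rng.randint(10, 40)  # intergenic gap
                    seq_parts.append(self._random_nt(cursor - sum(map(len, seq_parts))))
                    aa_len = rng.randint(20, 50)
                    aa = "M" + "".join(rng.choice(_AA) for _ in range(aa_len - 1))
                    nt = "".join(_CODON[a] for a in aa) + _STOP
                    strand = -1 if rng.random() < 0.3 else 1
                    two_seg = rng.random() < 0.25
                    placed = nt if strand == 1 else str(Seq(nt).reverse_complement())
                    if two_seg:
                        cut = 3 * rng.randint(2, len(nt) // 3 - 2)
                        intron = rng.randint(5, 20)
                        s1 = (cursor, cursor + cut)  # 0-based half-open
                        s2 = (s1[1] + intron, s1[1] + intron + len(nt) - cut)
                        seq_parts.append(placed[:cut])
                        seq_parts.append(self._random_nt(intron))
                        seq_parts.append(placed[cut:])
                        cursor = s2[1]
                        parts = [
                            SimpleLocation(s1[0], s1[1], strand),
                            SimpleLocation(s2[0], s2[1], strand),
                        ]
                        if strand == -1:
                            parts.reverse()  # biological order; prints ascending
                        location = CompoundLocation(parts)
                    else:
                        location = SimpleLocation(cursor, cursor + len(nt), strand)
                        seq_parts.append(placed)
                        cursor += len(nt)
                    protein_id = self._next_protein_id()
                    gene = f"syn{self._locus_counter:04d}"
                    locus_tag = f"SYN_{self._locus_counter:05d}"
                    features.append(
                        SeqFeature(
                            location,
                            type="CDS",
                            qualifiers={
                                "gene": [gene],
                                "locus_tag": [locus_tag],
                                "protein_id": [protein_id],
                                "product": [f"synthetic protein {self._locus_counter}"],
                                "translation": [aa],
                            },
                        )
                    )
                    self.cds.append(
                        {"protein_id": protein_id, "genome": accession,
                         "taxid": org["taxid"]}
                    )
                    self._cds_detail[protein_id] = {
                        "aa": aa, "nt": nt, "taxid": org["taxid"],
                        "genome": accession, "gene": gene,
                    }
                    n_cds += 1
                cursor += rng.randint(10, 40)
                seq_parts.append(self._random_nt(cursor - sum(map(len, seq_parts))))
                genome_seq = "".join(seq_parts)
                record = SeqRecord(
                    Seq(genome_seq),
                    id=accession,
                    name=accession.split(".")[0],
                    description=f"{org['name']} chromosome {rep + 1}, complete sequence",
                )
                record.annotations.update(
                    molecule_type="DNA",
                    topology="linear",
                    data_file_division="SYN",
                    date="01-JAN-2020",
                )
                source = SeqFeature(
                    SimpleLocation(0, len(genome_seq), 1),
                    type="source",
                    qualifiers={
                        "organism": [org["name"]],
                        "mol_type": ["genomic DNA"],
                        "db_xref": [f"taxon:{org['taxid']}"],
                        "chromosome": [str(rep + 1)],
                    },
                )
                record.features = [source] + features
                self._gb_records.append(record)
                self.genomes.append(
                    {"accession": accession, "taxid": org["taxid"],
                     "length": len(genome_seq), "n_cds": n_cds}
                )

    def _random_nt(self, n: int) -> str:
        return "".join(self.rng.choice("ACGT") for _ in range(max(n, 0)))

    # -- proteins ---------------------------------------------------------
    def build_proteins(self) -> None:
        rng = self.rng
        by_org: dict[int, list[str]] = {}
        for c in self.cds:
            by_org.setdefault(c["taxid"], []).append(c["protein_id"])
        usable_go = [t for t in self.go_pool if not t["obsolete"]]
        for taxid in sorted(by_org):
            ids = by_org[taxid]
            n_prot = round(self.p.proteins_linked_fraction * len(ids))
            for protein_id in sorted(rng.sample(ids, n_prot)):
                detail = self._cds_detail[protein_id]
                self._prot_counter += 1
                ac = f"P9{self._prot_counter:04d}"
                aa = detail["aa"]
                n_go = rng.randint(1, min(4, len(usable_go)))
                go_terms = sorted(
                    t["id"] for t in rng.sample(usable_go, n_go)
                )
                n_pfam = rng.randint(0, min(2, len(self.pfam_pool)))
                pfam_links = []
                for fam in rng.sample(self.pfam_pool, n_pfam):
                    start = rng.randint(1, max(1, len(aa) - 10))
                    stop = rng.randint(start, len(aa))
                    pfam_links.append({"ac": fam["ac"], "start": start, "stop": stop})
                pfam_links.sort(key=lambda x: x["ac"])
                chains = []
                if rng.random() < self.p.pdb_chain_fraction:
                    pdb = _pdb_id(self._pdb_counter)
                    self._pdb_counter += 1
                    for chain_id in ("A", "B")[: rng.randint(1, 2)]:
                        start = rng.randint(1, max(1, len(aa) // 2))
                        stop = rng.randint(start, len(aa))
                        chains.append(
                            {"pdb": pdb, "chain": chain_id,
                             "sp_start": start, "sp_stop": stop}
                        )
                n_iso = _poisson(rng, self.p.isoforms_per_protein_mean)
                isoforms = []
                for k in range(n_iso):
                    cut = rng.randint(1, max(1, len(aa) - 5))
                    width = rng.randint(1, 4)
                    isoforms.append(
                        {"ac": f"{ac}-{k + 2}", "seq": aa[:cut] + aa[cut + width :]}
                    )
                self.proteins.append(
                    {
                        "ac": ac,
                        "taxid": taxid,
                        "entry_name": f"SY{self._prot_counter:04d}_SYN",
                        "gene": detail["gene"],
                        "refseq": [protein_id],
                        "genome": detail["genome"],
                        "go": go_terms,
                        "pfam": pfam_links,
                        "chains": chains,
                        "isoforms": [i["ac"] for i in isoforms],
                        "_iso_seqs": isoforms,
                        "_aa": aa,
                    }
                )

    # -- writers ----------------------------------------------------------
    def write_taxdump(self, out: Path) -> None:
        name_lines: list[str] = []
        node_lines: list[str] = []
        for t in self.taxa:
            node_lines.append(f"{t['taxid']}\t|\t{t['parent']}\t|\t{t['rank']}\t|")
            name_lines.append(
                f"{t['taxid']}\t|\t{t['name']}\t|\t\t|\tscientific name\t|"
            )
            for syn in t["synonyms"]:
                name_lines.append(f"{t['taxid']}\t|\t{syn}\t|\t\t|\tsynonym\t|")
        (out / "nodes.dmp").write_text("\n".join(node_lines) + "\n")
        (out / "names.dmp").write_text("\n".join(name_lines) + "\n")

    def write_genbank(self, out: Path) -> None:
        buf = io.StringIO()
        SeqIO.write(self._gb_records, buf, "genbank")
        text = buf.getvalue()
        per_file: dict[str, int] = {}
        extra: list[str] = []
        for i in range(self.defects.get("truncated_entry", 0)):
            extra.append(
                f"LOCUS       NT_DEF{i:03d}               100 bp    DNA     linear   SYN 01-JAN-2020\n"
                "DEFINITION  truncated synthetic defect entry.\n"
                "FEATURES             Location/Qualifiers\n"
                "     source          1..100\n"
                f'                     /db_xref="taxon:{DEFECT_TAXID}"\n'
                "//\n"
            )
            per_file["truncated_entry"] = per_file.get("truncated_entry", 0) + 1
        for i in range(self.defects.get("bad_location", 0)):
            extra.append(
                f"LOCUS       NC_89999{i:02d}               300 bp    DNA     linear   SYN 01-JAN-2020\n"
                "DEFINITION  synthetic defect entry with an inverted CDS span.\n"
                f"VERSION     NC_89999{i:02d}.1\n"
                "FEATURES             Location/Qualifiers\n"
                "     source          1..300\n"
                f'                     /db_xref="taxon:{DEFECT_TAXID}"\n'
                "     CDS             200..100\n"
                f'                     /protein_id="WP_89999{i:02d}.1"\n'
                "//\n"
            )
            per_file["bad_location"] = per_file.get("bad_location", 0) + 1
        for i in range(self.defects.get("non_refseq_accession", 0)):
            extra.append(
                f"LOCUS       AB1234{i:02d}               120 bp    DNA     linear   SYN 01-JAN-2020\n"
                "DEFINITION  synthetic defect entry with a non-RefSeq accession.\n"
                f"VERSION     AB1234{i:02d}.1\n"
                "FEATURES             Location/Qualifiers\n"
                "     source          1..120\n"
                f'                     /db_xref="taxon:{DEFECT_TAXID}"\n'
                "//\n"
            )
            per_file["non_refseq_accession"] = per_file.get("non_refseq_accession", 0) + 1
        (out / "genomes.gbff").write_text(text + "".join(extra))
        if per_file:
            self.manifest_defects["genomes.gbff"] = per_file

    def write_swissprot(self, out: Path) -> None:
        rng = self.rng
        alias_of = {
            t["id"]: t["alt_ids"][0] for t in self.go_pool if t["alt_ids"]
        }
        orphans_left = self.defects.get("orphan_crossref", 0)
        planted_orphans = 0
        lines: list[str] = []
        for p in self.proteins:
            aa = p["_aa"]
            lines.append(
                f"ID   {p['entry_name']:<19} Reviewed; {len(aa):>11} AA."
            )
            lines.append(f"AC   {p['ac']};")
            lines.append("DT   01-JAN-2020, integrated into UniProtKB/Swiss-Prot.")
            lines.append(f"DE   RecName: Full=Synthetic protein {p['gene']};")
            org = next(t for t in self.taxa if t["taxid"] == p["taxid"])
            lines.append(f"OS   {org['name']}.")
            lines.append("OC   Synthetica.")
            lines.append(f"OX   NCBI_TaxID={p['taxid']};")
            if p["isoforms"]:
                n_named = len(p["isoforms"]) + 1
                lines.append("CC   -!- ALTERNATIVE PRODUCTS:")
                lines.append(
                    f"CC       Event=Alternative splicing; Named isoforms={n_named};"
                )
                lines.append(f"CC       Name=1; IsoId={p['ac']}-1; Sequence=Displayed;")
                for k, iso_ac in enumerate(p["isoforms"], start=2):
                    lines.append(
                        f"CC       Name={k}; IsoId={iso_ac}; Sequence=VSP_{k:06d};"
                    )
            lines.append(
                f"DR   RefSeq; {p['refseq'][0]}; {p['genome']}."
            )
            for go_id in p["go"]:
                # occasionally cite the alt_id; consumers must canonicalise
                printed = go_id
                if go_id in alias_of and rng.random() < 0.3:
                    printed = alias_of[go_id]
                aspect = {"biological_process": "P", "molecular_function": "F",
                          "cellular_component": "C"}[
                    next(t["namespace"] for t in self.go_pool if t["id"] == go_id)
                ]
                lines.append(
                    f"DR   GO; {printed}; {aspect}:synthetic process; IEA:Synth."
                )
            if orphans_left > 0:
                lines.append("DR   GO; GO:7777777; P:unknown process; IEA:Synth.")
                orphans_left -= 1
                planted_orphans += 1
            for link in p["pfam"]:
                fam = next(f for f in self.pfam_pool if f["ac"] == link["ac"])
                lines.append(f"DR   Pfam; {link['ac']}; {fam['id']}; 1.")
            for ch in p["chains"]:
                lines.append(
                    f"DR   PDB; {ch['pdb'].upper()}; X-ray; 2.00 A; "
                    f"{ch['chain']}={ch['sp_start']}-{ch['sp_stop']}."
                )
            lines.append(
                f"SQ   SEQUENCE   {len(aa)} AA;  {len(aa) * 110} MW;"
                "  0000000000000000 CRC64;"
            )
            for i in range(0, len(aa), 60):
                lines.append("     " + aa[i : i + 60])
            lines.append("//")
        (out / "swissprot.dat").write_text("\n".join(lines) + "\n")
        if planted_orphans:
            self.manifest_defects["swissprot.dat"] = {
                "orphan_crossref": planted_orphans
            }

    def write_varsplic(self, out: Path) -> None:
        chunks: list[str] = []
        for p in self.proteins:
            for iso in p["_iso_seqs"]:
                ordinal = iso["ac"].rsplit("-", 1)[1]
                chunks.append(
                    f">sp|{iso['ac']}|{p['entry_name']} Isoform {ordinal} of "
                    f"Synthetic protein {p['gene']}\n"
                )
                seq = iso["seq"]
                for i in range(0, len(seq), 60):
                    chunks.append(seq[i : i + 60] + "\n")
        (out / "varsplic.fasta").write_text("".join(chunks))

    def write_obo(self, out: Path) -> None:
        lines = [
            "format-version: 1.2",
            "date: 01:01:2020 00:00",
            "ontology: go",
            "",
        ]
        for t in self.go_pool:
            lines.append("[Term]")
            lines.append(f"id: {t['id']}")
            lines.append(f"name: {t['name']}")
            lines.append(f"namespace: {t['namespace']}")
            for alt in t["alt_ids"]:
                lines.append(f"alt_id: {alt}")
            if t["obsolete"]:
                lines.append("is_obsolete: true")
            lines.append("")
        (out / "go.obo").write_text("\n".join(lines))

    def write_pfam(self, out: Path) -> None:
        lines = ["#pfam_ac\tfamily_id\tdescription"]
        for f in self.pfam_pool:
            lines.append(f"{f['ac']}\t{f['id']}\t{f['description']}")
        (out / "pfam_families.tsv").write_text("\n".join(lines) + "\n")

    def write_sifts(self, out: Path) -> None:
        uni = ["# 2020/07/01", "PDB\tCHAIN\tSP_PRIMARY\tRES_BEG\tRES_END\tPDB_BEG\tPDB_END\tSP_BEG\tSP_END"]
        pfam = ["# 2020/07/01", "PDB\tCHAIN\tSP_PRIMARY\tPFAM_ID\tSP_BEG\tSP_END"]
        for p in self.proteins:
            for ch in p["chains"]:
                n_res = ch["sp_stop"] - ch["sp_start"] + 1
                uni.append(
                    f"{ch['pdb']}\t{ch['chain']}\t{p['ac']}\t1\t{n_res}\t"
                    f"{ch['sp_start']}\t{ch['sp_stop']}\t{ch['sp_start']}\t{ch['sp_stop']}"
                )
            if p["chains"]:
                ch = p["chains"][0]
                for link in p["pfam"]:
                    pfam.append(
                        f"{ch['pdb']}\t{ch['chain']}\t{p['ac']}\t{link['ac']}\t"
                        f"{link['start']}\t{link['stop']}"
                    )
        bad = self.defects.get("wrong_column_count", 0)
        for i in range(bad):
            uni.append(f"1bad\tA\tP90000")
        (out / "pdb_chain_uniprot.tsv").write_text("\n".join(uni) + "\n")
        (out / "pdb_chain_pfam.tsv").write_text("\n".join(pfam) + "\n")
        if bad:
            self.manifest_defects["pdb_chain_uniprot.tsv"] = {
                "wrong_column_count": bad
            }

    # -- top level ---------------------------------------------------------
    def run(self, out: Path) -> CorpusManifest:
        self.manifest_defects: dict[str, dict[str, int]] = {}
        self.build_tree()
        self.build_pools()
        self.build_genomes()
        self.build_proteins()
        out.mkdir(parents=True, exist_ok=True)
        self.write_taxdump(out)
        self.write_genbank(out)
        self.write_swissprot(out)
        self.write_varsplic(out)
        self.write_obo(out)
        self.write_pfam(out)
        self.write_sifts(out)
        manifest = CorpusManifest(
            params=asdict(self.p),
            root_name=self.root_name,
            genera=self.genera,
            taxa=[{k: t[k] for k in ("taxid", "parent", "rank", "name")}
                  for t in self.taxa],
            genomes=self.genomes,
            cds=self.cds,
            proteins=[{k: v for k, v in p.items() if not k.startswith("_")}
                      for p in self.proteins],
            go_pool=self.go_pool,
            pfam_pool=self.pfam_pool,
            defects=self.manifest_defects,
        )
        manifest.save(out / "manifest.json")
        return manifest


def generate_corpus(
    params: CorpusParams, out: str | Path, defects=()
) -> CorpusManifest:
    """Write a complete seven-source corpus plus manifest into ``out``.

    ``defects`` is an optional list of defect kinds (repeats allowed)
    from :data:`DEFECT_KINDS`, planted to exercise parser error paths;
    parameters are validated before any file is written.
    """
    params.validate()
    defect_counts = _normalise_defects(defects)
    return _Generator(params, defect_counts).run(Path(out))


def plant_defects(
    params: CorpusParams, out: str | Path, defect_spec
) -> CorpusManifest:
    """Generate a corpus with planted malformed records (see ``DEFECT_KINDS``)."""
    return generate_corpus(params, out, defects=defect_spec)


def write_config(corpus_dir: str | Path, config_path: str | Path | None = None) -> dict:
    """Offline run configuration pointing every source at ``corpus_dir``."""
    import yaml

    corpus_dir = str(Path(corpus_dir).resolve())
    config = {
        "sources": {
            name: corpus_dir
            for name in (
                "taxonomy", "nucleotide", "swissprot", "varsplic",
                "go", "pfam", "sifts",
            )
        },
        "offline": True,
    }
    if config_path is not None:
        Path(config_path).write_text(yaml.safe_dump(config, sort_keys=True))
    return config
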