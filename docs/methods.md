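# Methods

## Data model

The warehouse models seven biological entities as relational tables:
organism, nucleotide sequence (genome/chromosome/plasmid), CDS, protein,
GO term, Pfam domain family, and PDB structure chain, plus the
association tables that connect them (protein↔GO, protein↔domain with
Swiss-Prot coordinates, RefSeq↔UniProt). Natural keys are used wherever
the source provides one (UniProt accession, GO id, Pfam accession,
versioned RefSeq accession, taxid); arbitrary surrogate keys (`oid`,
`nts_id`, `cds_id`) stand in where no biological attribute is unique.
Twelve tables exist in total: the eleven entity/association tables and
`cds_segment`, a child table that preserves the individual spans of
multi-segment CDS locations while the `cds` row stores the envelope
(minimum start, maximum stop) and a single `+`/`-` strand character.

The CDS↔protein relationship is deliberately indirect, through the
`refseq_uniprot` association derived from Swiss-Prot DR lines. Proteins
without a CDS link and CDSs without a protein link are both kept:
the entity counts of a real organism are never 1:1, and forcing
joinability would silently drop data. The association is what the CDS
FASTA export traverses.

## Pipeline and its assumptions

A build runs resolve → plan → fetch → parse → load → stats.

* **Resolution** matches the query name exactly (case-insensitively)
  against scientific names first, then synonym/common-name classes;
  substring matching is refused because it silently inflates the taxon
  set. Ambiguous names resolve to the union of all matched subtrees.
  The member set is closed under the child relation — strains below a
  queried species are included, with no cutoff rank.
* **Filtering** is strict by default: a nucleotide or protein record
  whose taxid is outside the member set is skipped and counted. The
  alternative behaviour — admitting such records and flagging their
  organisms `source='nucleotide'` (organisms discovered only in
  nucleotide data) — exists behind an explicit flag
  (`admit_nucleotide_organisms` / `--admit-nucleotide-organisms`),
  because it is only meaningful when the upstream retrieval, not the
  loader, did the taxon gating.
* **Lazy annotation loading**: GO terms and Pfam families enter the
  warehouse only when referenced by a retained protein, keeping the
  vocabulary organism-specific rather than mirroring whole ontologies.
* **Idempotence**: every insert checks for an existing row under the
  table's natural key; an identical row is skipped, a conflicting
  payload under the same key aborts with an integrity error. Re-running
  a load therefore changes no row count. CDS rows, which have no
  natural key, are deduplicated on the tuple (record, envelope, strand,
  protein id, locus tag).

## Format readers and numerical choices

* **GenBank** reading is a streaming line scanner (constant memory in
  the number of records) with per-file tallies: entries missing a LOCUS
  length, VERSION or source taxon are rejected individually, non-RefSeq
  accessions are rejected with a counted warning, and a CDS with an
  unparseable location is dropped from its record without losing the
  record. The spliced CDS nucleotide sequence is captured from ORIGIN
  at parse time (segments concatenated in printed order,
  reverse-complemented on the minus strand) because the FASTA export is
  impossible without it.
* **Location grammar** accepts base spans, single bases, `join`,
  `order` (parsed like join but flagged, since it asserts no
  contiguity), one level of `complement`, and `<`/`>` partiality
  markers. Nested `complement` and external references (`ACC:span`) are
  rejected — the latter with a distinct error kind so callers can count
  them as warnings rather than parse failures. Coordinates stay 1-based
  inclusive as printed; all downstream conversions are the consumer's
  job.
* **Swiss-Prot** entries are isolated on the `//` terminator and parsed
  with Biopython, so one malformed entry cannot abort a file.
  Cross-references are restricted to the four databases the warehouse
  links (RefSeq, GO, Pfam, PDB); DR sub-fields beyond the identifier
  are preserved verbatim as qualifier strings rather than interpreted.
  Isoform accessions are taken from the `ALTERNATIVE PRODUCTS` comment
  block; isoform sequences come from the varsplic FASTA, whose parent
  accession is the prefix before the dash ordinal.
* **OBO** terms are read through obonet with obsolete terms retained;
  `alt_id` values form an alias table that must resolve every alias to
  exactly one canonical term. DR GO annotations are canonicalised
  through this table before loading; an id unknown to the ontology is
  an orphan cross-reference, counted and skipped.
* **SIFTS TSVs** validate Swiss-Prot coordinates as integers and keep
  PDB residue labels as opaque strings; PDB ids are lower-cased on
  ingest. Pfam domain placements take SIFTS coordinates when present
  and fall back to a bare DR reference (null coordinates) otherwise.

## Acquisition

The seven sources are fetched through an injectable transport callable.
Each missing file is retried up to `max_attempts` (default 5 — retrying
"until complete" without a bound is unacceptable engineering); partial
files are discarded, never resumed, and completed files are never
overwritten. Completeness means presence with non-zero size for
transfers; files already present in a local (offline) source directory
satisfy their plan items with zero transport calls, which is what makes
the full pipeline runnable with no network at all. Remote nucleotide
retrieval is planned as batches of member taxids
(`nucleotide_batch_size`, default 50) so CDS extraction works on bounded
bins rather than whole genomes.

## The synthetic corpus generator

The generator emulates the *structure* of the real sources, not their
biology. What it reproduces faithfully: the file dialects (taxdump
field/terminator conventions, GenBank flat files written through
Biopython's own writer — deliberately independent of the package's
reader — DAT line codes, OBO stanzas, SIFTS-style TSV layouts);
format-valid identifiers in reserved fictional ranges; cross-file
referential closure; genuine codon translations (each CDS is the
back-translation of its protein plus a stop codon, spliced into the
genome across one or two segments on either strand); and the
kingdom-dependent isoform pattern (eukaryote-like profiles draw isoform
counts from a Poisson with positive mean, prokaryote/virus-like profiles
use mean 0). What it does not attempt: codon bias, realistic domain
architectures, genome-scale sizes, sequence homology. Passing tests
therefore demonstrate that parsing, filtering, loading and reporting are
correct and mutually consistent — not that the package has been
validated against live database snapshots.

Generator defaults (3 species × 1 strain, 1 genome per organism, 4 CDSs
per genome, 80% of CDSs protein-backed, 40% of proteins with a PDB
chain, pools of 30 GO terms and 12 Pfam families) describe a small
bacteria-like clade large enough to populate every table while keeping
a full build under a second. A `manifest.json` written next to the
corpus records every planted entity and link; `CorpusManifest.stats_for`
recomputes expected warehouse counts for any member set directly from
those link lists, independently of both the parsers and the SQL path —
this manifest-versus-warehouse equality is the central oracle of the
test suite. Defect planting (truncated entries, inverted location
spans, wrong column counts, non-RefSeq accessions, orphan
cross-references) exercises every parser error path; defective GenBank
entries carry a taxid outside the generated clade so they perturb
parser tallies without touching warehouse counts.

## Problem sizes used in validation

The test suite and the acceptance script work at deliberately small
scale, chosen so the full battery (20+ randomized corpus builds, 1,000
location expressions against a brute-force span-expansion oracle,
subtree resolution on 1,000-node random trees checked against naive
recursion for every root) completes in seconds: corpora of 1–2 genera,
1–3 species, 0–2 strains, 2–6 CDSs per genome. Correctness claims are
exact (count equality, set equality), not statistical, so scale adds
nothing to them.

## Known limitations

* The reference store is embedded SQLite; the DDL is portable and a
  server-grade deployment is expected to run it unchanged, but no live
  PostgreSQL round-trip is tested here.
* Merged/deleted taxid remapping (`merged.dmp`, `delnodes.dmp`) is not
  supported; queries resolve only against current nodes.
* Protein–GO links come from Swiss-Prot DR lines only, not from GO
  association files, so annotation coverage equals Swiss-Prot's.
* The PDB entity stores the structure id and chain mapping plus the
  verbatim DR qualifier strings; method and resolution are not parsed
  into typed columns.
* TrEMBL entries, mmCIF/PDB coordinate files and GO graph edges
  (`is_a`/`part_of`) are out of scope.
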