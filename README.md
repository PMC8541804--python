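# cladehouse

Organism-centred integration of seven public biological data sources into a
single relational warehouse.

Comparative-genomics and structural-biology studies routinely start with the
same tedious data-preparation step: for one organism (or a whole clade),
collect its taxonomy, its curated genome records and coding sequences (CDSs),
its reviewed protein entries and splice isoforms, its Gene Ontology
annotations, its Pfam domain families, and the residue-level mappings of its
proteins onto solved PDB structures — each from a different database, each in
a different format. `cladehouse` automates that step. Given a genus or
species name it:

1. resolves the name against the NCBI taxdump and expands it to the complete
   taxonomic subtree (species, subspecies, strains);
2. parses the seven source formats — taxdump `names.dmp`/`nodes.dmp`, RefSeq
   records in GenBank flat-file format, UniProtKB/Swiss-Prot DAT plus the
   varsplic isoform FASTA, GO in OBO 1.2, a Pfam family table, and
   SIFTS-style chain-level TSVs (PDB↔UniProt and PDB↔Pfam);
3. loads everything belonging to the resolved subtree into an embedded
   SQLite warehouse (portable DDL; the same schema runs on PostgreSQL),
   enforcing referential integrity and loading annotation vocabularies
   lazily — a GO term or Pfam family enters the warehouse only when a
   retained protein references it;
4. prints a per-entity statistics report and supports deterministic CDS
   FASTA export by taxon, GO term or Pfam family.

Only RefSeq accessions (two letters + underscore) are admitted to the
nucleotide table, which keeps the CDS set non-redundant — the property that
matters when comparing organisms within a clade. Coordinates are stored
1-based inclusive exactly as printed in the sources: CDS `start`/`stop` on
the nucleotide sequence (multi-segment locations keep their detail in a
child table), and `sp_start`/`sp_stop` versus `pdb_start`/`pdb_stop` for the
Swiss-Prot/PDB residue-range alignments. PDB residue labels stay opaque
strings because author numbering may carry insertion codes or negatives.

The package also ships a synthetic-corpus generator
(`cladehouse.synthetic`) that writes a mutually consistent miniature of all
seven sources for a fictional clade, together with a ground-truth manifest
of everything planted. That makes the entire pipeline testable offline, and
it is how the test suite and the acceptance script validate the warehouse:
build from a generated corpus, then require the statistics report to equal
the manifest exactly.

## Worked example

Generate a small single-genus corpus (three species, one strain each, some
alternative splicing) and build a warehouse for the genus:

```sh
python -c "
from cladehouse import CorpusParams, generate_corpus
from cladehouse.synthetic import write_config
generate_corpus(CorpusParams(n_genera=1, n_species=3, strains_per_species=1,
                             isoforms_per_protein_mean=0.5, seed=42), 'corpus')
write_config('corpus', 'config.yaml')
"
cladehouse build --organism Synthetica --config config.yaml --db warehouse.db --offline
```

which prints:

```
Query: Synthetica
No of organisms
    From Taxonomy                  7
    From Nucleotide                0
No of curated genomes/chromosomes  6
No of CDSs                         24
No of proteins                     18
No of protein isoforms             5
No of GO terms                     19
No of protein domain families      9
No of protein 3D structures        5
```

Reading the report: the genus query expanded to 7 taxa (1 genus + 3 species
+ 3 strains); the 6 organisms with genomes contributed one replicon each and
4 CDSs per replicon; 18 of the 24 CDSs are backed by a reviewed protein
entry (the generator's 0.8 linked fraction); 5 varsplic isoforms attach to
those proteins; and 19 GO terms, 9 Pfam families and 5 PDB structures are
referenced by at least one retained protein. `cladehouse stats warehouse.db`
re-prints the same report from the database, and

```sh
cladehouse export warehouse.db pfam:PF90001
```

writes the spliced nucleotide sequences of every CDS whose protein carries
domain family PF90001, e.g.

```
>WP_9000016.1 syn0016 [Synthetica beta str. S1]
ATGTTTTATGCTAAATTTTTTGTTAAAGGTGAAGCTTTTGCTAATATTTGGATGGCTGGT
...
```

Selectors are `taxid:N`, `go:GO:NNNNNNN` or `pfam:PFNNNNN`; output is
ordered by RefSeq protein accession so repeated exports are byte-identical.

Exit codes: 0 success, 2 usage, 3 organism not found, 4 acquisition or
configuration failure, 5 integrity/schema failure.

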