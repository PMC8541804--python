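-- Portable DDL for the organism-centred warehouse.
-- Surrogate keys (oid, nts_id, cds_id) are arbitrary integers; natural
-- keys (taxid, accession, uniprot_ac, go_id, pfam_ac) carry UNIQUE
-- constraints.  Runs unchanged on SQLite and PostgreSQL.

CREATE TABLE organism (
    oid     INTEGER PRIMARY KEY,
    taxid   INTEGER NOT NULL UNIQUE,
    name    TEXT    NOT NULL,
    rank    TEXT,
    source  TEXT    NOT NULL CHECK (source IN ('taxonomy', 'nucleotide'))
);

CREATE TABLE nucleotide_sequence (
    nts_id     INTEGER PRIMARY KEY,
    accession  TEXT    NOT NULL UNIQUE,
    oid        INTEGER NOT NULL REFERENCES organism (oid),
    length     INTEGER NOT NULL,
    molecule   TEXT,
    definition TEXT
);

CREATE TABLE cds (
    cds_id            INTEGER PRIMARY KEY,
    nts_id            INTEGER NOT NULL REFERENCES nucleotide_sequence (nts_id),
    start             INTEGER NOT NULL,
    stop              INTEGER NOT NULL,
    strand            TEXT    NOT NULL CHECK (strand IN ('+', '-')),
    gene              TEXT,
    locus_tag         TEXT,
    refseq_protein_ac TEXT,
    product           TEXT,
    translation       TEXT,
    nt_sequence       TEXT
);

CREATE TABLE cds_segment (
    cds_id  INTEGER NOT NULL REFERENCES cds (cds_id),
    ordinal INTEGER NOT NULL,
    start   INTEGER NOT NULL,
    stop    INTEGER NOT NULL,
    PRIMARY KEY (cds_id, ordinal)
);

CREATE TABLE protein (
    uniprot_ac TEXT    PRIMARY KEY,
    oid        INTEGER NOT NULL REFERENCES organism (oid),
    entry_name TEXT,
    name       TEXT,
    sequence   TEXT    NOT NULL
);

CREATE TABLE isoform (
    isoform_ac TEXT NOT NULL PRIMARY KEY,
    uniprot_ac TEXT NOT NULL REFERENCES protein (uniprot_ac),
    sequence   TEXT NOT NULL
);

CREATE TABLE go_term (
    go_id     TEXT    PRIMARY KEY,
    name      TEXT    NOT NULL,
    namespace TEXT    NOT NULL,
    obsolete  INTEGER NOT NULL DEFAULT 0
);

CREATE TABLE protein_go (
    uniprot_ac TEXT NOT NULL REFERENCES protein (uniprot_ac),
    go_id      TEXT NOT NULL REFERENCES go_term (go_id),
    PRIMARY KEY (uniprot_ac, go_id)
);

CREATE TABLE domain_family (
    pfam_ac     TEXT PRIMARY KEY,
    family_id   TEXT,
    description TEXT
);

CREATE TABLE protein_domain (
    uniprot_ac TEXT NOT NULL REFERENCES protein (uniprot_ac),
    pfam_ac    TEXT NOT NULL REFERENCES domain_family (pfam_ac),
    sp_start   INTEGER,
    sp_stop    INTEGER,
    PRIMARY KEY (uniprot_ac, pfam_ac)
);

CREATE TABLE structure_chain (
    pdb_id     TEXT    NOT NULL,
    chain      TEXT    NOT NULL,
    uniprot_ac TEXT    NOT NULL REFERENCES protein (uniprot_ac),
    sp_start   INTEGER NOT NULL,
    sp_stop    INTEGER NOT NULL,
    pdb_start  TEXT,
    pdb_stop   TEXT,
    PRIMARY KEY (pdb_id, chain, uniprot_ac, sp_start)
);

CREATE TABLE refseq_uniprot (
    refseq_protein_ac TEXT NOT NULL,
    uniprot_ac        TEXT NOT NULL REFERENCES protein (uniprot_ac),
    PRIMARY KEY (refseq_protein_ac, uniprot_ac)
);

CREATE INDEX idx_nucleotide_oid ON nucleotide_sequence (oid);
CREATE INDEX idx_cds_nts ON cds (nts_id);
CREATE INDEX idx_cds_refseq_ac ON cds (refseq_protein_ac);
CREATE INDEX idx_protein_oid ON protein (oid);
CREATE INDEX idx_refseq_uniprot_ac ON refseq_uniprot (uniprot_ac);
CREATE INDEX idx_structure_chain_ac ON structure_chain (uniprot_ac);
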