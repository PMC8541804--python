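"""Gene Ontology OBO 1.2 reader.

Term stanzas are read through :mod:`obonet` (obsolete terms included);
this module validates identifiers, normalises the obsolete flag, and
builds the alias table that maps every ``alt_id`` onto exactly one
canonical term — the property consumers rely on when resolving DR-line
annotations against the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import obonet

from .errors import IntegrityError
from .records import GO_ID_RE, GoTerm


@dataclass
class OboReport:
    terms_parsed: int = 0
    stanzas_rejected: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class GoOntology:
    """Parsed term set plus the alias → canonical id map."""

    terms: dict[str, GoTerm]
    aliases: dict[str, str]

    def canonical(self, go_id: str) -> str | None:
        """Canonical id for ``go_id`` (resolving alt_ids), or None if unknown."""
        if go_id in self.terms:
            return go_id
        return self.aliases.get(go_id)

    def __len__(self) -> int:
        return len(self.terms)


def parse_obo(stream, report: OboReport | None = None) -> GoOntology:
    """Parse an OBO 1.2 document into a :class:`GoOntology`.

    Stanzas whose id does not match ``GO:`` + 7 digits are rejected and
    tallied; an alt_id claimed by two canonical terms raises
    :class:`IntegrityError`.
    """
    report = report if report is not None else OboReport()
    graph = obonet.read_obo(stream, ignore_obsolete=False)
    terms: dict[str, GoTerm] = {}
    aliases: dict[str, str] = {}
    for node_id, data in graph.nodes(data=True):
        if not GO_ID_RE.match(str(node_id)) or "name" not in data:
            report.stanzas_rejected += 1
            report.messages.append(f"stanza rejected: {node_id!r}")
            continue
        term = GoTerm(
            go_id=node_id,
            name=data["name"],
            namespace=data.get("namespace", ""),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            alt_ids=tuple(data.get("alt_id", ())),
        )
        terms[term.go_id] = term
        report.terms_parsed += 1
    for term in terms.values():
        for alt in term.alt_ids:
            if alt in aliases and aliases[alt] != term.go_id:
                raise IntegrityError(
                    f"alt_id {alt} claimed by {aliases[alt]} and {term.go_id}"
                )
            if alt in terms:
                raise IntegrityError(f"alt_id {alt} collides with a canonical id")
            aliases[alt] = term.go_id
    return GoOntology(terms=terms, aliases=aliases)
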