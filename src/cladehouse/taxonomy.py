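"""NCBI taxdump parsing and subtree resolution.

The taxonomic tree gates everything downstream: a user names an organism
(genus or species), the name is resolved against ``names.dmp``, and the
complete subtree of the matched node(s) — species, subspecies, strains —
becomes the member set to which all later retrieval and loading is
restricted.

Dump dialect: fields separated by ``\\t|\\t``, records terminated by
``\\t|``.  The root node is its own parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import IntegrityError, OrganismNotFoundError, TaxdumpError

SCIENTIFIC_NAME_CLASS = "scientific name"


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str
    synonyms: tuple[str, ...] = ()

    @property
    def is_root(self) -> bool:
        return self.taxid == self.parent_taxid


@dataclass(frozen=True)
class TaxonSet:
    """Result of resolving a user query against a parsed taxonomy."""

    query_name: str
    root_taxids: tuple[int, ...]
    member_taxids: frozenset[int]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.member_taxids

    def __len__(self) -> int:
        return len(self.member_taxids)


def _split_dmp_line(line: str, lineno: int, min_fields: int) -> list[str]:
    body = line.rstrip("\n")
    if body.endswith("\t|"):
        body = body[: -len("\t|")]
    fields = body.split("\t|\t")
    if len(fields) < min_fields:
        raise TaxdumpError(
            f"expected at least {min_fields} fields, got {len(fields)}", line=lineno
        )
    return fields


class Taxonomy:
    """Parsed taxdump: node table plus name and child indexes."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        self.children: dict[int, list[int]] = {}
        self._by_name: dict[str, list[int]] = {}
        self._by_synonym: dict[str, list[int]] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise IntegrityError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise IntegrityError(
                    f"taxid {node.taxid} has unknown parent {node.parent_taxid}"
                )
            if not node.is_root:
                self.children.setdefault(node.parent_taxid, []).append(node.taxid)
            self._by_name.setdefault(node.scientific_name.casefold(), []).append(
                node.taxid
            )
            for syn in node.synonyms:
                self._by_synonym.setdefault(syn.casefold(), []).append(node.taxid)

    def __iter__(self) -> Iterator[TaxonNode]:
        return iter(self.nodes.values())

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, taxid: int) -> TaxonNode:
        return self.nodes[taxid]

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def descendants(self, root: int) -> set[int]:
        """Root plus all transitive children (iterative, safe on the self-parent root)."""
        if root not in self.nodes:
            raise KeyError(f"unknown taxid {root}")
        out: set[int] = set()
        stack = [root]
        while stack:
            taxid = stack.pop()
            if taxid in out:
                continue
            out.add(taxid)
            stack.extend(self.children.get(taxid, ()))
        return out

    def resolve(self, query: str) -> TaxonSet:
        """Resolve an organism name (exact, case-insensitive) to its subtree.

        Scientific names are matched first; synonym/common-name classes
        are consulted only when no scientific name matches.  Ambiguous
        names resolve to the union of all matched subtrees.
        """
        trimmed = query.strip()
        if not trimmed:
            raise ValueError("empty organism query")
        key = trimmed.casefold()
        roots = self._by_name.get(key) or self._by_synonym.get(key)
        if not roots:
            raise OrganismNotFoundError(trimmed)
        members: set[int] = set()
        for root in roots:
            members |= self.descendants(root)
        return TaxonSet(
            query_name=trimmed,
            root_taxids=tuple(roots),
            member_taxids=frozenset(members),
        )


def parse_taxdump(
    names_source: Iterable[str], nodes_source: Iterable[str]
) -> Taxonomy:
    """Join ``nodes.dmp`` and ``names.dmp`` line streams into a :class:`Taxonomy`.

    Every node must carry exactly one scientific-name record; other name
    classes are kept as synonyms for lookup.
    """
    sci_names: dict[int, str] = {}
    synonyms: dict[int, list[str]] = {}
    for lineno, line in enumerate(names_source, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, 4)
        try:
            taxid = int(fields[0])
        except ValueError:
            raise TaxdumpError(f"non-integer taxid {fields[0]!r}", line=lineno)
        name_txt, name_class = fields[1], fields[3]
        if name_class == SCIENTIFIC_NAME_CLASS:
            if taxid in sci_names:
                raise IntegrityError(
                    f"taxid {taxid} has more than one scientific name"
                )
            sci_names[taxid] = name_txt
        else:
            synonyms.setdefault(taxid, []).append(name_txt)

    nodes: list[TaxonNode] = []
    seen: set[int] = set()
    for lineno, line in enumerate(nodes_source, start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line, lineno, 3)
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError:
            raise TaxdumpError(f"non-integer taxid fields {fields[:2]}", line=lineno)
        if taxid in seen:
            raise IntegrityError(f"duplicate taxid {taxid}")
        seen.add(taxid)
        if taxid not in sci_names:
            raise TaxdumpError(
                f"taxid {taxid} has no scientific-name record", line=lineno
            )
        nodes.append(
            TaxonNode(
                taxid=taxid,
                parent_taxid=parent,
                rank=fields[2],
                scientific_name=sci_names[taxid],
                synonyms=tuple(synonyms.get(taxid, ())),
            )
        )
    return Taxonomy(nodes)


def resolve_name(nodes: Taxonomy, query: str) -> TaxonSet:
    """Functional wrapper over :meth:`Taxonomy.resolve`."""
    return nodes.resolve(query)


def descendant_taxa(nodes: Taxonomy, root: int) -> set[int]:
    """Functional wrapper over :meth:`Taxonomy.descendants`."""
    return nodes.descendants(root)
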