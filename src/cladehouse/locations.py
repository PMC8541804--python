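"""GenBank feature-location grammar.

The accepted subset of the flat-file location language covers the forms
that occur on curated RefSeq CDS features:

    469..1143
    complement(5..20)
    join(10..20,30..40)
    order(10..20,30..40)
    complement(join(2..10,20..28))
    <1..100, 200..>350          (5'/3' partiality markers)

Coordinates are kept 1-based inclusive exactly as printed.  ``complement``
flips the strand; segment coordinates stay as printed and consumers that
need the biological reading order reverse-complement the concatenation of
the printed segments.  ``order(...)`` is parsed like ``join`` but flagged,
since it asserts no contiguity.  External references (``ACC:span``) and
nested ``complement`` are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import LocationParseError

_SPAN_RE = re.compile(r"^(<?)(\d+)(?:\.\.(>?)(\d+))?$")


@dataclass(frozen=True)
class GenomicLocation:
    """Parsed feature location: ordered 1-based inclusive segments plus strand."""

    segments: tuple[tuple[int, int], ...]
    strand: str = "+"  # "+" forward, "-" reverse
    partial5: bool = False
    partial3: bool = False
    is_order: bool = False

    def __post_init__(self) -> None:
        if not self.segments:
            raise LocationParseError("location has no segments")
        for start, stop in self.segments:
            if start > stop:
                raise LocationParseError(
                    f"inverted span {start}..{stop}", kind="inverted_span"
                )

    @property
    def start(self) -> int:
        """Envelope start (minimum printed coordinate)."""
        return min(s for s, _ in self.segments)

    @property
    def stop(self) -> int:
        """Envelope stop (maximum printed coordinate)."""
        return max(e for _, e in self.segments)

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    def positions(self) -> set[int]:
        """Set of covered 1-based positions (strand-insensitive)."""
        out: set[int] = set()
        for s, e in self.segments:
            out.update(range(s, e + 1))
        return out


def _split_top_level(text: str) -> list[str]:
    parts, depth, cur = [], 0, []
    for ch in text:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise LocationParseError(f"unbalanced parentheses in {text!r}")
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if depth != 0:
        raise LocationParseError(f"unbalanced parentheses in {text!r}")
    parts.append("".join(cur))
    return parts


def _parse_span(text: str) -> tuple[tuple[int, int], bool, bool]:
    text = text.strip()
    if "complement" in text:
        raise LocationParseError(
            f"nested complement in {text!r}", kind="nested_complement"
        )
    if ":" in text:
        raise LocationParseError(
            f"external sequence reference {text!r}", kind="external_reference"
        )
    m = _SPAN_RE.match(text)
    if m is None:
        raise LocationParseError(f"unrecognised span {text!r}")
    p5, start, p3, stop = m.groups()
    if stop is None:  # single-base location "123"
        stop = start
        p3 = ""
    s, e = int(start), int(stop)
    if s > e:
        raise LocationParseError(f"inverted span {s}..{e}", kind="inverted_span")
    return (s, e), bool(p5), bool(p3)


def parse_location(text: str) -> GenomicLocation:
    """Parse a feature-location expression into a :class:`GenomicLocation`.

    Raises :class:`LocationParseError` for anything outside the grammar
    subset described in the module docstring.
    """
    expr = text.strip().replace(" ", "")
    if not expr:
        raise LocationParseError("empty location")

    strand = "+"
    if expr.startswith("complement(") and expr.endswith(")"):
        strand = "-"
        expr = expr[len("complement(") : -1]

    is_order = False
    if (expr.startswith("join(") or expr.startswith("order(")) and expr.endswith(")"):
        is_order = expr.startswith("order(")
        inner = expr[expr.index("(") + 1 : -1]
        span_texts = _split_top_level(inner)
    else:
        span_texts = [expr]

    segments: list[tuple[int, int]] = []
    partial5 = partial3 = False
    for st in span_texts:
        seg, p5, p3 = _parse_span(st)
        segments.append(seg)
        partial5 = partial5 or p5
        partial3 = partial3 or p3
    return GenomicLocation(
        segments=tuple(segments),
        strand=strand,
        partial5=partial5,
        partial3=partial3,
        is_order=is_order,
    )
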