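"""PROSITE-style motif grammar compiler and protein sequence scanner.

The grammars handled here are dash-separated element strings:

* a single residue letter (``L``) — a residue class of one;
* a bracket class (``[TS]``) — any listed residue;
* ``X`` — a one-residue wildcard gap;
* ``X(n)`` / ``X(n,m)`` — a fixed or variable wildcard gap.

A compiled :class:`MotifPattern` knows its span bounds (sum of per-element
minima and maxima) and is scanned against sequences with a small backtracking
matcher.  The subject's ``X`` (unknown residue) satisfies wildcard gaps but
never a residue class.  All match coordinates are 1-based inclusive, the
convention used for residue ranges throughout the package.

The shipped registry holds the module grammars of the microtubule inner
protein (MIP) families: the minimal Mn repeat unit ``[TS]-[TS]-X(4)-[YF]``
(a ~7-residue microtubule-binding helix), the NWE seam-binding motif
``[ILV]-L-I-G-N-W-X-E``, the divergent-Mn SNYG motif ``[ST]-N-X-X-[ILVY]-G``,
the long gapped ELLEn module grammar, and reconstructed PYG/GFG unit
signatures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

from ._alphabet import CANONICAL_SET

ScanMode = Literal["all-overlapping", "leftmost-nonoverlapping"]

#: registry keys, in the order the registry file lists them
REGISTRY_NAMES = ("MN_UNIT", "NWE", "SNYG", "ELLEN", "PYG", "GFG")


class PatternSyntaxError(ValueError):
    """Raised when a motif syntax string cannot be compiled."""


@dataclass(frozen=True)
class PatternElement:
    """One grammar element: a width-1 residue class or a wildcard gap."""

    kind: Literal["residue-class", "wildcard-gap"]
    allowed: frozenset[str] = frozenset()
    min_len: int = 1
    max_len: int = 1

    def __post_init__(self) -> None:
        if self.kind == "residue-class":
            if not self.allowed:
                raise PatternSyntaxError("residue class must be non-empty")
            if self.min_len != 1 or self.max_len != 1:
                raise PatternSyntaxError("residue-class elements have width 1")
        elif self.kind == "wildcard-gap":
            if self.min_len < 0 or self.min_len > self.max_len:
                raise PatternSyntaxError(
                    f"gap bounds must satisfy 0 <= min <= max, got ({self.min_len}, {self.max_len})"
                )
        else:  # pragma: no cover - dataclass guards
            raise PatternSyntaxError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif grammar with precomputed span bounds."""

    name: str
    syntax: str
    elements: tuple[PatternElement, ...]
    min_span: int = field(init=False)
    max_span: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "min_span", sum(e.min_len for e in self.elements))
        object.__setattr__(self, "max_span", sum(e.max_len for e in self.elements))


@dataclass(frozen=True)
class MotifMatch:
    """A located motif occurrence; start/end are 1-based inclusive."""

    sequence_id: str
    pattern_name: str
    start: int
    end: int
    matched_text: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_GAP_RE = re.compile(r"^X\((\d+)(?:,(\d+))?\)$")


def parse_pattern(syntax: str, name: str = "") -> MotifPattern:
    """Compile a dash-separated motif syntax string into a :class:`MotifPattern`."""
    if not syntax or not syntax.strip():
        raise PatternSyntaxError("empty pattern syntax")
    elements: list[PatternElement] = []
    for token in syntax.strip().split("-"):
        tok = token.strip()
        if not tok:
            raise PatternSyntaxError(f"empty token in syntax {syntax!r}")
        elements.append(_parse_token(tok, syntax))
    return MotifPattern(name=name or syntax, syntax=syntax, elements=tuple(elements))


def _parse_token(tok: str, syntax: str) -> PatternElement:
    if tok.startswith("["):
        if not tok.endswith("]"):
            raise PatternSyntaxError(f"unbalanced bracket in token {tok!r} of {syntax!r}")
        body = tok[1:-1]
        if not body:
            raise PatternSyntaxError(f"empty residue class in {syntax!r}")
        bad = set(body.upper()) - CANONICAL_SET
        if bad:
            raise PatternSyntaxError(
                f"non-canonical residue(s) {sorted(bad)} in class {tok!r} of {syntax!r}"
            )
        return PatternElement(kind="residue-class", allowed=frozenset(body.upper()))
    if tok == "X":
        return PatternElement(kind="wildcard-gap", min_len=1, max_len=1)
    if tok.startswith("X("):
        m = _GAP_RE.match(tok)
        if m is None:
            raise PatternSyntaxError(f"malformed gap token {tok!r} in {syntax!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if lo > hi:
            raise PatternSyntaxError(f"gap token {tok!r} has min > max in {syntax!r}")
        return PatternElement(kind="wildcard-gap", min_len=lo, max_len=hi)
    if len(tok) == 1 and tok.upper() in CANONICAL_SET:
        return PatternElement(kind="residue-class", allowed=frozenset(tok.upper()))
    raise PatternSyntaxError(f"unknown token {tok!r} in syntax {syntax!r}")


def span_bounds(pattern: MotifPattern) -> tuple[int, int]:
    """(min, max) match length in residues; idempotent on a compiled pattern."""
    return (pattern.min_span, pattern.max_span)


def _ends_from(seq: str, pos: int, elements: Sequence[PatternElement], idx: int):
    """Yield 0-based exclusive end offsets of matches starting at *pos*.

    Gap lengths are expanded shortest-first, so ends arrive in a deterministic
    order (not necessarily sorted across branches; callers dedupe/sort).
    """
    if idx == len(elements):
        yield pos
        return
    el = elements[idx]
    if el.kind == "residue-class":
        if pos < len(seq) and seq[pos] in el.allowed:
            yield from _ends_from(seq, pos + 1, elements, idx + 1)
    else:
        for k in range(el.min_len, el.max_len + 1):
            if pos + k > len(seq):
                break
            yield from _ends_from(seq, pos + k, elements, idx + 1)


def scan(
    sequence,
    pattern: MotifPattern,
    mode: ScanMode = "all-overlapping",
) -> list[MotifMatch]:
    """Find occurrences of *pattern* in *sequence*.

    ``all-overlapping`` reports, for every satisfying start position, every
    distinct end position reachable by some gap expansion (shortest expansion
    found first).  ``leftmost-nonoverlapping`` walks left to right, keeps the
    shortest match at each satisfying start, and resumes after its end.
    Output is sorted by start, then end.
    """
    seq = sequence.residues
    sid = sequence.id
    n = len(seq)
    matches: list[MotifMatch] = []
    if n == 0 or pattern.min_span == 0 or pattern.min_span > n:
        return matches

    if mode == "all-overlapping":
        for start in range(0, n - pattern.min_span + 1):
            ends = sorted(set(_ends_from(seq, start, pattern.elements, 0)))
            for end in ends:
                matches.append(
                    MotifMatch(sid, pattern.name, start + 1, end, seq[start:end])
                )
    elif mode == "leftmost-nonoverlapping":
        start = 0
        while start <= n - pattern.min_span:
            ends = list(_ends_from(seq, start, pattern.elements, 0))
            if ends:
                end = min(ends)
                matches.append(
                    MotifMatch(sid, pattern.name, start + 1, end, seq[start:end])
                )
                start = end
            else:
                start += 1
    else:
        raise ValueError(f"unknown scan mode {mode!r}")
    matches.sort(key=lambda m: (m.start, m.end))
    return matches


def load_registry() -> dict[str, MotifPattern]:
    """Load the shipped motif grammar registry (name -> compiled pattern)."""
    text = (resources.files("mipscan.data") / "motif_registry.tsv").read_text()
    registry: dict[str, MotifPattern] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        name, syntax = parts[0], parts[1]
        if name == "name":
            continue
        registry[name] = parse_pattern(syntax, name=name)
    return registry


def matches_to_rows(matches: Iterable[MotifMatch]) -> list[dict]:
    """Matches as plain dicts for TSV output."""
    return [
        {
            "sequence_id": m.sequence_id,
            "pattern_name": m.pattern_name,
            "start": m.start,
            "end": m.end,
            "matched_text": m.matched_text,
        }
        for m in matches
    ]


def matches_to_gff3(matches: Iterable[MotifMatch], source: str = "mipscan") -> str:
    """Matches as GFF3 (type ``motif_match``, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for m in matches:
        lines.append(
            "\t".join(
                [
                    m.sequence_id,
                    source,
                    "motif_match",
                    str(m.start),
                    str(m.end),
                    ".",
                    ".",
                    ".",
                    f"Name={m.pattern_name}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
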