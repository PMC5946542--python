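"""Domain types for annotated circular mitogenomes.

A :class:`GeneOrder` is a circular, strand-aware sequence of
:class:`GeneToken`.  Token names come from the closed vocabulary in
:mod:`mitorder.vocab`; duplicated names (two control regions, a duplicated
tRNA) are permitted and are distinguished only by position on the circle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from . import vocab

ANCHOR_PRIORITY = ("F", "12S")


@dataclass(frozen=True)
class GeneToken:
    """One annotated feature on the mitochondrial circle."""

    name: str
    category: str
    strand: int = 1
    length_bp: int | None = None

    def __post_init__(self) -> None:
        expected = vocab.category_of(self.name)  # raises on unknown names
        if self.category != expected:
            raise ValueError(
                f"token {self.name!r}: category {self.category!r} does not "
                f"match vocabulary category {expected!r}"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"token {self.name!r}: strand must be +1 or -1")
        if self.length_bp is not None and self.length_bp <= 0:
            raise ValueError(f"token {self.name!r}: length must be positive")
        if self.category == vocab.CATEGORY_NC and self.length_bp is None:
            raise ValueError("NC tokens must carry a length")

    @property
    def is_pseudo(self) -> bool:
        return self.category == vocab.CATEGORY_PSEUDO

    def __str__(self) -> str:
        return format_token(self)


def make_token(name: str, strand: int | None = None,
               length_bp: int | None = None) -> GeneToken:
    """Build a token with vocabulary-derived category and default strand."""
    if length_bp is None:
        length_bp = vocab.default_length(name)
    return GeneToken(
        name=name,
        category=vocab.category_of(name),
        strand=vocab.default_strand(name) if strand is None else strand,
        length_bp=length_bp,
    )


_TOKEN_RE = re.compile(
    r"^(?P<strand>-?)(?P<name>[A-Za-z0-9]+\*?)(?::(?P<len>\d+))?$"
)


def parse_token(text: str) -> GeneToken:
    """Parse one token of the gene-order dialect, e.g. ``-Q`` or ``CR:4110``.

    A leading ``-`` marks the light strand, a trailing ``*`` a pseudogene,
    and ``:N`` a length in bp.
    """
    m = _TOKEN_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed gene-order token: {text!r}")
    name = m.group("name")
    length = int(m.group("len")) if m.group("len") else None
    strand = -1 if m.group("strand") else 1
    tok_len = length if length is not None else vocab.default_length(name)
    return GeneToken(
        name=name, category=vocab.category_of(name),
        strand=strand, length_bp=tok_len,
    )


def format_token(tok: GeneToken, with_length: bool = False) -> str:
    s = ("-" if tok.strand == -1 else "") + tok.name
    if tok.length_bp is not None and (
        with_length or tok.category == vocab.CATEGORY_NC
    ):
        # NC lengths are part of the token invariant and always emitted
        s += f":{tok.length_bp}"
    return s


@dataclass(frozen=True)
class GeneOrder:
    """Circular, strand-aware ordered sequence of gene tokens."""

    tokens: tuple[GeneToken, ...]
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("a gene order must contain at least one token")
        names = {t.name for t in self.tokens}
        if not names & set(ANCHOR_PRIORITY):
            raise ValueError(
                "gene order lacks an anchor gene (tRNA-Phe or 12S rRNA)"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tokens)

    def rotate(self, k: int) -> "GeneOrder":
        n = len(self.tokens)
        k %= n
        return GeneOrder(self.tokens[k:] + self.tokens[:k], self.is_circular)

    def neighbors(self, index: int) -> tuple[GeneToken, GeneToken]:
        """Circular (5', 3') neighbours of the token at ``index``."""
        n = len(self.tokens)
        return self.tokens[(index - 1) % n], self.tokens[(index + 1) % n]

    def indices_of(self, name: str) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if t.name == name]

    def cr_lengths(self) -> list[int]:
        return [
            t.length_bp for t in self.tokens
            if t.category == vocab.CATEGORY_CR and t.length_bp is not None
        ]

    def count(self, name: str) -> int:
        return sum(1 for t in self.tokens if t.name == name)


def order_from_string(text: str) -> GeneOrder:
    """Parse a comma-separated token string into a gene order."""
    items = [s for s in (p.strip() for p in text.split(",")) if s]
    if not items:
        raise ValueError("empty gene-order string")
    return GeneOrder(tuple(parse_token(s) for s in items))


def order_to_string(order: GeneOrder, with_lengths: bool = False) -> str:
    return ",".join(format_token(t, with_length=with_lengths)
                    for t in order.tokens)


def linearize(order: GeneOrder, anchor: str | None = None) -> list[GeneToken]:
    """Deterministic linear form of a circular order.

    Rotates the circle so it starts at an occurrence of ``anchor``; when the
    anchor is duplicated the rotation giving the lexicographically smallest
    token-name sequence is chosen, so the result is unique.  Falls back from
    tRNA-Phe to 12S rRNA when no anchor is given.
    """
    if anchor is None:
        for cand in ANCHOR_PRIORITY:
            if order.indices_of(cand):
                anchor = cand
                break
    starts = order.indices_of(anchor) if anchor else []
    if not starts:
        raise ValueError(
            f"anchor {anchor!r} absent from order; try one of "
            f"{', '.join(ANCHOR_PRIORITY)}"
        )
    best = min(order.rotate(k).names() for k in starts)
    for k in starts:
        rot = order.rotate(k)
        if rot.names() == best:
            return list(rot.tokens)
    raise AssertionError("unreachable")


LOSS = "LOSS"
DUPLICATION = "DUPLICATION"
TRANSLOCATION = "TRANSLOCATION"
INSERTION = "INSERTION"
PSEUDOGENIZATION = "PSEUDOGENIZATION"
CR_ASYMMETRY = "CR_ASYMMETRY"
EVENT_KINDS = (
    LOSS, DUPLICATION, TRANSLOCATION, INSERTION, PSEUDOGENIZATION,
    CR_ASYMMETRY,
)


@dataclass(frozen=True)
class EventAnnotation:
    """One inferred rearrangement event with its locus context.

    ``from_context``/``to_context`` are (5', 3') neighbour-name pairs in the
    source and derived arrangement respectively; a translocation carries
    both, a loss only the source context, an insertion/duplication/
    pseudogenization only the target context.
    """

    kind: str
    subject: str
    from_context: tuple[str, str] | None = None
    to_context: tuple[str, str] | None = None
    length_bp: int | None = None
    edge: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == TRANSLOCATION and not (
            self.from_context and self.to_context
        ):
            raise ValueError("a translocation requires both contexts")
        if self.kind == LOSS and self.from_context is None:
            raise ValueError("a loss requires its source context")
        if self.kind in (INSERTION, DUPLICATION, PSEUDOGENIZATION) \
                and self.to_context is None:
            raise ValueError(f"a {self.kind.lower()} requires a target context")

    def placed(self, parent: str, child: str) -> "EventAnnotation":
        return replace(self, edge=(parent, child))

    def __str__(self) -> str:
        parts = [self.kind, self.subject]
        if self.from_context:
            parts.append(f"from({self.from_context[0]},{self.from_context[1]})")
        if self.to_context:
            parts.append(f"to({self.to_context[0]},{self.to_context[1]})")
        if self.length_bp:
            parts.append(f"{self.length_bp}bp")
        return " ".join(parts)


@dataclass
class MitogenomeRecord:
    """One annotated mitogenome: identity, provenance and gene order."""

    taxon_id: str
    species: str
    family: str
    order: GeneOrder
    genome_length_bp: int | None = None
    source: str = "parsed"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.source not in ("parsed", "fixture", "generated"):
            raise ValueError(f"unknown record source {self.source!r}")
        if self.genome_length_bp is not None and self.genome_length_bp <= 0:
            raise ValueError("genome length must be positive")

    def with_order(self, order: GeneOrder) -> "MitogenomeRecord":
        return replace(self, order=order)
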