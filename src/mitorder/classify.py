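"""Arrangement typing: canonical circular comparison and type assignment.

Two mitogenomes belong to the same arrangement type when they have the
same components in the same circular order — lengths are abstracted away,
with one deliberate exception: the III-E arrangement is token-identical to
Type III and differs only by its strongly asymmetric control regions, so
its registry entry carries a mandatory asymmetric-CR marker and records
with a Type III token order are promoted to III-E when their CR length
ratio exceeds the asymmetry threshold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from . import vocab
from .model import (
    CR_ASYMMETRY,
    DUPLICATION,
    EventAnnotation,
    GeneOrder,
    INSERTION,
    LOSS,
    MitogenomeRecord,
    PSEUDOGENIZATION,
    TRANSLOCATION,
    order_from_string,
)

logger = logging.getLogger(__name__)

#: CR length ratio (max/min) above which a pair of control regions is
#: called asymmetric; the one diagnostic printed ratio is 4110/2878 = 1.43,
#: concertedly evolving CR pairs sit near 1.0.
CR_ASYMMETRY_RATIO = 1.2

THE_ELEVEN = (
    "I", "II", "III", "III-A", "III-B", "III-B1", "III-C", "III-D",
    "III-E", "III-F", "III-G",
)


def _token_key(tok) -> str:
    name = "NC" if tok.category == vocab.CATEGORY_NC else tok.name
    return ("-" if tok.strand == -1 else "") + name


def canonical_key(order: GeneOrder, compare_lengths: bool = False) -> str:
    """Rotation-invariant string key for a circular arrangement.

    The lexicographically minimal rotation of the token string (name and
    strand; NC tokens reduced to the bare symbol unless
    ``compare_lengths``).  Equal keys <=> same circular arrangement.
    """
    if compare_lengths:
        parts = [
            _token_key(t) + (f":{t.length_bp}" if t.length_bp else "")
            for t in order.tokens
        ]
    else:
        parts = [_token_key(t) for t in order.tokens]
    n = len(parts)
    doubled = parts + parts
    best = min(tuple(doubled[k:k + n]) for k in range(n))
    return ",".join(best)


def same_arrangement(a: GeneOrder, b: GeneOrder) -> bool:
    """The identity rule: same components and circular order, lengths
    abstracted."""
    return canonical_key(a) == canonical_key(b)


def is_cr_asymmetric(order: GeneOrder,
                     ratio: float = CR_ASYMMETRY_RATIO) -> bool:
    lengths = order.cr_lengths()
    if len(lengths) < 2:
        return False
    return max(lengths) / min(lengths) > ratio


@dataclass
class ArrangementType:
    """A labeled reference arrangement plus its diagnostic event list."""

    label: str
    reference_order: GeneOrder
    description: str = ""
    diagnostic_events: list[EventAnnotation] = field(default_factory=list)
    requires_cr_asymmetry: bool = False
    parent_label: str | None = None

    def key(self) -> str:
        return canonical_key(self.reference_order)

    def matches(self, order: GeneOrder,
                ratio: float = CR_ASYMMETRY_RATIO) -> bool:
        if canonical_key(order) != self.key():
            return False
        if self.requires_cr_asymmetry:
            return is_cr_asymmetric(order, ratio)
        return True


class TypeRegistry:
    """Ordered collection of arrangement types plus the canonical baseline."""

    def __init__(self, types: list[ArrangementType],
                 canonical: GeneOrder | None = None,
                 ratio: float = CR_ASYMMETRY_RATIO):
        labels = [t.label for t in types]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate type labels in registry")
        self.types = list(types)
        self.canonical = canonical
        self.ratio = ratio
        self._new_labels: list[str] = []
        self._check_integrity()

    def _check_integrity(self) -> None:
        # at most one plain and one asymmetry-flagged type per canonical key
        seen: dict[tuple[str, bool], str] = {}
        for t in self.types:
            k = (t.key(), t.requires_cr_asymmetry)
            if k in seen:
                raise ValueError(
                    f"registry integrity: types {seen[k]!r} and {t.label!r} "
                    f"share a canonical key"
                )
            seen[k] = t.label

    def __iter__(self):
        return iter(self.types)

    def __len__(self) -> int:
        return len(self.types)

    def labels(self) -> list[str]:
        return [t.label for t in self.types]

    def get(self, label: str) -> ArrangementType:
        for t in self.types:
            if t.label == label:
                return t
        raise KeyError(label)

    def classify(self, record: MitogenomeRecord) -> str:
        """Label a record, minting a deterministic NEW-k label when no
        registry type matches; a record is never left unlabeled."""
        key = canonical_key(record.order)
        candidates = [t for t in self.types if t.key() == key]
        flagged = [t for t in candidates if t.requires_cr_asymmetry]
        plain = [t for t in candidates if not t.requires_cr_asymmetry]
        asym = is_cr_asymmetric(record.order, self.ratio)
        n_cr = sum(1 for t in record.order
                   if t.category == vocab.CATEGORY_CR)
        if n_cr >= 2 and len(record.order.cr_lengths()) < n_cr:
            logger.info("%s: CR lengths absent; asymmetry treated as false",
                        record.taxon_id)
        chosen: ArrangementType | None = None
        if asym and flagged:
            chosen = flagged[0]
        elif plain:
            chosen = plain[0]
        elif flagged and not asym:
            chosen = None  # needs asymmetry the record does not show
        if chosen is not None:
            return chosen.label
        # mint or reuse a NEW-k label for this unseen canonical key
        for i, k in enumerate(self._new_labels, start=1):
            if k == key:
                return f"NEW-{i}"
        self._new_labels.append(key)
        label = f"NEW-{len(self._new_labels)}"
        logger.info("novel arrangement %s: key=%s", label, key)
        return label


def classify_record(record: MitogenomeRecord,
                    registry: TypeRegistry) -> str:
    if len(registry) == 0:
        raise ValueError("cannot classify against an empty registry")
    return registry.classify(record)


def type_census(records: list[MitogenomeRecord],
                registry: TypeRegistry) -> tuple[pd.Series, int]:
    """Per-label record counts and the number of distinct types observed."""
    if not records:
        raise ValueError("type census requires at least one record")
    labels = [classify_record(r, registry) for r in records]
    counts = pd.Series(labels, name="count").value_counts().sort_index()
    return counts, int((counts >= 1).sum())


def novel_types(registry_now: TypeRegistry,
                registry_prior: TypeRegistry) -> list[str]:
    """Labels in the current registry with no arrangement-identical member
    of the prior registry.

    A type with a mandatory asymmetric-CR marker only matches a prior
    arrangement whose reference itself shows the asymmetry (III-E is not
    "already known" merely because its token order equals Type III).
    """
    novel = []
    for t in registry_now:
        known = False
        for p in registry_prior:
            if canonical_key(t.reference_order) != canonical_key(
                    p.reference_order):
                continue
            if t.requires_cr_asymmetry and not is_cr_asymmetric(
                    p.reference_order, registry_now.ratio):
                continue
            known = True
            break
        if not known:
            novel.append(t.label)
    return sorted(novel)


# --- built-in registries ---------------------------------------------------

#: diagnostic rearrangement events of each type relative to its parent in
#: the derivation graph (UNKNOWN ancestor for I, II, III).
DIAGNOSTIC_EVENTS: dict[str, tuple[str, list[EventAnnotation]]] = {
    "I": ("UNKNOWN", [
        EventAnnotation(LOSS, "OL", from_context=("N", "C")),
        EventAnnotation(TRANSLOCATION, "Q", from_context=("I", "M"),
                        to_context=("W", "A")),
    ]),
    "II": ("UNKNOWN", [
        EventAnnotation(LOSS, "OL", from_context=("N", "C")),
    ]),
    "III": ("UNKNOWN", [
        EventAnnotation(DUPLICATION, "CR", to_context=("I", "L2")),
        EventAnnotation(TRANSLOCATION, "L2", from_context=("16S", "ND1"),
                        to_context=("CR", "Q")),
    ]),
    "III-A": ("III", [
        EventAnnotation(TRANSLOCATION, "K", from_context=("COX2", "ATP8"),
                        to_context=("ATP8", "ATP6")),
    ]),
    "III-B": ("III", [
        EventAnnotation(TRANSLOCATION, "P", from_context=("T", "CR"),
                        to_context=("I", "CR")),
    ]),
    "III-B1": ("III-B", [
        EventAnnotation(PSEUDOGENIZATION, "P*", to_context=("T", "CR")),
    ]),
    "III-C": ("III", [
        EventAnnotation(PSEUDOGENIZATION, "P*", to_context=("I", "CR")),
    ]),
    "III-D": ("III", [
        EventAnnotation(DUPLICATION, "I", to_context=("P", "CR")),
    ]),
    "III-E": ("III", [
        EventAnnotation(CR_ASYMMETRY, "CR"),
    ]),
    "III-F": ("III", [
        EventAnnotation(INSERTION, "NC", to_context=("ND5", "ND6"),
                        length_bp=342),
        EventAnnotation(CR_ASYMMETRY, "CR"),
    ]),
    "III-G": ("III", [
        EventAnnotation(INSERTION, "NC", to_context=("C", "Y"),
                        length_bp=5702),
    ]),
}


def _load_registry_rows(filename: str):
    text = resources.files("mitorder.data").joinpath(filename).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


def _registry_from_rows(rows, with_events: bool,
                        ratio: float) -> TypeRegistry:
    types: list[ArrangementType] = []
    canonical = None
    for row in rows:
        order = order_from_string(row["order"])
        if row["role"] == "reference":
            canonical = order
            continue
        label = row["label"]
        parent, events = (None, [])
        if with_events and label in DIAGNOSTIC_EVENTS:
            parent, events = DIAGNOSTIC_EVENTS[label]
        types.append(ArrangementType(
            label=label,
            reference_order=order,
            description=row["description"],
            diagnostic_events=list(events),
            requires_cr_asymmetry=row["requires_cr_asymmetry"] == "1",
            parent_label=parent,
        ))
    return TypeRegistry(types, canonical=canonical, ratio=ratio)


def builtin_registry(ratio: float = CR_ASYMMETRY_RATIO) -> TypeRegistry:
    """The eleven snake arrangement types plus the canonical squamate
    baseline."""
    reg = _registry_from_rows(
        _load_registry_rows("arrangement_types.tsv"), True, ratio
    )
    if tuple(reg.labels()) != THE_ELEVEN:
        raise ValueError("built-in registry does not list the eleven types")
    if reg.canonical is None:
        raise ValueError("built-in registry lacks the canonical baseline")
    return reg


def prior_registry(ratio: float = CR_ASYMMETRY_RATIO) -> TypeRegistry:
    """The six previously reported snake arrangements."""
    return _registry_from_rows(
        _load_registry_rows("prior_arrangements.tsv"), False, ratio
    )
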