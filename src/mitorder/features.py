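"""Rule-based detectors for mitogenome rearrangement features.

Each detector scores one of the features used to diagnose snake
arrangement types: presence/absence of the light-strand replication origin
(OL), control-region count and length asymmetry, gene translocations
relative to a reference order, pseudogenes, duplicated functional genes,
and non-coding insertions.  ``hotspot_assignment`` maps a type's
diagnostic events onto the two rearrangement hotspots (the WANCY tRNA
cluster and the control regions with their flanking segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import vocab
from .model import CR_ASYMMETRY, EventAnnotation, GeneOrder, \
    MitogenomeRecord, linearize

#: members of the WANCY tRNA cluster (the light-strand replication origin
#: sits inside it in the typical order)
WANCY = frozenset({"W", "A", "N", "OL", "C", "Y"})

HOTSPOT_WANCY = "WANCY"
HOTSPOT_CR_FLANK = "CR-flank"
HOTSPOT_OTHER = "other"

CR_ASYMMETRY_RATIO = 1.2


def detect_ol(order: GeneOrder) -> tuple[bool, tuple[str, str] | None]:
    """OL presence and, when present, its circular neighbours."""
    idx = [i for i, t in enumerate(order)
           if t.category == vocab.CATEGORY_OL]
    if len(idx) > 1:
        raise ValueError("order integrity: more than one OL token")
    if not idx:
        return False, None
    left, right = order.neighbors(idx[0])
    return True, (left.name, right.name)


def count_control_regions(record: MitogenomeRecord,
                          ratio: float = CR_ASYMMETRY_RATIO,
                          ) -> tuple[int, list[int], bool]:
    """(cr_count, cr_lengths, cr_asymmetric); asymmetry = max/min > ratio."""
    order = record.order
    count = sum(1 for t in order if t.category == vocab.CATEGORY_CR)
    lengths = order.cr_lengths()
    asymmetric = (
        len(lengths) >= 2 and max(lengths) / min(lengths) > ratio
    )
    return count, lengths, asymmetric


def _anchored_names(order: GeneOrder) -> list[str]:
    return [t.name for t in linearize(order)]


def _occurrence_labels(names: list[str]) -> list[tuple[str, int]]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        k = seen.get(n, 0)
        out.append((n, k))
        seen[n] = k + 1
    return out


def _reduced(names_a: list[str], names_b: list[str]
             ) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Delete per-name copies beyond the shared count, then label the
    surviving duplicates by occurrence index so that e.g. the two control
    regions can be told apart in neighbour comparisons.

    When an order carries more copies of a name than the other, the copies
    whose (5', 3') name-context matches a context of the same name in the
    other order are retained preferentially (so a freshly inserted
    duplicate is the one deleted), falling back to first-in-anchored-order.
    """
    from collections import Counter
    ca, cb = Counter(names_a), Counter(names_b)
    shared = {n: min(ca[n], cb[n]) for n in ca.keys() & cb.keys()}

    def contexts(names: list[str]) -> dict[str, list[tuple[str, str]]]:
        n = len(names)
        out: dict[str, list[tuple[str, str]]] = {}
        for i, name in enumerate(names):
            out.setdefault(name, []).append(
                (names[(i - 1) % n], names[(i + 1) % n])
            )
        return out

    def keep(names: list[str], other: list[str]) -> list[str]:
        own_ctx = contexts(names)
        other_ctx = contexts(other)
        n = len(names)
        keep_idx: set[int] = set()
        occ_seen: dict[str, int] = {}
        # rank each name's occurrences: context-matched first, then order
        per_name: dict[str, list[tuple[int, int]]] = {}
        for i, name in enumerate(names):
            k = occ_seen.get(name, 0)
            occ_seen[name] = k + 1
            ctx = own_ctx[name][k]
            matched = 0 if ctx in other_ctx.get(name, []) else 1
            per_name.setdefault(name, []).append((matched, i))
        for name, ranked in per_name.items():
            quota = shared.get(name, 0)
            for _, i in sorted(ranked)[:quota]:
                keep_idx.add(i)
        return [names[i] for i in range(n) if i in keep_idx]

    return (
        _occurrence_labels(keep(names_a, names_b)),
        _occurrence_labels(keep(names_b, names_a)),
    )


def detect_translocations(order: GeneOrder, reference_order: GeneOrder
                          ) -> list[tuple[str, tuple[str, str],
                                          tuple[str, str]]]:
    """Genes whose circular neighbourhood differs between two orders.

    A gene is reported iff it occurs exactly once in both orders and BOTH
    its circular neighbours differ after (a) deleting tokens absent from
    either order, so single insertions/losses elsewhere do not cascade into
    spurious calls, and (b) disambiguating surviving duplicate names by
    occurrence index along the anchor-rotated order.  Sorted by gene name;
    neighbour pairs are reported as (5', 3') names.
    """
    names_o = _anchored_names(order)
    names_r = _anchored_names(reference_order)
    red_o, red_r = _reduced(names_o, names_r)

    def neighbour_map(labels: list[tuple[str, int]]):
        n = len(labels)
        return {
            lab: (labels[(i - 1) % n], labels[(i + 1) % n])
            for i, lab in enumerate(labels)
        }

    nb_o, nb_r = neighbour_map(red_o), neighbour_map(red_r)
    from collections import Counter
    c_o, c_r = Counter(names_o), Counter(names_r)
    calls = []
    for name in sorted(c_o.keys() & c_r.keys()):
        if c_o[name] != 1 or c_r[name] != 1:
            continue
        lab = (name, 0)
        (l_o, r_o), (l_r, r_r) = nb_o[lab], nb_r[lab]
        if l_o != l_r and r_o != r_r:
            calls.append((name, (l_r[0], r_r[0]), (l_o[0], r_o[0])))
    return _drop_shadow_calls(calls, red_o, red_r)


def _drop_shadow_calls(calls, red_o, red_r):
    """Suppress calls that are artifacts of another called gene's move.

    Moving one gene between two others changes the displaced neighbours'
    flanks too; a call g is a shadow of a call h when deleting h restores
    g's neighbourhood.  Mutual shadows (an adjacent swap) are resolved in
    favour of the tRNA — single-tRNA translocation is the expected
    mitochondrial mechanism — then by name.
    """
    if len(calls) < 2:
        return calls

    def resolved_without(g: str, h: str) -> bool:
        def nb(labels):
            keep = [lab for lab in labels if lab[0] != h]
            n = len(keep)
            for i, lab in enumerate(keep):
                if lab == (g, 0):
                    return keep[(i - 1) % n], keep[(i + 1) % n]
            return None
        return nb(red_o) == nb(red_r) and nb(red_o) is not None

    def is_trna(name: str) -> bool:
        return vocab.category_of(name) == vocab.CATEGORY_TRNA

    names = [c[0] for c in calls]
    kept = []
    for g, ref_nb, obs_nb in calls:
        shadowed = False
        for h in names:
            if h == g or not resolved_without(g, h):
                continue
            if not resolved_without(h, g):
                shadowed = True
                break
            # mutual shadow: keep the tRNA, then the alphabetically first
            keep_g = (is_trna(g) and not is_trna(h)) or (
                is_trna(g) == is_trna(h) and g < h
            )
            if not keep_g:
                shadowed = True
                break
        if not shadowed:
            kept.append((g, ref_nb, obs_nb))
    return kept


def detect_pseudogenes(order: GeneOrder
                       ) -> list[tuple[str, tuple[str, str]]]:
    """All pseudogene tokens with their immediate (5', 3') neighbours."""
    out = []
    for i, tok in enumerate(order):
        if tok.is_pseudo:
            left, right = order.neighbors(i)
            out.append((tok.name, (left.name, right.name)))
    return out


def detect_extra_copies(order: GeneOrder) -> list[str]:
    """Functional gene names occurring at least twice (CR excluded: control
    region duplications are reported by count_control_regions)."""
    from collections import Counter
    counts = Counter(
        t.name for t in order
        if t.category in (vocab.CATEGORY_TRNA, vocab.CATEGORY_RRNA,
                          vocab.CATEGORY_PCG)
    )
    return sorted(n for n, c in counts.items() if c >= 2)


def detect_nc_insertions(order: GeneOrder
                         ) -> list[tuple[int, tuple[str, str]]]:
    """All non-coding insertion tokens with flanks, longest first."""
    out = []
    for i, tok in enumerate(order):
        if tok.category == vocab.CATEGORY_NC:
            left, right = order.neighbors(i)
            out.append((tok.length_bp, (left.name, right.name)))
    return sorted(out, key=lambda x: -x[0])


@dataclass
class FeatureReport:
    """Per-taxon summary of every scored rearrangement feature."""

    taxon_id: str
    ol_present: bool
    cr_count: int
    cr_lengths: list[int]
    cr_asymmetric: bool
    translocations: list[tuple[str, tuple[str, str], tuple[str, str]]]
    pseudogenes: list[tuple[str, tuple[str, str]]]
    nc_insertions: list[tuple[int, tuple[str, str]]]
    extra_copies: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cr_lengths and len(self.cr_lengths) != self.cr_count:
            raise ValueError("cr_lengths inconsistent with cr_count")
        if self.cr_asymmetric and self.cr_count < 2:
            raise ValueError("asymmetry requires at least two CRs")

    def to_dict(self) -> dict:
        return {
            "taxon_id": self.taxon_id,
            "ol_present": self.ol_present,
            "cr_count": self.cr_count,
            "cr_lengths": list(self.cr_lengths),
            "cr_asymmetric": self.cr_asymmetric,
            "translocations": [
                {"gene": g, "reference_neighbors": list(r),
                 "observed_neighbors": list(o)}
                for g, r, o in self.translocations
            ],
            "pseudogenes": [
                {"symbol": s, "neighbors": list(nb)}
                for s, nb in self.pseudogenes
            ],
            "nc_insertions": [
                {"length_bp": ln, "neighbors": list(nb)}
                for ln, nb in self.nc_insertions
            ],
            "extra_copies": list(self.extra_copies),
        }


def feature_report(record: MitogenomeRecord,
                   reference_order: GeneOrder,
                   ratio: float = CR_ASYMMETRY_RATIO) -> FeatureReport:
    """Run the full detector suite for one record against a reference."""
    ol_present, _ = detect_ol(record.order)
    cr_count, cr_lengths, cr_asym = count_control_regions(record, ratio)
    return FeatureReport(
        taxon_id=record.taxon_id,
        ol_present=ol_present,
        cr_count=cr_count,
        cr_lengths=cr_lengths,
        cr_asymmetric=cr_asym,
        translocations=detect_translocations(record.order, reference_order),
        pseudogenes=detect_pseudogenes(record.order),
        nc_insertions=detect_nc_insertions(record.order),
        extra_copies=detect_extra_copies(record.order),
    )


def _event_locus(event: EventAnnotation, order: GeneOrder) -> str:
    """Hotspot locus of one diagnostic event.

    CR-flank: the event concerns a control region (CR asymmetry, a CR
    duplication) or a token that lands/sits circularly adjacent to a CR in
    the type's own order.  WANCY: the event's subject or resting context
    lies inside the W..Y tRNA span (inclusive of OL).  Everything else is
    "other".  A translocation is judged where its subject LANDS in the
    derived order.
    """
    if event.kind == CR_ASYMMETRY:
        return HOTSPOT_CR_FLANK
    base = vocab.base_symbol(event.subject)
    context = event.to_context or event.from_context or ()
    if base == "CR" or "CR" in context:
        return HOTSPOT_CR_FLANK
    # adjacency to a CR in the type's own order
    for i, tok in enumerate(order):
        if tok.name == event.subject:
            left, right = order.neighbors(i)
            if "CR" in (left.name, right.name):
                return HOTSPOT_CR_FLANK
    in_wancy = base in WANCY or (
        bool(context) and all(vocab.base_symbol(c) in WANCY for c in context)
    )
    return HOTSPOT_WANCY if in_wancy else HOTSPOT_OTHER


def hotspot_assignment(arrangement_type) -> set[str]:
    """Hotspot loci of an arrangement type's diagnostic events.

    One locus per event from {WANCY, CR-flank, other}.  A type "has a
    CR-flank rearrangement" iff at least one of its events maps there.
    """
    events = arrangement_type.diagnostic_events
    if not events:
        raise ValueError(
            f"type {arrangement_type.label!r} has no diagnostic events"
        )
    return {
        _event_locus(ev, arrangement_type.reference_order) for ev in events
    }


def cr_flank_type_count(registry) -> int:
    """How many registry types have at least one CR-flank diagnostic
    event."""
    return sum(
        1 for t in registry if HOTSPOT_CR_FLANK in hotspot_assignment(t)
    )
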