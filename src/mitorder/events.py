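"""Event-path inference between arrangements and the derivation graph.

``infer_event_path`` decomposes the difference between a parent and a
child gene order into an ordered list of rearrangement events: first
content changes (losses, then insertions / pseudogenizations /
duplications, classified by token category), then positional changes
(translocations by circular-neighbourhood comparison), then control-region
asymmetry changes.  ``derivation_graph`` maps resolved ancestral
arrangement types onto a tree and collects every distinct parent→child
type transition as a directed edge annotated with its event path.
"""

from __future__ import annotations

from collections import Counter

import networkx as nx

from . import vocab
from .features import detect_translocations
from .io import PhyloTree
from .model import (
    CR_ASYMMETRY,
    DUPLICATION,
    EventAnnotation,
    GeneOrder,
    INSERTION,
    LOSS,
    PSEUDOGENIZATION,
    TRANSLOCATION,
    linearize,
)
from .parsimony import DELTRAN, resolve_states, transitions

UNKNOWN = "UNKNOWN"

_CATEGORY_ORDER = {
    LOSS: 0, INSERTION: 1, PSEUDOGENIZATION: 2, DUPLICATION: 3,
    TRANSLOCATION: 4, CR_ASYMMETRY: 5,
}

CR_ASYMMETRY_RATIO = 1.2


def _occurrences(order: GeneOrder) -> list[tuple[str, tuple[str, str]]]:
    toks = linearize(order)
    n = len(toks)
    return [
        (toks[i].name, (toks[(i - 1) % n].name, toks[(i + 1) % n].name))
        for i in range(n)
    ]


def _novel_occurrences(name: str, more: list, fewer: list, k: int
                       ) -> list[tuple[str, str]]:
    """Contexts of the k copies of ``name`` present in ``more`` but not
    matched by context in ``fewer`` (fallback: the last k occurrences)."""
    ctx_more = [c for n, c in more if n == name]
    ctx_fewer = [c for n, c in fewer if n == name]
    unmatched = list(ctx_more)
    for c in ctx_fewer:
        if c in unmatched:
            unmatched.remove(c)
    if len(unmatched) >= k:
        return unmatched[-k:]
    return ctx_more[-k:]


def _cr_ratio(order: GeneOrder) -> float | None:
    lengths = order.cr_lengths()
    if len(lengths) < 2:
        return None
    return max(lengths) / min(lengths)


def infer_event_path(parent: GeneOrder, child: GeneOrder,
                     ratio: float = CR_ASYMMETRY_RATIO
                     ) -> list[EventAnnotation]:
    """Deterministic event decomposition of a parent→child transition.

    Events come out in category order (losses, insertions,
    pseudogenizations, duplications, translocations, CR asymmetry),
    alphabetical by subject within a category.
    """
    occ_p, occ_c = _occurrences(parent), _occurrences(child)
    count_p = Counter(n for n, _ in occ_p)
    count_c = Counter(n for n, _ in occ_c)

    events: list[EventAnnotation] = []
    for name in sorted(set(count_p) | set(count_c)):
        d = count_c[name] - count_p[name]
        if d < 0:
            for ctx in _novel_occurrences(name, occ_p, occ_c, -d):
                events.append(
                    EventAnnotation(LOSS, name, from_context=ctx)
                )
        elif d > 0:
            cat = vocab.category_of(name)
            if cat == vocab.CATEGORY_NC:
                kind = INSERTION
            elif cat == vocab.CATEGORY_PSEUDO:
                kind = PSEUDOGENIZATION
            elif count_p[name] >= 1 or cat == vocab.CATEGORY_CR:
                kind = DUPLICATION
            else:
                kind = INSERTION
            if cat == vocab.CATEGORY_NC:
                toks = linearize(child)
                n = len(toks)
                ctx_len = {}
                for i, t in enumerate(toks):
                    if t.name == name:
                        ctx = (toks[(i - 1) % n].name, toks[(i + 1) % n].name)
                        ctx_len.setdefault(ctx, t.length_bp)
            else:
                ctx_len = {}
            for ctx in _novel_occurrences(name, occ_c, occ_p, d):
                events.append(
                    EventAnnotation(kind, name, to_context=ctx,
                                    length_bp=ctx_len.get(ctx))
                )

    for gene, ref_nb, obs_nb in detect_translocations(child, parent):
        events.append(
            EventAnnotation(TRANSLOCATION, gene, from_context=ref_nb,
                            to_context=obs_nb)
        )

    rp, rc = _cr_ratio(parent), _cr_ratio(child)
    if rp is not None and rc is not None and rp <= ratio < rc:
        events.append(EventAnnotation(CR_ASYMMETRY, "CR"))

    events.sort(key=lambda e: (_CATEGORY_ORDER[e.kind], e.subject))
    return events


def derivation_graph(registry, tree: PhyloTree, charmap: dict[str, str],
                     mode: str = DELTRAN,
                     ratio: float = CR_ASYMMETRY_RATIO) -> nx.DiGraph:
    """Directed graph of arrangement-type derivations on the tree.

    The root state is forced to UNKNOWN (the ancestral arrangement is
    deliberately left indeterminate); edges out of UNKNOWN take their
    event paths from the registry's stored diagnostic events, all other
    edges are annotated by diffing the two reference orders.  The result
    must be a DAG.
    """
    states = sorted(set(charmap.values()))
    graph = nx.DiGraph()
    if len(states) == 1:
        # a single observed arrangement supports no derivation inference
        graph.add_node(states[0])
        return graph
    resolved = resolve_states(tree, charmap, force_root=UNKNOWN, mode=mode)
    graph.add_node(UNKNOWN)
    for label in states:
        graph.add_node(label)
    for ps, cs, _, _ in transitions(tree, resolved):
        if graph.has_edge(ps, cs):
            continue
        if ps == UNKNOWN:
            events = list(registry.get(cs).diagnostic_events)
        else:
            events = infer_event_path(
                registry.get(ps).reference_order,
                registry.get(cs).reference_order,
                ratio=ratio,
            )
        graph.add_edge(ps, cs, events=events)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("derivation graph contains a cycle")
    return graph


def graph_to_dot(graph: nx.DiGraph) -> str:
    """Minimal DOT serialisation of the derivation graph."""
    lines = ["digraph derivations {"]
    for node in sorted(graph.nodes):
        lines.append(f'  "{node}";')
    for a, b, data in sorted(graph.edges(data=True)):
        label = "\\n".join(str(e) for e in data.get("events", []))
        lines.append(f'  "{a}" -> "{b}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)


def graph_to_json_dict(graph: nx.DiGraph) -> dict:
    return {
        "nodes": sorted(graph.nodes),
        "edges": [
            {
                "from": a,
                "to": b,
                "events": [str(e) for e in data.get("events", [])],
            }
            for a, b, data in sorted(graph.edges(data=True))
        ],
    }
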