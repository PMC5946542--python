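"""Unordered-character parsimony on rooted (possibly multifurcating) trees.

``fitch_reconstruct`` performs the classic bottom-up pass (multifurcations
handled by iterated pairwise intersection in child-list order) and returns
per-node state sets plus the minimum change count.  ``resolve_states``
picks one state per node using minimal-cost (Sankoff, unit costs) state
sets — the full set of most-parsimonious-reconstruction states, not just
the down-pass sets — resolved top-down with DELTRAN (keep the parent's
state whenever it is equally parsimonious, delaying transformations toward
the tips) or ACCTRAN tie-breaking.  An outgroup state can be supplied as a
virtual root neighbour: this is how ancestral knowledge from taxa outside
the tree (e.g. lizard outgroups carrying a functional OL) enters the
reconstruction.  ``brute_force_parsimony`` is an exhaustive enumerator for
small trees used as an independent oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .io import PhyloTree

INF = float("inf")

DELTRAN = "DELTRAN"
ACCTRAN = "ACCTRAN"


def _children(node):
    return node.child_nodes()


def _tip_label(node) -> str:
    return node.taxon.label


@dataclass
class FitchResult:
    state_sets: dict  # node -> frozenset of states
    score: int


def fitch_reconstruct(tree: PhyloTree, charmap: dict[str, str]
                      ) -> FitchResult:
    """Bottom-up Fitch pass; the score counts empty-intersection events.

    On binary trees this equals the true parsimony score; on
    multifurcations children are folded pairwise in child-list order.
    """
    tree.validate_charmap(charmap)
    sets: dict = {}
    score = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({charmap[_tip_label(node)]})
            continue
        kids = _children(node)
        acc = sets[kids[0]]
        for kid in kids[1:]:
            inter = acc & sets[kid]
            if inter:
                acc = inter
            else:
                acc = acc | sets[kid]
                score += 1
        sets[node] = acc
    return FitchResult(state_sets=sets, score=score)


def _sankoff_below(tree: PhyloTree, charmap: dict[str, str],
                   alphabet: list[str]) -> dict:
    """cost_below[node][state] = minimal changes in the subtree rooted at
    node given the node takes that state (unit substitution costs)."""
    below: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            s0 = charmap[_tip_label(node)]
            below[node] = {s: (0 if s == s0 else INF) for s in alphabet}
            continue
        costs = {}
        for s in alphabet:
            total = 0
            for kid in _children(node):
                kb = below[kid]
                total += min(kb[t] + (0 if t == s else 1) for t in alphabet)
            costs[s] = total
        below[node] = costs
    return below


def resolve_states(tree: PhyloTree, charmap: dict[str, str],
                   outgroup_state: str | None = None,
                   force_root: str | None = None,
                   mode: str = DELTRAN) -> dict:
    """One state per node, minimal total changes, DELTRAN/ACCTRAN ties.

    ``outgroup_state`` acts as a virtual extra root neighbour (one edge of
    unit cost), pulling the root toward the outgroup-compatible state when
    that is equally parsimonious.  ``force_root`` pins the root to a given
    state unconditionally — used for characters whose ancestral condition
    is declared unknown/external (the root then pays one change to every
    child state that differs).
    """
    if mode not in (DELTRAN, ACCTRAN):
        raise ValueError(f"unknown resolution mode {mode!r}")
    tree.validate_charmap(charmap)
    alphabet = sorted(set(charmap.values()))
    below = _sankoff_below(tree, charmap, alphabet)
    root = tree.tree.seed_node
    resolved: dict = {}

    if force_root is not None:
        resolved[root] = force_root
    else:
        def root_total(s: str) -> float:
            extra = 0 if (outgroup_state is None or s == outgroup_state) \
                else 1
            return below[root][s] + extra

        best = min(root_total(s) for s in alphabet)
        minima = [s for s in alphabet if root_total(s) == best]
        if outgroup_state in minima:
            resolved[root] = outgroup_state
        else:
            resolved[root] = minima[0]

    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = resolved[node.parent_node]
        costs = {
            s: below[node][s] + (0 if s == parent_state else 1)
            for s in alphabet
        }
        best = min(costs.values())
        minima = [s for s in alphabet if costs[s] == best]
        if mode == DELTRAN:
            resolved[node] = parent_state if parent_state in minima \
                else minima[0]
        else:  # ACCTRAN: accept a change as early as possible
            non_parent = [s for s in minima if s != parent_state]
            resolved[node] = non_parent[0] if non_parent else parent_state
    return resolved


def transitions(tree: PhyloTree, resolved: dict
                ) -> list[tuple[str, str, object, object]]:
    """All state-changing edges as (parent_state, child_state, parent_node,
    child_node), preorder."""
    out = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        ps, cs = resolved[node.parent_node], resolved[node]
        if ps != cs:
            out.append((ps, cs, node.parent_node, node))
    return out


def count_origins(tree: PhyloTree, charmap: dict[str, str], state: str,
                  outgroup_state: str | None = None,
                  force_root: str | None = None,
                  mode: str = DELTRAN) -> int:
    """Independent origins of ``state``: edges where the parent lacks it
    and the child has it, under the resolved reconstruction."""
    resolved = resolve_states(tree, charmap, outgroup_state=outgroup_state,
                              force_root=force_root, mode=mode)
    return sum(1 for ps, cs, _, _ in transitions(tree, resolved)
               if cs == state and ps != state)


def count_losses(tree: PhyloTree, charmap: dict[str, str], state: str,
                 outgroup_state: str | None = None,
                 force_root: str | None = None,
                 mode: str = DELTRAN) -> int:
    """Independent losses of ``state``: edges where the parent has it and
    the child does not."""
    resolved = resolve_states(tree, charmap, outgroup_state=outgroup_state,
                              force_root=force_root, mode=mode)
    return sum(1 for ps, cs, _, _ in transitions(tree, resolved)
               if ps == state and cs != state)


MAX_BRUTE_TIPS = 12
MAX_BRUTE_COMBOS = 2_000_000


def brute_force_parsimony(tree: PhyloTree, charmap: dict[str, str]
                          ) -> tuple[int, list[dict]]:
    """Exact minimum change count by exhaustive enumeration of ancestral
    labelings; refuses trees above 12 tips.  Returns (score, labelings)
    where each labeling maps node -> state (tips included)."""
    if tree.n_tips() > MAX_BRUTE_TIPS:
        raise ValueError(
            f"brute force refuses trees above {MAX_BRUTE_TIPS} tips"
        )
    tree.validate_charmap(charmap)
    alphabet = sorted(set(charmap.values()))
    internals = [n for n in tree.tree.preorder_node_iter()
                 if not n.is_leaf()]
    if len(alphabet) ** len(internals) > MAX_BRUTE_COMBOS:
        raise ValueError("state space too large for brute force")
    tips = {n: charmap[_tip_label(n)]
            for n in tree.tree.leaf_node_iter()}
    best_score = None
    best_labelings: list[dict] = []
    for combo in itertools.product(alphabet, repeat=len(internals)):
        labeling = dict(tips)
        labeling.update(zip(internals, combo))
        score = sum(
            1 for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
            and labeling[n] != labeling[n.parent_node]
        )
        if best_score is None or score < best_score:
            best_score = score
            best_labelings = [labeling]
        elif score == best_score:
            best_labelings.append(labeling)
    return best_score, best_labelings


def origin_range_over_optima(tree: PhyloTree, charmap: dict[str, str],
                             state: str) -> tuple[int, int]:
    """Min/max independent-origin counts of ``state`` across all optimal
    labelings (brute force; small trees only)."""
    _, labelings = brute_force_parsimony(tree, charmap)
    counts = []
    for lab in labelings:
        c = sum(
            1 for n in tree.tree.preorder_node_iter()
            if n.parent_node is not None
            and lab[n] == state and lab[n.parent_node] != state
        )
        counts.append(c)
    return min(counts), max(counts)
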