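"""Shared helper: random binary trees for parsimony oracle tests."""

from mitorder import PhyloTree


def random_binary_tree(labels, rng) -> PhyloTree:
    nodes = list(labels)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b})")
    return PhyloTree.from_newick(nodes[0] + ";")
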