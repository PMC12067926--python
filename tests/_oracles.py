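"""Independent brute-force oracles used by more than one test module."""

import numpy as np


def brute_force_unifrac(tree, u, v, taxa, normalized):
    """Abundance-weighted UniFrac by explicit enumeration over every branch."""
    u = np.asarray(u, float) / np.sum(u)
    v = np.asarray(v, float) / np.sum(v)
    abundance = {t: (a, b) for t, a, b in zip(taxa, u, v)}
    raw = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.edge.length is None:
            continue
        tips = [l.taxon.label for l in node.leaf_iter()]
        A = sum(abundance[t][0] for t in tips if t in abundance)
        B = sum(abundance[t][1] for t in tips if t in abundance)
        raw += node.edge.length * abs(A - B)
    if not normalized:
        return raw
    depth = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d
    denom = sum(depth[t] * (abundance[t][0] + abundance[t][1]) for t in taxa)
    return raw / denom
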