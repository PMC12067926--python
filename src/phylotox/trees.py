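"""Rooted-phylogeny handling: Newick I/O, patristic distances, trait covariance.

Trees are held as :class:`dendropy.Tree` objects. Two matrix views of a tree
are used throughout the package:

* the **patristic distance matrix** ``d[i, j]`` — the sum of branch lengths on
  the path between tips *i* and *j*;
* the **phylogenetic variance–covariance matrix** (VCV) ``V[i, j]`` — the
  shared root-to-MRCA path length of tips *i* and *j*, which is the trait
  covariance implied by Brownian motion run along the tree. The diagonal holds
  root-to-tip depths.

The two are linked by ``d[i, j] = V[i, i] + V[j, j] - 2 V[i, j]``.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "write_newick",
    "tip_labels",
    "patristic_distances",
    "phylo_vcv",
]


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Parameters
    ----------
    source
        Path to a Newick file, or a Newick string itself (detected by the
        presence of ``(`` / ``;``).

    Raises
    ------
    ValueError
        If any non-root edge lacks a branch length, a branch length is
        negative, or tip labels are duplicated.
    """
    text = str(source)
    try:
        if "(" in text and ";" in text:
            tree = dendropy.Tree.get(data=text, schema="newick", rooting="force-rooted")
        else:
            tree = dendropy.Tree.get(path=text, schema="newick", rooting="force-rooted")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
        raise ValueError(f"duplicate tip labels in Newick source: {err}") from err
    _validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue()


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    root = tree.seed_node
    for edge in tree.preorder_edge_iter():
        if edge.head_node is root:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if edge.length < 0:
            raise ValueError(f"negative branch length: {edge.length}")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip patristic distance matrix as a labelled square DataFrame."""
    V = phylo_vcv(tree)
    depths = np.diag(V.to_numpy())
    D = depths[:, None] + depths[None, :] - 2.0 * V.to_numpy()
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=V.index, columns=V.columns)


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion variance–covariance matrix of a rooted tree.

    ``V[i, j]`` is the path length from the root node to the most recent
    common ancestor of tips *i* and *j*; the diagonal is the root-to-tip
    depth. Any edge length on the root itself (a stem edge) is ignored: the
    crown node defines time zero.
    """
    _validate_tree(tree)
    labels = tip_labels(tree)
    n = len(labels)
    idx = {lab: k for k, lab in enumerate(labels)}
    V = np.zeros((n, n))

    # node depth from the crown (root) node, ignoring the root's own edge
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    # postorder: tips descending from each node; pairs split across children
    # of a node have that node as MRCA, so their covariance is its depth
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = idx[node.taxon.label]
            V[k, k] = depth[node]
            below[node] = [k]
            continue
        children = [below[c] for c in node.child_nodes()]
        d = depth[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        V[i, j] = V[j, i] = d
        below[node] = [i for ch in children for i in ch]
    return pd.DataFrame(V, index=labels, columns=labels)
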