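"""Clonal population-structure correction for strain panels.

Near-identical (clonal) strains violate the independence assumption of a
two-sample test and inflate association statistics. The correction used here
builds a UPGMA guide tree from pairwise k-mer distances and converts it to
Gerstein-Sonnhammer-Chothia (GSC) leaf weights: branch length is distributed
from the tips towards the root, so a cluster of clones shares the weight mass
that a single distinct lineage would receive.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class StructureWeights:
    """Per-strain weights (normalized to mean 1) plus their guide tree."""

    weights: dict  # strain_id -> non-negative float, mean 1
    tree: dendropy.Tree

    def aligned(self, strain_ids) -> np.ndarray:
        return np.array([self.weights[s] for s in strain_ids])


def build_guide_tree(distances) -> dendropy.Tree:
    """UPGMA agglomeration of a symmetric distance matrix (pandas DataFrame).

    Deterministic: among equally close pairs, the pair whose (lexicographically
    smallest member) labels sort first is merged. Returns a rooted ultrametric
    dendropy tree with branch lengths in distance units (heights are half the
    merge distance, as usual for UPGMA).
    """
    labels = list(distances.index)
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if len(labels) == 1:
        return dendropy.Tree.get(data=f"({labels[0]}:0.0);", schema="newick",
                                 preserve_underscores=True)

    # active clusters: rep label -> (newick fragment, size, height, index set)
    def pair_key(a, b):
        return (a, b) if a <= b else (b, a)

    dist = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            dist[pair_key(a, labels[j])] = d[i, j]
    clusters = {lab: (lab, 1, 0.0) for lab in labels}

    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), dab = best
        na_frag, na, ha = clusters[a]
        nb_frag, nb, hb = clusters[b]
        height = dab / 2.0
        frag = (f"({na_frag}:{height - ha:.10g},"
                f"{nb_frag}:{height - hb:.10g})")
        rep = min(a, b)
        other = [c for c in clusters if c not in (a, b)]
        for c in other:
            dac = dist.pop(pair_key(a, c))
            dbc = dist.pop(pair_key(b, c))
            dist[pair_key(rep, c)] = (na * dac + nb * dbc) / (na + nb)
        dist.pop(pair_key(a, b))
        del clusters[a], clusters[b]
        clusters[rep] = (frag, na + nb, height)

    frag, _, _ = next(iter(clusters.values()))
    tree = dendropy.Tree.get(data=frag + ";", schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def gsc_weights(tree: dendropy.Tree) -> StructureWeights:
    """Gerstein-Sonnhammer-Chothia weights from a rooted tree.

    Each leaf starts with the length of its terminal branch; ascending from
    the tips, every internal branch's length is divided among its descendant
    leaves in proportion to their accumulated weights (equally if all are
    still zero). Weights are finally normalized to mean 1.
    """
    if not tree.is_rooted:
        raise ValueError("GSC weights require a rooted tree")
    leaf_weight = {}
    leaf_sets = {}
    root = tree.seed_node
    for node in tree.postorder_node_iter():
        length = node.edge.length or 0.0
        if length < 0:
            raise ValueError("negative branch length")
        if node.is_leaf():
            label = node.taxon.label
            leaf_weight[label] = float(length)
            leaf_sets[node] = [label]
        else:
            leaves = [lf for ch in node.child_nodes() for lf in leaf_sets[ch]]
            leaf_sets[node] = leaves
            if node is root or length == 0.0:
                continue
            total = sum(leaf_weight[lf] for lf in leaves)
            if total == 0.0:
                share = length / len(leaves)
                for lf in leaves:
                    leaf_weight[lf] += share
            else:
                for lf in leaves:
                    leaf_weight[lf] += length * leaf_weight[lf] / total
    w = np.array(list(leaf_weight.values()))
    mean = w.mean()
    if mean == 0.0:
        weights = {lf: 1.0 for lf in leaf_weight}  # star of zero branches
    else:
        weights = {lf: v / mean for lf, v in leaf_weight.items()}
    return StructureWeights(weights=weights, tree=tree)
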