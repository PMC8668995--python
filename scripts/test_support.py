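"""Small oracles shared by the acceptance script: random additive trees and
their exact path-length distance matrices."""

from __future__ import annotations

import numpy as np

from wee1kit.phylo import Node, PhyloTree, _adjacency, _leaf_paths


def random_additive_tree(n: int, rng, blmin: float = 0.1,
                         blmax: float = 2.0) -> PhyloTree:
    nodes = [Node(label=f"t{i:02d}") for i in range(n)]
    while len(nodes) > 3:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        p = Node()
        p.add(a, round(rng.uniform(blmin, blmax), 3))
        p.add(b, round(rng.uniform(blmin, blmax), 3))
        nodes.append(p)
    root = Node()
    for x in nodes:
        root.add(x, round(rng.uniform(blmin, blmax), 3))
    return PhyloTree(root=root, rooted=False)


def tree_distance_matrix(tree: PhyloTree):
    adj, node_of = _adjacency(tree)
    leaves = {x.label: id(x) for x in tree.leaves()}
    labs = sorted(leaves)
    D = np.zeros((len(labs), len(labs)))
    for i, la in enumerate(labs):
        dist, _ = _leaf_paths(adj, node_of, leaves[la])
        for j, lb in enumerate(labs):
            D[i, j] = dist[leaves[lb]]
    return D, labs
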