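"""Shared fixtures and independent oracles used across the test suite."""

from itertools import combinations

import numpy as np
import pytest

from tfbsevol.parsimony import SpeciesTree


def enumerate_rooted_topologies(leaves):
    """All rooted binary topologies over the given labeled leaves (newick).

    Counts follow the double factorial (2n-3)!!: 1, 1, 3, 15, 105, 945 for
    n = 1..6.  Branch lengths of 1 are attached to every edge.
    """
    leaves = list(leaves)

    def build(subset):
        if len(subset) == 1:
            yield subset[0]
            return
        first, rest = subset[0], subset[1:]
        for k in range(0, len(rest)):
            for left_rest in combinations(rest, k):
                left = [first, *left_rest]
                right = [x for x in rest if x not in left_rest]
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        yield f"({lt}:1,{rt}:1)"
    return [t + ";" for t in build(leaves)]


def brute_force_parsimony_score(tree: SpeciesTree, presence) -> int:
    """Minimum state changes over exhaustive internal labelings."""
    internal = [lab for lab in tree.node_labels if not tree.is_leaf(lab)]
    edges = tree.edge_child_labels
    best = len(edges) + 1
    for mask in range(2 ** len(internal)):
        states = dict(presence)
        for i, lab in enumerate(internal):
            states[lab] = (mask >> i) & 1
        changes = sum(states[tree.parent(c)] != states[c] for c in edges)
        best = min(best, changes)
    return best


def brute_force_spanning_length(tree: SpeciesTree, present_leaves) -> float:
    """Minimal subtree connecting leaves = union of pairwise path edges."""

    def path_edges(a, b):
        anc_a = []
        node = a
        while node is not None:
            anc_a.append(node)
            node = tree.parent(node)
        edges = set()
        node = b
        while node not in anc_a:
            edges.add(node)
            node = tree.parent(node)
        mrca = node
        for node in anc_a:
            if node == mrca:
                break
            edges.add(node)
        return edges

    present = sorted(present_leaves)
    union = set()
    for a, b in combinations(present, 2):
        union |= path_edges(a, b)
    return sum(tree.branch_length(e) for e in union)


def enumerate_word_scores(matrix):
    """Exact scores and background probabilities of all 4^L words."""
    L = matrix.length
    n = 4 ** L
    idx = (np.arange(n)[:, None] // (4 ** np.arange(L)[::-1])) % 4
    scores = matrix.logodds[np.arange(L), idx].sum(axis=1)
    probs = matrix.background[idx].prod(axis=1)
    return scores, probs


@pytest.fixture
def balanced4_tree():
    return SpeciesTree.from_newick("((A:1,B:1)ab:1,(C:1,D:1)cd:1)root;")
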