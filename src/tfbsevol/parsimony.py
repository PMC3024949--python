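"""Ancestral presence/absence of site characters on a species tree.

Each homologous site is a binary character observed at the leaves of a
rooted species tree.  Internal states are reconstructed by small parsimony
(minimum number of 0<->1 changes, unit costs), implemented as the binary
Sankoff dynamic program with explicit backtracking so that the two standard
resolutions of ambiguity are available:

* ``DELTRAN`` (default) keeps the parent's state on ties, delaying changes
  toward the leaves — independent late gains rather than an early gain plus
  losses;
* ``ACCTRAN`` places the change on the current edge on ties, accelerating
  changes toward the root.

Both resolutions are guaranteed minimum-change reconstructions because the
tie-break only chooses among argmin candidates of the exact DP.  An
ambiguous root defaults to state 0: absence is treated as ancestral, so
regulatory elements are derived.

Gains (0 -> 1) and losses (1 -> 0) are read off the edges; an edge is named
by its child node.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

_INF = float("inf")


@dataclass
class _Node:
    index: int
    label: str
    parent: int | None
    children: list[int]
    length: float


class SpeciesTree:
    """A rooted species tree with branch lengths and unique leaf labels.

    Internal nodes keep their newick labels when present; unlabeled internal
    nodes get deterministic ``anc<k>`` names in preorder.  Edges are
    identified by their child node's label.
    """

    def __init__(self, nodes: list[_Node]):
        self._nodes = nodes
        labels = [n.label for n in nodes]
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        self._by_label = {n.label: n.index for n in nodes}
        leaves = self.leaf_labels
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf labels must be unique")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid newick: {exc}") from exc
        nodes: list[_Node] = []
        counter = [0]

        def walk(dnode, parent_index):
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            else:
                counter[0] += 1
                label = f"anc{counter[0]}"
            idx = len(nodes)
            length = float(dnode.edge.length) if dnode.edge.length is not None else 0.0
            nodes.append(_Node(idx, label, parent_index, [], length))
            for child in dnode.child_nodes():
                child_idx = walk(child, idx)
                nodes[idx].children.append(child_idx)
            return idx

        walk(tree.seed_node, None)
        return cls(nodes)

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            n = self._nodes[i]
            if not n.children:
                body = n.label
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")" + n.label
            if n.parent is None:
                return body
            return f"{body}:{n.length:g}"

        return fmt(0) + ";"

    # -- structure --------------------------------------------------------

    @property
    def root_label(self) -> str:
        return self._nodes[0].label

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self._nodes if not n.children)

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self._nodes)

    @property
    def edge_child_labels(self) -> tuple[str, ...]:
        """Labels of non-root nodes, i.e. one per edge, in preorder."""
        return tuple(self.preorder_labels[1:])

    @property
    def preorder_labels(self) -> tuple[str, ...]:
        order: list[str] = []

        def walk(i: int):
            order.append(self._nodes[i].label)
            for c in self._nodes[i].children:
                walk(c)

        walk(0)
        return tuple(order)

    def children(self, label: str) -> tuple[str, ...]:
        return tuple(self._nodes[c].label for c in self._nodes[self._by_label[label]].children)

    def parent(self, label: str) -> str | None:
        p = self._nodes[self._by_label[label]].parent
        return None if p is None else self._nodes[p].label

    def branch_length(self, child_label: str) -> float:
        return self._nodes[self._by_label[child_label]].length

    def is_leaf(self, label: str) -> bool:
        return not self._nodes[self._by_label[label]].children

    @property
    def total_branch_length(self) -> float:
        return sum(n.length for n in self._nodes if n.parent is not None)

    def leaves_below(self, label: str) -> frozenset[str]:
        node = self._nodes[self._by_label[label]]
        if not node.children:
            return frozenset([label])
        out: set[str] = set()
        for c in node.children:
            out |= self.leaves_below(self._nodes[c].label)
        return frozenset(out)

    def _postorder_indices(self) -> list[int]:
        order: list[int] = []

        def walk(i: int):
            for c in self._nodes[i].children:
                walk(c)
            order.append(i)

        walk(0)
        return order


@dataclass(frozen=True)
class EventLabeling:
    """A most-parsimonious reconstruction for one character.

    ``gains``/``losses`` list edges (by child label) whose parent/child
    states are 0/1 resp. 1/0; ``parsimony_score == len(gains) + len(losses)``.
    """

    character_id: str
    node_states: Mapping[str, int]
    gains: tuple[str, ...]
    losses: tuple[str, ...]
    parsimony_score: int


def fitch_reconstruct(
    tree: SpeciesTree,
    presence: Mapping[str, int],
    resolution: str = "DELTRAN",
    root_state: int = 0,
    character_id: str = "",
) -> EventLabeling:
    """Minimum-change reconstruction of a binary character on ``tree``.

    ``presence`` must assign 0/1 to every leaf.  ``root_state`` is the state
    preferred at the root when both are equally parsimonious.
    """
    if resolution not in ("DELTRAN", "ACCTRAN"):
        raise ValueError("resolution must be DELTRAN or ACCTRAN")
    missing = set(tree.leaf_labels) - set(presence)
    if missing:
        raise ValueError(f"presence missing for leaves: {sorted(missing)}")

    nodes = tree._nodes
    post = tree._postorder_indices()
    cost = [[0.0, 0.0] for _ in nodes]
    for i in post:
        node = nodes[i]
        if not node.children:
            state = int(presence[node.label])
            if state not in (0, 1):
                raise ValueError(f"leaf {node.label!r} state must be 0 or 1")
            cost[i][0] = 0.0 if state == 0 else _INF
            cost[i][1] = 0.0 if state == 1 else _INF
        else:
            for s in (0, 1):
                cost[i][s] = sum(
                    min(cost[c][0] + (s != 0), cost[c][1] + (s != 1))
                    for c in node.children
                )

    states: dict[str, int] = {}
    best = min(cost[0])
    root_candidates = [s for s in (0, 1) if cost[0][s] == best]
    states[nodes[0].label] = root_state if root_state in root_candidates else root_candidates[0]

    def assign(i: int):
        p = states[nodes[i].label]
        for c in nodes[i].children:
            best_c = min(cost[c][t] + (t != p) for t in (0, 1))
            cands = [t for t in (0, 1) if cost[c][t] + (t != p) == best_c]
            if len(cands) == 1:
                t = cands[0]
            elif resolution == "DELTRAN":
                t = p  # delay the change below this edge
            else:
                t = 1 - p  # ACCTRAN: place the change on this edge
            states[nodes[c].label] = t
            assign(c)

    assign(0)

    gains, losses = [], []
    for child in tree.edge_child_labels:
        ps = states[tree.parent(child)]
        cs = states[child]
        if ps == 0 and cs == 1:
            gains.append(child)
        elif ps == 1 and cs == 0:
            losses.append(child)
    score = len(gains) + len(losses)
    assert score == int(best), "reconstruction must achieve the DP optimum"
    return EventLabeling(
        character_id=character_id,
        node_states=states,
        gains=tuple(gains),
        losses=tuple(losses),
        parsimony_score=score,
    )


@dataclass(frozen=True)
class Event:
    """A state change on one edge for one character."""

    edge: str  # child label of the edge
    type: str  # 'gain' or 'loss'
    character_id: str


def extract_events(labeling: EventLabeling, tree: SpeciesTree) -> list[Event]:
    """One event per state-changing edge, in preorder edge order."""
    by_edge = {e: "gain" for e in labeling.gains}
    by_edge.update({e: "loss" for e in labeling.losses})
    return [
        Event(edge=child, type=by_edge[child], character_id=labeling.character_id)
        for child in tree.edge_child_labels
        if child in by_edge
    ]


def events_to_tsv(events: Sequence[Event]) -> str:
    lines = ["character_id\tedge\ttype"]
    for ev in events:
        lines.append(f"{ev.character_id}\t{ev.edge}\t{ev.type}")
    return "\n".join(lines) + "\n"
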