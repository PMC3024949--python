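"""Synthetic regulatory regions evolving along a species tree.

The generator plants motif gain/loss events on tree edges and evolves a
background region by Jukes-Cantor substitution so that every pipeline stage
(scan -> homology -> parsimony -> modules) can be exercised against known
truth without any downloads.

The model: a root sequence is drawn from the background distribution; along
each edge every site substitutes independently with probability
``1 - exp(-rate * branch_length)`` (to one of the three other bases,
uniformly).  A gain planted on an edge writes the motif's consensus at a
fixed position in the child's sequence, which is then inherited (and
further mutated) below; a loss re-randomizes the site from background.
There are no indels, so the alignment is the exact column-wise stack of the
leaf sequences.  The truth log records the planted events and the intended
presence of each motif at each leaf.

Defaults describe the easy regime used throughout the test suite: a
six-species mammal-like tree, a 500 bp region, a ~22-bit 14 bp motif, and a
per-branch substitution probability of about 0.02 per site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .homology import RegionAlignment
from .motifs import BASES, MotifMatrix, build_matrix
from .parsimony import SpeciesTree

#: six eutherian-flavoured species; the planted gain edge in tests is
#: 'euarchontoglires' (human, macaque, mouse, rat below it)
DEFAULT_TREE_NEWICK = (
    "((((human:0.02,macaque:0.02)primates:0.02,(mouse:0.02,rat:0.02)rodents:0.02)"
    "euarchontoglires:0.02,dog:0.02)eutheria:0.02,opossum:0.04)root;"
)

DEFAULT_REGION_LENGTH = 500
DEFAULT_SUBSTITUTION_RATE = 1.0  # expected substitutions/site per unit branch


def default_simulation_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(DEFAULT_TREE_NEWICK)


def default_simulation_motif() -> MotifMatrix:
    """A strong 14 bp site model (~22 bits) for planted-event simulations."""
    consensus = "TGACGTCATTGCAT"
    counts = np.ones((len(consensus), 4))
    for i, base in enumerate(consensus):
        counts[i] = [1.0 if b != base else 19.0 for b in BASES]
        # two of the three off-consensus bases never observed
        off = [j for j in range(4) if BASES[j] != base]
        counts[i, off[1]] = 0.0
        counts[i, off[2]] = 0.0
    return build_matrix(counts, motif_id="simTF", factor_family="simTF")


@dataclass(frozen=True)
class PlantedEvent:
    """A motif gain or loss planted on a tree edge (edge = child label).

    ``edge`` may also name the root, meaning the motif is present in the
    root sequence.
    """

    edge: str
    type: str  # 'gain' or 'loss'
    motif_id: str
    position: int  # 0-based offset of the site in the region

    def __post_init__(self) -> None:
        if self.type not in ("gain", "loss"):
            raise ValueError("event type must be 'gain' or 'loss'")


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    tree: SpeciesTree
    motifs: Mapping[str, MotifMatrix]
    planted_events: tuple[PlantedEvent, ...]
    region_length: int = DEFAULT_REGION_LENGTH
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(self.tree.node_labels)
        intervals = []
        for ev in self.planted_events:
            if ev.edge not in known:
                raise SimulationConfigError(f"unknown edge {ev.edge!r}")
            if ev.motif_id not in self.motifs:
                raise SimulationConfigError(f"unknown motif {ev.motif_id!r}")
            L = self.motifs[ev.motif_id].length
            if not 0 <= ev.position <= self.region_length - L:
                raise SimulationConfigError(
                    f"motif at {ev.position} does not fit in region"
                )
            intervals.append((ev.position, ev.position + L, ev.motif_id))
        intervals.sort()
        for (s1, e1, m1), (s2, e2, m2) in zip(intervals, intervals[1:]):
            if s2 < e1 and m1 != m2:
                raise SimulationConfigError(
                    f"planted motifs {m1} and {m2} overlap"
                )


@dataclass(frozen=True)
class TruthLog:
    """Planted events plus intended presence per motif per leaf."""

    events: tuple[PlantedEvent, ...]
    presence: Mapping[str, Mapping[str, int]]  # motif_id -> leaf -> 0/1
    positions: Mapping[str, int]  # motif_id -> region offset


def simulate_region(config: SimulationConfig) -> tuple[RegionAlignment, TruthLog]:
    """Evolve one region along the tree; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    bg = np.asarray(config.background, dtype=float)
    L = config.region_length

    consensus_codes = {
        mid: np.array([BASES.index(b) for b in m.consensus], dtype=np.int8)
        for mid, m in config.motifs.items()
    }
    events_at: dict[str, list[PlantedEvent]] = {}
    for ev in config.planted_events:
        events_at.setdefault(ev.edge, []).append(ev)

    seqs: dict[str, np.ndarray] = {}
    motif_state: dict[str, dict[str, int]] = {}
    presence: dict[str, dict[str, int]] = {m: {} for m in config.motifs}

    def apply_events(label: str, seq: np.ndarray, state: dict[str, int]):
        for ev in events_at.get(label, []):
            codes = consensus_codes[ev.motif_id]
            if ev.type == "gain":
                seq[ev.position : ev.position + codes.size] = codes
                state[ev.motif_id] = 1
            else:
                seq[ev.position : ev.position + codes.size] = rng.choice(
                    4, size=codes.size, p=bg
                )
                state[ev.motif_id] = 0

    def walk(label: str, parent: str | None):
        if parent is None:
            seq = rng.choice(4, size=L, p=bg).astype(np.int8)
            state = {m: 0 for m in config.motifs}
        else:
            seq = seqs[parent].copy()
            state = dict(motif_state[parent])
            p_sub = 1.0 - np.exp(-config.substitution_rate * tree.branch_length(label))
            mask = rng.random(L) < p_sub
            if mask.any():
                shifts = rng.integers(1, 4, size=int(mask.sum()))
                seq[mask] = (seq[mask] + shifts) % 4
        apply_events(label, seq, state)
        seqs[label] = seq
        motif_state[label] = state
        if tree.is_leaf(label):
            for m in config.motifs:
                presence[m][label] = state[m]
        for child in tree.children(label):
            walk(child, label)

    walk(tree.root_label, None)

    species = tree.leaf_labels
    rows = tuple("".join(BASES[c] for c in seqs[sp]) for sp in species)
    alignment = RegionAlignment(species=species, rows=rows, anchor=("chrSim", 1))
    truth = TruthLog(
        events=config.planted_events,
        presence={m: dict(v) for m, v in presence.items()},
        positions={ev.motif_id: ev.position for ev in config.planted_events},
    )
    return alignment, truth


def default_gain_config(seed: int, substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
                        edge: str = "euarchontoglires", position: int = 240) -> SimulationConfig:
    """The standard single-gain scenario used by the recovery suite."""
    motif = default_simulation_motif()
    return SimulationConfig(
        tree=default_simulation_tree(),
        motifs={motif.motif_id: motif},
        planted_events=(PlantedEvent(edge, "gain", motif.motif_id, position),),
        substitution_rate=substitution_rate,
        seed=seed,
    )
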