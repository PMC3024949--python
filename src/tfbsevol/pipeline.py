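"""End-to-end inference: scan, group, reconstruct, rank.

Glue over the pipeline stages: scan every species row of an alignment with
a matrix library, group hits into homologous site characters, reconstruct
gain/loss by parsimony per character, and partition events into ranked
modules.  Nothing here adds model behaviour beyond composing the stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .homology import RegionAlignment, SiteCharacter, build_character_matrix
from .modules import ScoredModule, detect_modules
from .motifs import MotifHit, MotifMatrix, scan_many
from .parsimony import Event, EventLabeling, SpeciesTree, extract_events, fitch_reconstruct


@dataclass(frozen=True)
class PipelineResult:
    hits_per_species: Mapping[str, tuple[MotifHit, ...]]
    characters: tuple[SiteCharacter, ...]
    labelings: Mapping[str, EventLabeling]
    events: tuple[Event, ...]
    modules: tuple[ScoredModule, ...]


def infer_site_evolution(
    alignment: RegionAlignment,
    tree: SpeciesTree,
    matrices: Sequence[MotifMatrix],
    family_map: Mapping[str, str] | None = None,
    pvalue: float = 1e-4,
    overlap_fraction: float = 0.5,
    resolution: str = "DELTRAN",
    module_score: str = "min",
) -> PipelineResult:
    """Run the full inference on one aligned region.

    ``family_map`` defaults to each matrix's own factor family.  Every
    alignment species must be a leaf of ``tree``.
    """
    if family_map is None:
        family_map = {m.motif_id: m.factor_family or m.motif_id for m in matrices}
    missing = set(alignment.species) - set(tree.leaf_labels)
    if missing:
        raise ValueError(f"alignment species not in tree: {sorted(missing)}")

    hits_per_species = {
        sp: tuple(
            scan_many(matrices, alignment.ungapped(sp), sequence_id=sp, pvalue=pvalue)
        )
        for sp in alignment.species
    }
    characters = build_character_matrix(
        alignment, hits_per_species, family_map, overlap_fraction=overlap_fraction
    )
    labelings = {}
    events: list[Event] = []
    for char in characters:
        presence = {leaf: char.presence.get(leaf, 0) for leaf in tree.leaf_labels}
        labeling = fitch_reconstruct(
            tree, presence, resolution=resolution, character_id=char.character_id
        )
        labelings[char.character_id] = labeling
        events.extend(extract_events(labeling, tree))
    modules = detect_modules(events, tree, characters, score=module_score)
    return PipelineResult(
        hits_per_species=hits_per_species,
        characters=tuple(characters),
        labelings=labelings,
        events=tuple(events),
        modules=tuple(modules),
    )


def recovered_planted_gain(result: PipelineResult, edge: str, position: int,
                           motif_length: int, family: str) -> bool:
    """Did the pipeline place a gain of the planted site on the planted edge?

    Looks for a character of the planted family overlapping the planted
    interval (alignment columns coincide with region offsets when the
    simulation has no indels) whose reconstruction gains exactly on
    ``edge``.
    """
    for char in result.characters:
        if char.factor_family != family:
            continue
        if char.column_end <= position or char.column_start >= position + motif_length:
            continue
        labeling = result.labelings[char.character_id]
        if labeling.gains == (edge,) and not labeling.losses:
            return True
    return False
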