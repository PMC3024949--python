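"""UCSC custom-track output for hits, curated sites and ranked modules.

Everything downstream is a plain-text custom track: one ``track name=...``
line followed by BED records, suitable for upload to a genome browser.
Ungapped hit offsets are mapped to genomic coordinates through an anchor
(chrom, 1-based genomic position of offset 0); scores are scaled to UCSC's
0-1000 convention relative to the matrix score range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .homology import RegionAlignment, SiteCharacter, columns_to_seq
from .modules import ScoredModule
from .motifs import MotifHit, MotifMatrix

VISIBILITIES = ("hide", "dense", "pack", "full")


class CoordinateError(ValueError):
    """A feature falls outside the anchored region."""


@dataclass(frozen=True)
class TrackSpec:
    """Presentation attributes of one custom track."""

    name: str
    description: str
    visibility: str = "dense"
    color: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("track name must be non-empty")
        if len(self.name) > 15:
            raise ValueError("track name must be at most 15 characters")
        if self.visibility not in VISIBILITIES:
            raise ValueError(f"visibility must be one of {VISIBILITIES}")
        if any(not 0 <= c <= 255 for c in self.color):
            raise ValueError("color components must be in 0..255")

    def track_line(self) -> str:
        r, g, b = self.color
        return (
            f'track name="{self.name}" description="{self.description}" '
            f"visibility={self.visibility} color={r},{g},{b}"
        )


def scaled_bed_score(score: float, min_score: float, max_score: float) -> int:
    """Map a bit score into UCSC's 0-1000 display range."""
    if max_score <= min_score:
        return 0
    frac = (score - min_score) / (max_score - min_score)
    return int(round(1000 * min(1.0, max(0.0, frac))))


def write_hit_track(
    hits: Sequence[MotifHit],
    anchor: tuple[str, int],
    spec: TrackSpec,
    matrices: Mapping[str, MotifMatrix],
    region_length: int | None = None,
) -> str:
    """BED6 custom track for motif hits anchored at (chrom, 1-based start)."""
    chrom, start1 = anchor
    offset = start1 - 1
    lines = [spec.track_line()]
    rows = []
    for h in hits:
        if h.start < 0 or (region_length is not None and h.end > region_length):
            raise CoordinateError(
                f"hit {h.motif_id}@{h.start} outside anchored region"
            )
        m = matrices.get(h.motif_id)
        if m is None:
            raise ValueError(f"no matrix for hit motif {h.motif_id!r}")
        bed_score = scaled_bed_score(h.score, m.min_score, m.max_score)
        rows.append(
            (chrom, offset + h.start, offset + h.end, h.motif_id, bed_score, h.strand)
        )
    rows.sort()
    for chrom_, s, e, name, score, strand in rows:
        lines.append(f"{chrom_}\t{s}\t{e}\t{name}\t{score}\t{strand}")
    return "\n".join(lines) + "\n"


def write_module_tracks(
    modules: Sequence[ScoredModule],
    characters: Sequence[SiteCharacter],
    alignment: RegionAlignment,
    reference_species: str,
    anchor: tuple[str, int],
    visibility: str = "dense",
) -> str:
    """One custom track per module, ordered by rank (track k = rank k).

    Member character spans are projected from alignment columns onto the
    reference species row and emitted as BED4 blocks.  Members whose span
    contains no reference-species sequence are skipped in that track.
    """
    by_id = {c.character_id: c for c in characters}
    chrom, start1 = anchor
    offset = start1 - 1
    ref_row = alignment.row(reference_species)
    sections = []
    for module in sorted(modules, key=lambda m: m.rank):
        spec = TrackSpec(
            name=f"module_{module.rank}",
            description=(
                f"{module.event_type} at {module.event_edge}, "
                f"BLS {module.bls:.3f}"
            ),
            visibility=visibility,
        )
        lines = [spec.track_line()]
        rows = []
        for member in module.members:
            char = by_id[member]
            seq_start, seq_len = columns_to_seq(
                ref_row, char.column_start, char.column_end
            )
            if seq_len == 0:
                continue
            rows.append(
                (chrom, offset + seq_start, offset + seq_start + seq_len, member)
            )
        rows.sort()
        for chrom_, s, e, name in rows:
            lines.append(f"{chrom_}\t{s}\t{e}\t{name}")
        sections.append("\n".join(lines))
    return "\n".join(sections) + "\n" if sections else ""


def parse_bed_track(text: str) -> list[tuple]:
    """Re-parse an emitted custom track: (chrom, start, end, name[, score, strand])."""
    feats = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("track"):
            continue
        fields = ln.split("\t")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        if len(fields) >= 6:
            feats.append((chrom, start, end, name, int(fields[4]), fields[5]))
        else:
            feats.append((chrom, start, end, name))
    return feats
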