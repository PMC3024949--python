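"""Cross-species homology of predicted binding sites.

Hits are found per species on ungapped sequence; to compare them across
species they are projected into the column space of the multiple alignment
of the orthologous region.  Two hits are taken to be homologous when the
factors are known homologs (same factor family, supplied as an explicit
motif -> family table) and the projected intervals overlap reciprocally by
at least a configurable fraction (default 0.5) — the operational reading of
"essentially the same genomic coordinates".  Single-linkage clustering over
that relation yields one binary presence/absence character per homologous
site, anchored to alignment columns, which is what the parsimony stage
consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

from Bio import AlignIO

from .motifs import MotifHit

GAP = "-"


class CoordinateError(ValueError):
    """An ungapped offset lies beyond the ungapped length of a row."""


@dataclass(frozen=True)
class RegionAlignment:
    """A gapped multi-species alignment of one regulatory region."""

    species: tuple[str, ...]
    rows: tuple[str, ...]
    anchor: tuple[str, int] | None = None  # (chrom, 1-based genomic start of row 0)

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rows):
            raise ValueError("one row per species required")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, species: str) -> str:
        try:
            return self.rows[self.species.index(species)]
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None

    def ungapped(self, species: str) -> str:
        return self.row(species).replace(GAP, "")

    @classmethod
    def from_fasta(cls, handle: str | TextIO, anchor=None) -> "RegionAlignment":
        """Aligned multi-FASTA (gap character '-')."""
        if isinstance(handle, str):
            handle = io.StringIO(handle)
        aln = AlignIO.read(handle, "fasta")
        return cls(
            species=tuple(rec.id for rec in aln),
            rows=tuple(str(rec.seq).upper() for rec in aln),
            anchor=anchor,
        )

    @classmethod
    def from_maf(cls, handle: str | TextIO) -> "RegionAlignment":
        """A single MAF block; species = the part of ``src`` before '.'.

        The anchor is taken from the first row (the reference species),
        converting MAF's 0-based start to a 1-based genomic coordinate.
        Multi-block stitching is out of scope.
        """
        if isinstance(handle, str):
            handle = io.StringIO(handle)
        blocks = list(AlignIO.parse(handle, "maf"))
        if len(blocks) != 1:
            raise ValueError(f"expected exactly one MAF block, got {len(blocks)}")
        aln = blocks[0]
        species, rows = [], []
        anchor = None
        for rec in aln:
            name, _, chrom = rec.id.partition(".")
            species.append(name)
            rows.append(str(rec.seq).upper())
            if anchor is None:
                anchor = (chrom or name, int(rec.annotations["start"]) + 1)
        return cls(species=tuple(species), rows=tuple(rows), anchor=anchor)

    def to_fasta(self) -> str:
        out = []
        for sp, row in zip(self.species, self.rows):
            out.append(f">{sp}\n{row}")
        return "\n".join(out) + "\n"


def seq_to_columns(row: str, start: int, length: int) -> tuple[int, int]:
    """Half-open alignment-column interval of an ungapped sub-sequence.

    ``start`` is a 0-based offset into the ungapped content of ``row``; the
    returned interval spans the columns holding the start-th through
    (start+length-1)-th non-gap characters.
    """
    if start < 0 or length < 0:
        raise CoordinateError("start and length must be non-negative")
    seen = 0
    col_start = col_end = None
    for col, ch in enumerate(row):
        if ch == GAP:
            continue
        if seen == start:
            col_start = col
        if seen == start + length - 1:
            col_end = col + 1
            break
        seen += 1
    if length == 0:
        if col_start is None:
            raise CoordinateError(f"offset {start} beyond ungapped length {seen}")
        return col_start, col_start
    if col_start is None or col_end is None:
        raise CoordinateError(
            f"[{start}, {start + length}) beyond ungapped length of row"
        )
    return col_start, col_end


def columns_to_seq(row: str, col_start: int, col_end: int) -> tuple[int, int]:
    """Inverse projection: (ungapped start offset, ungapped length).

    The start offset is the number of non-gap characters strictly before
    ``col_start``; the length counts non-gap characters inside the interval.
    """
    if not (0 <= col_start <= col_end <= len(row)):
        raise CoordinateError("column interval outside alignment")
    before = sum(1 for ch in row[:col_start] if ch != GAP)
    inside = sum(1 for ch in row[col_start:col_end] if ch != GAP)
    return before, inside


@dataclass(frozen=True)
class SiteCharacter:
    """A homology-grouped site: binary presence over species, at columns."""

    character_id: str
    factor_family: str
    column_start: int
    column_end: int
    presence: Mapping[str, int]
    supporting_hits: tuple[MotifHit, ...]
    unalignable: frozenset[str] = frozenset()  # all-gap rows across the span

    def __post_init__(self) -> None:
        if self.column_start >= self.column_end:
            raise ValueError("character span must be non-empty")

    def presence_vector(self, species_order: Sequence[str]) -> tuple[int, ...]:
        return tuple(self.presence[sp] for sp in species_order)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int], frac: float) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def build_character_matrix(
    alignment: RegionAlignment,
    hits_per_species: Mapping[str, Sequence[MotifHit]],
    family_map: Mapping[str, str],
    overlap_fraction: float = 0.5,
) -> list[SiteCharacter]:
    """Group per-species hits into homologous site characters.

    Single-linkage clustering joins two hits iff they share a factor family
    and their alignment-column projections overlap reciprocally by at least
    ``overlap_fraction``.  Every hit ends up in exactly one character; a
    character's span is the union of its members' spans and its presence is
    1 for every species contributing a hit.  Species whose row is entirely
    gaps across the span are scored absent and flagged ``unalignable``.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    items = []  # (family, species, (col_start, col_end), hit)
    for species in sorted(hits_per_species):
        if species not in alignment.species:
            raise ValueError(f"hits reference unknown species {species!r}")
        row = alignment.row(species)
        for hit in sorted(
            hits_per_species[species], key=lambda h: (h.start, h.strand, h.motif_id)
        ):
            try:
                family = family_map[hit.motif_id]
            except KeyError:
                raise ValueError(f"no factor family for motif {hit.motif_id!r}") from None
            span = seq_to_columns(row, hit.start, hit.length)
            items.append((family, species, span, hit))

    # union-find over hits (single linkage)
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][0] != items[j][0]:
                continue
            if _reciprocal_overlap(items[i][2], items[j][2], overlap_fraction):
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(find(i), []).append(i)

    characters = []
    for members in clusters.values():
        family = items[members[0]][0]
        col_start = min(items[i][2][0] for i in members)
        col_end = max(items[i][2][1] for i in members)
        presence = {sp: 0 for sp in alignment.species}
        hits = []
        for i in members:
            presence[items[i][1]] = 1
            hits.append(items[i][3])
        hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand, h.motif_id))
        unalignable = frozenset(
            sp
            for sp in alignment.species
            if set(alignment.row(sp)[col_start:col_end]) == {GAP}
        )
        characters.append(
            (family, col_start, col_end, presence, tuple(hits), unalignable)
        )
    characters.sort(key=lambda c: (c[0], c[1], c[2]))

    out: list[SiteCharacter] = []
    seen_ids: dict[str, int] = {}
    for family, col_start, col_end, presence, hits, unalignable in characters:
        cid = f"{family}:{col_start:06d}"
        if cid in seen_ids:
            seen_ids[cid] += 1
            cid = f"{cid}.{seen_ids[cid]}"
        else:
            seen_ids[cid] = 1
        out.append(
            SiteCharacter(
                character_id=cid,
                factor_family=family,
                column_start=col_start,
                column_end=col_end,
                presence=presence,
                supporting_hits=hits,
                unalignable=unalignable,
            )
        )
    return out


def read_family_map(text: str | TextIO) -> dict[str, str]:
    """TSV of (motif_id, factor_family) pairs; '#' lines are comments."""
    if not isinstance(text, str):
        text = text.read()
    mapping: dict[str, str] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValueError(f"family map line must have 2 columns: {ln!r}")
        mapping[fields[0]] = fields[1]
    return mapping
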