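"""Literature-curated TFBS annotation tables.

Experimentally validated transcription-factor binding sites are collected
from the literature as rows of a tab-separated table: the gene whose
regulatory region the site lies in, the factor (verbatim, possibly a
composite such as ``Nr1b*/2b*; Rar*/Rxr*``), an optional site class and
identifier, the abbreviated citation key(s), and the genomic interval.
Coordinates are 1-based inclusive, mirroring genome-browser display; BED
export converts to 0-based half-open.

A verification marker records whether the nucleotides at the stated genomic
position could be confirmed against the reference assembly: ``+`` means the
reported site sequence matches the reference (``revcom`` in the class column
when it matches on the opposite strand), ``dna_not_matching`` flags a
reported sequence that disagrees with the reference, and conserved-region
rows (factor names like CR1/N2/SRR1, or class ``R()``) describe regions
rather than verified sites.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, TextIO

from Bio.Seq import Seq


class Verification(str, Enum):
    """Outcome of checking a reported site against the reference sequence."""

    CONFIRMED = "confirmed"
    REGION_ONLY = "region_only"
    REVCOM_CONFIRMED = "revcom_confirmed"
    MISMATCH = "mismatch"
    UNCHECKED = "unchecked"


class CuratedTableError(ValueError):
    """Malformed curated-table input; message names the offending row."""


class CoordinateError(ValueError):
    """A genomic interval falls outside the available reference sequence."""


HEADER = (
    "gene_region",
    "factor_name",
    "site_class",
    "identifier",
    "abbrev_ref",
    "ref_id",
    "chrom",
    "start",
    "end",
    "marker",
)

#: factor names that denote conserved (sub)regions rather than single sites
_REGION_FACTOR = re.compile(r"^(CR|N|SRR)\d")


def _is_region_row(factor_name: str, site_class: str) -> bool:
    return "R()" in site_class or bool(_REGION_FACTOR.match(factor_name))


@dataclass(frozen=True)
class CuratedSiteRecord:
    """One curated binding site or conserved region.

    ``start``/``end`` are 1-based inclusive genomic coordinates on ``chrom``.
    ``abbrev_ref`` may hold several citation keys separated by ``;``.
    """

    gene_region: str
    factor_name: str
    site_class: str
    identifier: str
    abbrev_ref: str
    ref_id: str
    chrom: str
    start: int
    end: int
    verified: Verification

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.abbrev_ref:
            raise ValueError("abbrev_ref must be non-empty")
        if self.start > self.end:
            raise ValueError(f"start > end ({self.start} > {self.end})")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")
        if self.verified is Verification.REVCOM_CONFIRMED and "revcom" not in self.site_class:
            raise ValueError("revcom_confirmed requires a 'revcom' site class")
        if self.verified is Verification.REGION_ONLY and not _is_region_row(
            self.factor_name, self.site_class
        ):
            raise ValueError("region_only requires an R() class or CR*/N*/SRR* factor")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _verified_from_marker(
    marker: str, site_class: str, factor_name: str, rowno: int
) -> Verification:
    marker = marker.strip()
    if marker == "+":
        if "revcom" in site_class:
            return Verification.REVCOM_CONFIRMED
        return Verification.CONFIRMED
    if marker == "dna_not_matching":
        return Verification.MISMATCH
    if marker == "":
        if _is_region_row(factor_name, site_class):
            return Verification.REGION_ONLY
        return Verification.UNCHECKED
    raise CuratedTableError(f"row {rowno}: unknown verification marker {marker!r}")


def parse_curated_table(table: str | TextIO) -> list[CuratedSiteRecord]:
    """Parse a curated-site TSV into records, preserving row order.

    The header must carry the ten schema columns.  A missing trailing marker
    cell is read as the empty marker.  Malformed coordinates, inverted
    intervals and unknown markers raise :class:`CuratedTableError` naming the
    1-based data row.
    """
    handle = io.StringIO(table) if isinstance(table, str) else table
    reader = csv.reader(handle, delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise CuratedTableError("empty input: header row required") from None
    header = tuple(h.strip().lower() for h in header)
    if header != HEADER:
        raise CuratedTableError(
            f"unexpected header {header!r}; expected {HEADER!r}"
        )
    records: list[CuratedSiteRecord] = []
    for rowno, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) == len(HEADER) - 1:  # trailing empty marker cell omitted
            row = row + [""]
        if len(row) != len(HEADER):
            raise CuratedTableError(
                f"row {rowno}: expected {len(HEADER)} columns, got {len(row)}"
            )
        (region, factor, site_class, ident, ref, ref_id, chrom, start_s, end_s, marker) = (
            c.strip() for c in row
        )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise CuratedTableError(
                f"row {rowno}: malformed coordinate ({start_s!r}, {end_s!r})"
            ) from None
        verified = _verified_from_marker(marker, site_class, factor, rowno)
        try:
            rec = CuratedSiteRecord(
                gene_region=region,
                factor_name=factor,
                site_class=site_class,
                identifier=ident,
                abbrev_ref=ref,
                ref_id=ref_id,
                chrom=chrom,
                start=start,
                end=end,
                verified=verified,
            )
        except ValueError as exc:
            raise CuratedTableError(f"row {rowno}: {exc}") from None
        records.append(rec)
    return records


def _marker_for(record: CuratedSiteRecord) -> str:
    if record.verified in (Verification.CONFIRMED, Verification.REVCOM_CONFIRMED):
        return "+"
    if record.verified is Verification.MISMATCH:
        return "dna_not_matching"
    return ""


def render_curated_table(records: Iterable[CuratedSiteRecord]) -> str:
    """Inverse of :func:`parse_curated_table` (round-trips valid records)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(HEADER)
    for rec in records:
        writer.writerow(
            [
                rec.gene_region,
                rec.factor_name,
                rec.site_class,
                rec.identifier,
                rec.abbrev_ref,
                rec.ref_id,
                rec.chrom,
                rec.start,
                rec.end,
                _marker_for(rec),
            ]
        )
    return out.getvalue()


def count_distinct_references(records: Iterable[CuratedSiteRecord]) -> int:
    """Distinct citation keys, splitting multi-reference cells on ``;``."""
    keys: set[str] = set()
    for rec in records:
        for part in rec.abbrev_ref.split(";"):
            part = part.strip()
            if part:
                keys.add(part)
    return len(keys)


@dataclass(frozen=True)
class ReferenceSequence:
    """A slice of reference assembly sequence anchored at a genomic position.

    ``name`` encodes the origin as ``chrom:origin`` (1-based position of the
    first residue), the convention used by the packaged FASTA fixtures.
    """

    name: str
    residues: str
    origin_coordinate: int

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be non-empty")
        if self.origin_coordinate < 1:
            raise ValueError("origin_coordinate is 1-based; must be >= 1")

    @property
    def chrom(self) -> str:
        return self.name.split(":", 1)[0]

    @property
    def end_coordinate(self) -> int:
        """1-based inclusive coordinate of the last residue."""
        return self.origin_coordinate + len(self.residues) - 1

    def covers(self, chrom: str, start: int, end: int) -> bool:
        return (
            chrom == self.chrom
            and start >= self.origin_coordinate
            and end <= self.end_coordinate
        )

    def slice(self, start: int, end: int) -> str:
        """Residues for the 1-based inclusive interval [start, end]."""
        if not self.covers(self.chrom, start, end):
            raise CoordinateError(
                f"[{start}, {end}] outside {self.name} "
                f"({self.origin_coordinate}-{self.end_coordinate})"
            )
        off = start - self.origin_coordinate
        return self.residues[off : off + (end - start + 1)]


def load_reference_fasta(handle: str | TextIO) -> list[ReferenceSequence]:
    """Read reference slices from FASTA whose ids encode ``chrom:origin``."""
    from Bio import SeqIO

    if isinstance(handle, str):
        handle = io.StringIO(handle)
    refs = []
    for rec in SeqIO.parse(handle, "fasta"):
        chrom, _, origin = rec.id.partition(":")
        if not origin:
            raise ValueError(f"reference id {rec.id!r} must encode chrom:origin")
        refs.append(ReferenceSequence(rec.id, str(rec.seq).upper(), int(origin)))
    return refs


def find_reference(
    refs: Sequence[ReferenceSequence], record: CuratedSiteRecord
) -> ReferenceSequence:
    """The slice covering a record's interval, or :class:`CoordinateError`."""
    for ref in refs:
        if ref.covers(record.chrom, record.start, record.end):
            return ref
    raise CoordinateError(
        f"no reference slice covers {record.chrom}:{record.start}-{record.end}"
    )


def verify_site_sequence(
    record: CuratedSiteRecord, ref: ReferenceSequence, reported_site: str
) -> Verification:
    """Check the reported binding-site sequence against the reference.

    Returns ``confirmed`` when the reference slice at the record's interval
    equals ``reported_site`` (case-insensitive), ``revcom_confirmed`` when it
    equals its reverse complement, and ``mismatch`` otherwise.
    """
    if record.chrom != ref.chrom or not ref.covers(record.chrom, record.start, record.end):
        raise CoordinateError(
            f"{record.chrom}:{record.start}-{record.end} outside reference {ref.name}"
        )
    if len(reported_site) != record.length:
        raise ValueError(
            f"reported site length {len(reported_site)} != interval length {record.length}"
        )
    genomic = ref.slice(record.start, record.end).upper()
    reported = reported_site.upper()
    if genomic == reported:
        return Verification.CONFIRMED
    if genomic == str(Seq(reported).reverse_complement()):
        return Verification.REVCOM_CONFIRMED
    return Verification.MISMATCH


def _bed_name(record: CuratedSiteRecord) -> str:
    parts = [record.abbrev_ref.replace("; ", ";"), record.factor_name]
    if record.identifier:
        parts.append(record.identifier)
    return "_".join(re.sub(r"\s+", "_", p) for p in parts if p)


def curated_to_bed(
    records: Iterable[CuratedSiteRecord],
    track_name: str,
    track_description: str,
    visibility: str = "dense",
) -> str:
    """Render records as a UCSC custom track (track line + BED4).

    1-based inclusive table coordinates become 0-based half-open BED
    intervals; features are named ``abbrevRef_factor[_identifier]`` with
    internal whitespace replaced by ``_``; lines are sorted by
    (chrom, start).
    """
    lines = [
        f'track name="{track_name}" description="{track_description}" '
        f"visibility={visibility}"
    ]
    feats = sorted(records, key=lambda r: (r.chrom, r.start, r.end, _bed_name(r)))
    for rec in feats:
        lines.append(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{_bed_name(rec)}")
    return "\n".join(lines) + "\n"
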