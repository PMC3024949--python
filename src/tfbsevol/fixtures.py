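"""Packaged curated-site fixtures and their synthetic reference slices.

The curated table of experimentally validated Oct4/Sox2/Nanog binding sites
ships with the package as a TSV (``data/curated_sites.tsv``).  The genome
slices it is verified against are synthetic stand-ins for the mm9 assembly:
random sequence generated from a fixed internal seed, constructed so that
every '+' row verifies as ``confirmed``, the ``revcom`` row as
``revcom_confirmed`` and the ``dna_not_matching`` row as ``mismatch``.
They exercise the verification machinery at desk scale; they carry no real
mm9 sequence.  The generated files are also shipped
(``data/synthetic_mm9_slices.fa``, ``data/synthetic_reported_sites.tsv``)
and regenerating them is byte-deterministic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .curation import (
    CuratedSiteRecord,
    ReferenceSequence,
    Verification,
    load_reference_fasta,
    parse_curated_table,
)
from .motifs import BASES

#: internal seed for the synthetic reference slices (fixture constant)
FIXTURE_SEED = 20101229
_PAD = 10  # residues of context around each verified interval

_SHIFT = str.maketrans("ACGT", "CGTA")  # base cycle used to plant mismatches


def _data_text(name: str) -> str:
    return resources.files("tfbsevol.data").joinpath(name).read_text()


def load_curated_records() -> list[CuratedSiteRecord]:
    """The packaged curated table of validated binding sites."""
    return parse_curated_table(_data_text("curated_sites.tsv"))


def _verifiable(records):
    return [
        (i, r)
        for i, r in enumerate(records)
        if r.verified
        in (Verification.CONFIRMED, Verification.REVCOM_CONFIRMED, Verification.MISMATCH)
    ]


def synthesize_reference(
    records: list[CuratedSiteRecord], seed: int = FIXTURE_SEED
) -> tuple[list[ReferenceSequence], dict[int, str]]:
    """Deterministic synthetic reference slices plus reported-site strings.

    Returns the slices and a map from table row index (0-based) to the
    reported binding-site sequence: equal to the reference slice for
    confirmed rows, its reverse complement for revcom rows, and a shifted
    (mismatching) variant for dna_not_matching rows.
    """
    from Bio.Seq import Seq

    rng = np.random.default_rng(seed)
    verifiable = _verifiable(records)

    windows: dict[str, list[list[int]]] = {}
    for _, rec in verifiable:
        lo, hi = rec.start - _PAD, rec.end + _PAD
        merged = windows.setdefault(rec.chrom, [])
        for w in merged:
            if lo <= w[1] + 1 and hi >= w[0] - 1:
                w[0], w[1] = min(w[0], lo), max(w[1], hi)
                break
        else:
            merged.append([lo, hi])
    # collapse any windows that became adjacent after extension
    refs: list[ReferenceSequence] = []
    for chrom in sorted(windows):
        spans = sorted(tuple(w) for w in windows[chrom])
        merged: list[list[int]] = []
        for lo, hi in spans:
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            seq = "".join(BASES[c] for c in rng.choice(4, size=hi - lo + 1))
            refs.append(ReferenceSequence(f"{chrom}:{lo}", seq, lo))

    reported: dict[int, str] = {}
    for idx, rec in verifiable:
        ref = next(r for r in refs if r.covers(rec.chrom, rec.start, rec.end))
        genomic = ref.slice(rec.start, rec.end)
        if rec.verified is Verification.CONFIRMED:
            reported[idx] = genomic
        elif rec.verified is Verification.REVCOM_CONFIRMED:
            site = str(Seq(genomic).reverse_complement())
            if site == genomic:  # palindromic slice would be read as confirmed
                raise AssertionError("synthetic slice unexpectedly palindromic")
            reported[idx] = site
        else:
            site = genomic.translate(_SHIFT)
            if site == str(Seq(genomic).reverse_complement()):
                raise AssertionError("planted mismatch coincides with revcom")
            reported[idx] = site
    return refs, reported


def render_reference_fasta(refs: list[ReferenceSequence]) -> str:
    out = []
    for ref in refs:
        out.append(f">{ref.name}")
        for i in range(0, len(ref.residues), 70):
            out.append(ref.residues[i : i + 70])
    return "\n".join(out) + "\n"


def render_reported_sites(reported: dict[int, str]) -> str:
    lines = ["row_index\treported_site"]
    for idx in sorted(reported):
        lines.append(f"{idx}\t{reported[idx]}")
    return "\n".join(lines) + "\n"


def parse_reported_sites(text: str) -> dict[int, str]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines[0] != "row_index\treported_site":
        raise ValueError("unexpected reported-sites header")
    out = {}
    for ln in lines[1:]:
        idx, site = ln.split("\t")
        out[int(idx)] = site
    return out


def make_table2_fixture() -> tuple[
    list[CuratedSiteRecord], list[ReferenceSequence], dict[int, str]
]:
    """The packaged curated table with its synthetic verification fixtures.

    Returns (records, reference slices, row index -> reported site).  Reads
    the shipped static files; these are byte-identical to what
    :func:`synthesize_reference` regenerates from the table.
    """
    records = load_curated_records()
    refs = load_reference_fasta(_data_text("synthetic_mm9_slices.fa"))
    reported = parse_reported_sites(_data_text("synthetic_reported_sites.tsv"))
    return records, refs, reported


def write_fixture_files(directory) -> None:
    """Regenerate the synthetic static fixture files into ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    records = load_curated_records()
    refs, reported = synthesize_reference(records)
    (directory / "synthetic_mm9_slices.fa").write_text(render_reference_fasta(refs))
    (directory / "synthetic_reported_sites.tsv").write_text(
        render_reported_sites(reported)
    )
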