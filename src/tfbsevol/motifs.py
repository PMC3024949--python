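"""Position-specific scoring matrices and sequence scanning.

A binding-site model is a count matrix over the four bases.  With a
background distribution ``b`` and a pseudocount ``c`` distributed by
background, position ``i`` scores base ``x`` as

    logodds[i][x] = log2( (n_ix + c * b_x) / (N_i + c) / b_x )

in bits, where ``N_i`` is the column count sum.  A window of length L scores
the sum over positions; hits are windows whose score clears a threshold
given either in bits or as a p-value cutoff.

P-values are exact under the background model: the full score distribution
over random words of length L is computed by dynamic programming on a
discretized score lattice (default pitch 1/1000 bit), and
``P(score >= s)`` is read off the survival function.  E-values multiply by
the number of scanned windows, both strands counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_GRANULARITY = 1e-3  # bits per lattice step in the p-value DP


class DegenerateMatrixError(ValueError):
    """A matrix column has zero total count and no pseudocount to rescue it."""


def encode(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A=0..T=3, anything else = 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


@dataclass
class MotifMatrix:
    """A count matrix with its derived log-odds scores (bits)."""

    motif_id: str
    factor_family: str
    counts: np.ndarray  # (L, 4) non-negative
    background: np.ndarray  # (4,) strictly positive, sums to 1
    pseudocount: float
    logodds: np.ndarray = field(repr=False)  # (L, 4) bits
    _survival_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    @property
    def information_content(self) -> float:
        """Total information content in bits (relative entropy to background)."""
        probs = (self.counts + self.pseudocount * self.background) / (
            self.counts.sum(axis=1, keepdims=True) + self.pseudocount
        )
        return float((probs * np.log2(probs / self.background)).sum())

    def reverse_complement(self) -> "MotifMatrix":
        rc_counts = self.counts[::-1, ::-1].copy()
        return build_matrix(
            rc_counts,
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            motif_id=self.motif_id + "_rc",
            factor_family=self.factor_family,
        )


def build_matrix(
    counts,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    motif_id: str = "motif",
    factor_family: str = "",
) -> MotifMatrix:
    """Turn an L x 4 count matrix into a log-odds scoring matrix.

    ``background`` defaults to uniform.  The pseudocount is distributed
    across bases in proportion to the background.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
        raise ValueError("counts must be an L x 4 matrix with L >= 1")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    background = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    if background.shape != (4,) or (background <= 0).any():
        raise ValueError("background must be 4 strictly positive probabilities")
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    colsums = counts.sum(axis=1)
    if ((colsums == 0) & (pseudocount == 0)).any():
        raise DegenerateMatrixError(
            "column with zero total count and zero pseudocount"
        )
    probs = (counts + pseudocount * background) / (colsums + pseudocount)[:, None]
    logodds = np.log2(probs / background)
    return MotifMatrix(
        motif_id=motif_id,
        factor_family=factor_family,
        counts=counts,
        background=background,
        pseudocount=pseudocount,
        logodds=logodds,
    )


def parse_matrices(text: str | TextIO, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Read count matrices from JASPAR-style plain text.

    Format: a ``>motif_id factor_family`` header followed by four labeled
    rows (A/C/G/T), optionally with JASPAR's square brackets::

        >M001 POU
        A [ 10  0  3 ]
        C [  0 12  1 ]
        ...
    """
    if not isinstance(text, str):
        text = text.read()
    matrices = []
    header = None
    rows: dict[str, list[float]] = {}

    def flush():
        if header is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise ValueError(f"matrix {header[0]}: missing rows {sorted(missing)}")
        counts = np.array([rows[b] for b in BASES], dtype=float).T
        matrices.append(
            build_matrix(
                counts,
                pseudocount=pseudocount,
                motif_id=header[0],
                factor_family=header[1],
            )
        )

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1].strip() if len(parts) > 1 else "")
            rows = {}
        else:
            m = re.match(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]+?)\s*\]?$", line)
            if not m or header is None:
                raise ValueError(f"unparseable matrix line: {line!r}")
            rows[m.group(1)] = [float(x) for x in m.group(2).split()]
    flush()
    return matrices


@dataclass(frozen=True)
class MotifHit:
    """One scored window on either strand of an ungapped sequence."""

    motif_id: str
    sequence_id: str
    start: int  # 0-based offset in the ungapped sequence (forward coords)
    length: int
    strand: str  # '+' or '-'
    score: float  # bits
    pvalue: float
    evalue: float

    @property
    def end(self) -> int:
        return self.start + self.length


def score_distribution(
    matrix: MotifMatrix, granularity: float = DEFAULT_GRANULARITY
) -> tuple[int, np.ndarray]:
    """Survival function of the score under the background model.

    Returns ``(base, survival)`` where ``survival[j]`` is the probability
    that a random word's lattice score is at least ``(base + j) *
    granularity``.  Per-position scores are rounded to the nearest lattice
    step; the worst-case score discretization error is L * granularity / 2.
    """
    key = granularity
    cached = matrix._survival_cache.get(key)
    if cached is not None:
        return cached
    lattice = np.rint(matrix.logodds / granularity).astype(np.int64)  # (L, 4)
    mins = lattice.min(axis=1)
    maxs = lattice.max(axis=1)
    base = int(mins.sum())
    width = int((maxs - mins).sum()) + 1
    dist = np.zeros(width)
    dist[0] = 1.0
    top = 1  # number of occupied entries so far
    for i in range(matrix.length):
        span = int(maxs[i] - mins[i])
        new = np.zeros(top + span)
        for b in range(4):
            off = int(lattice[i, b] - mins[i])
            new[off : off + top] += dist[:top] * matrix.background[b]
        dist = np.zeros(width)
        top += span
        dist[:top] = new
    survival = np.cumsum(dist[::-1])[::-1]
    out = (base, survival)
    matrix._survival_cache[key] = out
    return out


def exact_pvalue(
    matrix: MotifMatrix, score: float, granularity: float = DEFAULT_GRANULARITY
) -> float:
    """P(random background word of length L scores >= ``score``).

    Computed on the discretized score lattice; exact up to lattice rounding
    (see :func:`score_distribution`).  Scores at or below the matrix minimum
    give exactly 1, scores above the maximum exactly 0.
    """
    if score <= matrix.min_score:
        return 1.0
    if score > matrix.max_score:
        return 0.0
    base, survival = score_distribution(matrix, granularity)
    idx = int(np.rint(score / granularity)) - base
    idx = max(1, min(idx, survival.size - 1))
    return float(min(1.0, survival[idx]))


def _window_scores(logodds: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all length-L windows plus a validity mask (no N)."""
    L = logodds.shape[0]
    n_win = codes.size - L + 1
    # pad a zero column so code 4 (N) is scoreable; validity tracked separately
    lo = np.concatenate([logodds, np.zeros((L, 1))], axis=1)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for i in range(L):
        window_codes = codes[i : i + n_win]
        scores += lo[i, window_codes]
        valid &= window_codes != 4
    return scores, valid


def scan_sequence(
    matrix: MotifMatrix,
    seq: str,
    sequence_id: str = "seq",
    score_threshold: float | None = None,
    pvalue: float | None = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[MotifHit]:
    """Scan both strands of ``seq`` for hits of ``matrix``.

    Exactly one of ``score_threshold`` (bits) or ``pvalue`` (cutoff) must be
    given.  Windows containing non-ACGT characters are skipped and excluded
    from the E-value denominator.  Hits come back sorted by (start, strand);
    a minus-strand hit's ``start`` is the window start in forward
    coordinates.
    """
    if (score_threshold is None) == (pvalue is None):
        raise ValueError("give exactly one of score_threshold or pvalue")
    L = matrix.length
    codes = encode(seq)
    if codes.size < L:
        return []
    fwd_scores, valid = _window_scores(matrix.logodds, codes)
    # reverse strand: score the reverse complement of each window, which
    # equals scoring the forward window with the reverse-complemented matrix
    rc_logodds = matrix.logodds[::-1, ::-1]
    rev_scores, _ = _window_scores(rc_logodds, codes)

    n_windows = int(valid.sum())
    score_distribution(matrix, granularity)  # warm the cache once

    def pval(s: float) -> float:
        return exact_pvalue(matrix, s, granularity)

    hits = []
    for strand, scores in (("+", fwd_scores), ("-", rev_scores)):
        for start in np.flatnonzero(valid):
            s = float(scores[start])
            p = pval(s)
            if score_threshold is not None:
                if s < score_threshold:
                    continue
            elif p > pvalue:
                continue
            hits.append(
                MotifHit(
                    motif_id=matrix.motif_id,
                    sequence_id=sequence_id,
                    start=int(start),
                    length=L,
                    strand=strand,
                    score=s,
                    pvalue=p,
                    evalue=p * 2 * n_windows,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_many(
    matrices: Iterable[MotifMatrix],
    seq: str,
    sequence_id: str = "seq",
    **kwargs,
) -> list[MotifHit]:
    """Scan one sequence with several matrices; hits sorted by (start, strand)."""
    hits: list[MotifHit] = []
    for m in matrices:
        hits.extend(scan_sequence(m, seq, sequence_id=sequence_id, **kwargs))
    hits.sort(key=lambda h: (h.start, h.strand, h.motif_id))
    return hits


HIT_FIELDS = (
    "motif_id",
    "sequence_id",
    "start",
    "length",
    "strand",
    "score",
    "pvalue",
    "evalue",
)


def hits_to_tsv(hits: Sequence[MotifHit]) -> str:
    lines = ["\t".join(HIT_FIELDS)]
    for h in hits:
        lines.append(
            f"{h.motif_id}\t{h.sequence_id}\t{h.start}\t{h.length}\t{h.strand}"
            f"\t{h.score:.4f}\t{h.pvalue:.6g}\t{h.evalue:.6g}"
        )
    return "\n".join(lines) + "\n"


def hits_from_tsv(text: str | TextIO) -> list[MotifHit]:
    if not isinstance(text, str):
        text = text.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or tuple(lines[0].split("\t")) != HIT_FIELDS:
        raise ValueError("hits TSV must start with the standard header")
    hits = []
    for ln in lines[1:]:
        motif_id, seq_id, start, length, strand, score, p, e = ln.split("\t")
        hits.append(
            MotifHit(motif_id, seq_id, int(start), int(length), strand,
                     float(score), float(p), float(e))
        )
    return hits
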