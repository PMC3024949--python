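"""Scoring matrices, scanning and exact p-values."""

import math

import numpy as np
import pytest

from tfbsevol.motifs import (
    DegenerateMatrixError,
    build_matrix,
    exact_pvalue,
    hits_from_tsv,
    hits_to_tsv,
    parse_matrices,
    scan_sequence,
)

from conftest import enumerate_word_scores


def random_matrix(rng, L):
    counts = rng.integers(0, 40, size=(L, 4)).astype(float)
    counts[np.arange(L), rng.integers(0, 4, size=L)] += 1  # no all-zero column
    bg = rng.random(4) + 0.2
    bg /= bg.sum()
    return build_matrix(counts, background=bg, motif_id=f"rand{L}")


class TestBuildMatrix:
    def test_uniform_counts_give_zero_logodds(self):
        m = build_matrix(np.full((5, 4), 5.0), pseudocount=2.0)
        assert np.allclose(m.logodds, 0.0)
        assert m.max_score == m.min_score == 0.0

    def test_single_column_hand_arithmetic(self):
        m = build_matrix([[10, 0, 0, 0]], pseudocount=1.0)
        assert m.logodds[0, 0] == pytest.approx(math.log2((10 + 0.25) / 11 / 0.25))
        assert m.logodds[0, 1] == pytest.approx(math.log2((0.25) / 11 / 0.25))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            build_matrix([[1, -1, 0, 0]])

    def test_zero_column_without_pseudocount_is_degenerate(self):
        with pytest.raises(DegenerateMatrixError):
            build_matrix([[1, 1, 1, 1], [0, 0, 0, 0]], pseudocount=0.0)

    def test_parse_jaspar_style_text(self):
        text = """>M001 POU
A [ 10  0  3 ]
C [  0 12  1 ]
G [  5  2  0 ]
T [  1  2 12 ]
>M002 SOX
A 1 2
C 3 4
G 5 6
T 7 8
"""
        m1, m2 = parse_matrices(text)
        assert (m1.motif_id, m1.factor_family, m1.length) == ("M001", "POU", 3)
        assert m2.counts[1, 3] == 8


class TestScan:
    def test_best_word_scores_max_on_plus_strand(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 6)
        # the top-scoring word maximizes log-odds (not raw counts: a skewed
        # background can shift the optimum away from the count consensus)
        best = "".join("ACGT"[i] for i in m.logodds.argmax(axis=1))
        hits = scan_sequence(m, best, score_threshold=m.max_score - 1e-9)
        assert (hits[0].start, hits[0].strand) == (0, "+")
        assert hits[0].score == pytest.approx(m.max_score)

    def test_sequence_shorter_than_motif_yields_no_hits(self):
        m = build_matrix(np.eye(4)[:, :4][:3] * 5 + 1)
        assert scan_sequence(m, "AC", score_threshold=-100) == []

    def test_scan_agrees_with_per_window_scoring_on_all_3mers(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 3)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        hits = scan_sequence(m, seq, score_threshold=-1e9)
        direct = {}
        for start in range(len(seq) - 2):
            word = seq[start : start + 3]
            codes = ["ACGT".index(c) for c in word]
            direct[(start, "+")] = sum(m.logodds[i, c] for i, c in enumerate(codes))
            rc = [3 - c for c in reversed(codes)]
            direct[(start, "-")] = sum(m.logodds[i, c] for i, c in enumerate(rc))
        assert len(hits) == 2 * (len(seq) - 2)
        for h in hits:
            assert h.score == pytest.approx(direct[(h.start, h.strand)])

    def test_windows_with_n_are_skipped_and_excluded_from_evalue(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 4)
        seq = "ACGTNACGTACG"
        hits = scan_sequence(m, seq, score_threshold=-1e9)
        starts = {h.start for h in hits}
        assert starts == {0, 5, 6, 7, 8}  # windows 1..4 contain the N
        n_windows = len(starts)
        for h in hits:
            assert h.evalue == pytest.approx(h.pvalue * 2 * n_windows)

    def test_exactly_one_threshold_scale_required(self):
        m = build_matrix([[5, 1, 1, 1]])
        with pytest.raises(ValueError):
            scan_sequence(m, "ACGT")
        with pytest.raises(ValueError):
            scan_sequence(m, "ACGT", score_threshold=0, pvalue=0.5)

    def test_prepending_background_bases_shifts_hit_starts(self):
        rng = np.random.default_rng(11)
        m = random_matrix(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        prefix = "".join(rng.choice(list("ACGT"), size=9))
        before = scan_sequence(m, seq, score_threshold=-1e9)
        after = scan_sequence(m, prefix + seq, score_threshold=-1e9)
        shifted = {(h.start + 9, h.strand, round(h.score, 9)) for h in before}
        interior = {
            (h.start, h.strand, round(h.score, 9)) for h in after if h.start >= 9
        }
        assert shifted == interior

    def test_scanning_reverse_complement_mirrors_hits_with_strands_swapped(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 4)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        rc_seq = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        fwd = scan_sequence(m, seq, score_threshold=-1e9)
        rc = scan_sequence(m, rc_seq, score_threshold=-1e9)
        swap = {"+": "-", "-": "+"}
        mirrored = {
            (len(seq) - h.end, swap[h.strand], round(h.score, 9)) for h in fwd
        }
        assert {(h.start, h.strand, round(h.score, 9)) for h in rc} == mirrored

    def test_reverse_complement_matrix_scores_minus_strand_forward(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), size=25))
        fwd = scan_sequence(m, seq, score_threshold=-1e9)
        rcm = scan_sequence(m.reverse_complement(), seq, score_threshold=-1e9)
        minus = {(h.start, round(h.score, 9)) for h in fwd if h.strand == "-"}
        plus_rc = {(h.start, round(h.score, 9)) for h in rcm if h.strand == "+"}
        assert minus == plus_rc

    def test_hits_tsv_round_trip(self):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 4)
        hits = scan_sequence(m, "ACGTACGTAAAT", sequence_id="s1", pvalue=1.0)
        assert hits_from_tsv(hits_to_tsv(hits)) == [
            h.__class__(
                h.motif_id, h.sequence_id, h.start, h.length, h.strand,
                float(f"{h.score:.4f}"), float(f"{h.pvalue:.6g}"),
                float(f"{h.evalue:.6g}"),
            )
            for h in hits
        ]


class TestExactPvalue:
    def test_extremes(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 5)
        assert exact_pvalue(m, m.min_score) == 1.0
        assert exact_pvalue(m, m.min_score - 5) == 1.0
        assert exact_pvalue(m, m.max_score + 1e-6) == 0.0

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 6)
        scores = np.linspace(m.min_score - 1, m.max_score + 1, 200)
        pvals = [exact_pvalue(m, s) for s in scores]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    @pytest.mark.parametrize("L", [2, 4, 6])
    def test_dp_matches_enumeration_away_from_lattice_boundaries(self, L):
        rng = np.random.default_rng(100 + L)
        m = random_matrix(rng, L)
        scores, probs = enumerate_word_scores(m)
        uniq = np.unique(scores)
        gaps = np.diff(uniq)
        # thresholds centered in gaps wider than the lattice rounding error,
        # where discretized and exact classification provably coincide
        wide = np.flatnonzero(gaps > 2 * L * 1e-3)
        for i in wide[:: max(1, wide.size // 20)]:
            s = (uniq[i] + uniq[i + 1]) / 2
            expected = probs[scores >= s].sum()
            assert exact_pvalue(m, s) == pytest.approx(expected, abs=1e-6)
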