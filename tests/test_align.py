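"""Alignment engine: seeded search vs exhaustive oracles, DP cross-checks,
protein alignment conventions, strand/symmetry properties."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from mobilome.align import (
    KmerIndex,
    alignment_fraction_vs_shorter,
    dp_local_align_nt,
    gapfree_best_hit,
    protein_local_align,
    seeded_nt_search,
    ungapped_identity,
)
from mobilome.io import SeqRecord, revcomp

from conftest import AA20, brute_force_hits, mutate, rand_seq


class TestSeededSearch:
    def test_verbatim_embedding(self, rng):
        q = rand_seq(rng, 35)
        t = rand_seq(rng, 2000) + q + rand_seq(rng, 2000)
        (hit,) = seeded_nt_search(q, [SeqRecord("t", t)])
        assert (hit.target_start, hit.target_end) == (2000, 2035)
        assert hit.identity == 1.0 and hit.query_coverage == 1.0

    def test_one_substitution_found_three_rejected(self, rng):
        q = rand_seq(rng, 35)
        t1 = rand_seq(rng, 1000) + mutate(rng, q, 1) + rand_seq(rng, 1000)
        hits = seeded_nt_search(q, [SeqRecord("t", t1)])
        assert hits and hits[0].identity >= 34 / 35 - 1e-9
        # 3 interior substitutions: no sub-window passes 95/95
        buf = list(q)
        for p in (8, 17, 26):
            buf[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[buf[p]]
        t3 = rand_seq(rng, 1000) + "".join(buf) + rand_seq(rng, 1000)
        assert seeded_nt_search(q, [SeqRecord("t", t3)]) == []

    def test_query_shorter_than_k_errors(self, rng):
        with pytest.raises(ValueError, match="shorter than seed"):
            seeded_nt_search("ACGTACG", [SeqRecord("t", rand_seq(rng, 100))])

    def test_equals_brute_force_oracle_on_implants(self, rng):
        """Accepted hit set identical to the exhaustive enumeration oracle."""
        targets = []
        queries = [rand_seq(rng, int(rng.integers(26, 51))) for _ in range(30)]
        for t_i in range(8):
            seq = rand_seq(rng, 4000)
            for q in rng.choice(len(queries), size=4, replace=False):
                implant = mutate(rng, queries[q], int(rng.integers(0, 3)))
                if rng.random() < 0.5:
                    implant = revcomp(implant)
                pos = int(rng.integers(0, 4000 - 60))
                seq = seq[:pos] + implant + seq[pos + len(implant):]
            targets.append(SeqRecord(f"t{t_i}", seq))
        index = KmerIndex.build(targets, 10)
        for q in queries:
            got = {
                (h.target_id, h.strand, h.target_start, h.target_end, round(h.identity, 10))
                for h in seeded_nt_search(q, index=index)
            }
            expected = {
                (o.target_id, o.strand, o.target_start, o.target_end, o.identity)
                for o in brute_force_hits(q, targets)
            }
            assert got == expected

    def test_reverse_complement_consistency(self, rng):
        q = rand_seq(rng, 34)
        t = rand_seq(rng, 500) + q + rand_seq(rng, 500)
        fwd = seeded_nt_search(q, [SeqRecord("t", t)])
        rev = seeded_nt_search(q, [SeqRecord("t", revcomp(t))])
        assert len(fwd) == len(rev) == 1
        L = len(t)
        assert rev[0].strand == "-"
        assert (rev[0].target_start, rev[0].target_end) == (
            L - fwd[0].target_end,
            L - fwd[0].target_start,
        )

    def test_monotonicity_in_thresholds(self, rng):
        q = rand_seq(rng, 40)
        t = rand_seq(rng, 800) + mutate(rng, q, 1) + rand_seq(rng, 800)
        rec = SeqRecord("t", t)
        loose = seeded_nt_search(q, [rec], min_identity=0.9, min_coverage=0.9)
        tight = seeded_nt_search(q, [rec], min_identity=0.99, min_coverage=0.99)
        assert len(tight) <= len(loose)

    def test_gapped_mode_finds_single_deletion(self, rng):
        q = rand_seq(rng, 40)
        with_del = q[:20] + q[21:]  # one deleted base
        t = rand_seq(rng, 600) + with_del + rand_seq(rng, 600)
        gapfree = seeded_nt_search(q, [SeqRecord("t", t)], min_identity=0.95,
                                   min_coverage=0.95)
        gapped = seeded_nt_search(q, [SeqRecord("t", t)], min_identity=0.95,
                                  min_coverage=0.95, allow_gaps=True)
        assert gapfree == []  # a deletion breaks every gap-free window
        assert len(gapped) == 1 and gapped[0].identity >= 39 / 41


class TestDpOracle:
    def test_identical_sequences(self, rng):
        s = rand_seq(rng, 20)
        rec = dp_local_align_nt(s, s)
        assert rec.identity == 1.0 and rec.alignment_length == 20

    def test_forced_single_base(self):
        rec = dp_local_align_nt("ACGT", "TTTT", match=1, mismatch=-2, gap=-2.5)
        assert rec.matches == 1 and rec.alignment_length == 1

    def test_budget(self, rng):
        with pytest.raises(ValueError, match="budget"):
            dp_local_align_nt(rand_seq(rng, 3000), rand_seq(rng, 3000), budget=10000)

    def test_score_agrees_with_biopython_on_random_pairs(self, rng):
        """Cross-implementation check against an independent quadratic aligner."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1.0
        aligner.mismatch_score = -2.0
        aligner.open_gap_score = -2.5
        aligner.extend_gap_score = -2.5
        for _ in range(200):
            a = rand_seq(rng, int(rng.integers(10, 60)))
            b = rand_seq(rng, int(rng.integers(10, 60)))
            if rng.random() < 0.5:  # make half the pairs related
                b = mutate(rng, a, int(rng.integers(1, 4)))
            rec = dp_local_align_nt(a, b)
            assert rec is None or rec.score == pytest.approx(aligner.score(a, b))
            if rec is None:
                assert aligner.score(a, b) <= 0 or max(len(a), len(b)) < 2

    def test_symmetry(self, rng):
        a, b = rand_seq(rng, 40), rand_seq(rng, 45)
        r1, r2 = dp_local_align_nt(a, b), dp_local_align_nt(b, a)
        assert (r1 is None) == (r2 is None)
        if r1:
            assert r1.score == r2.score and r1.matches == r2.matches


def _gotoh_local_score(a, b, matrix, open_cost=12.0, extend_cost=1.0):
    """Independent affine-gap local alignment score (reference for the
    production aligner; first gap residue costs open, subsequent extend)."""
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - extend_cost)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - extend_cost)
            s = matrix[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


class TestProteinAlign:
    def test_self_alignment(self, rng):
        p = "".join(rng.choice(list(AA20), 120))
        rec = protein_local_align(p, p)
        assert rec.identity == 1.0
        assert alignment_fraction_vs_shorter(rec, len(p), len(p)) == 1.0

    def test_half_identical_fails_coverage_gate(self, rng):
        shared = "".join(rng.choice(list(AA20), 100))
        a = shared + "".join(rng.choice(list(AA20), 100))
        b = shared + "".join(rng.choice(list(AA20), 120))
        rec = protein_local_align(a, b)
        af = alignment_fraction_vs_shorter(rec, len(a), len(b))
        assert af < 0.80  # only ~half the shorter protein aligns

    def test_score_matches_independent_gotoh(self, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        for _ in range(25):
            a = "".join(rng.choice(list(AA20), int(rng.integers(30, 80))))
            b = "".join(rng.choice(list(AA20), int(rng.integers(30, 80))))
            if rng.random() < 0.5:
                b = a[: len(b)]
            rec = protein_local_align(a, b)
            ref = _gotoh_local_score(a, b, blosum)
            if rec is None:
                assert ref <= 0
            else:
                assert rec.score == pytest.approx(ref)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list(AA20), 60))
        b = mutate_protein(rng, a, 10)
        r1 = protein_local_align(a, b)
        r2 = protein_local_align(b, a)
        assert r1.score == r2.score and r1.matches == r2.matches
        assert r1.identity == pytest.approx(r2.identity)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            protein_local_align("", "ACD")


def mutate_protein(rng, seq, n_subs):
    buf = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        options = [c for c in AA20 if c != buf[p]]
        buf[p] = options[rng.integers(0, len(options))]
    return "".join(buf)


class TestHelpers:
    def test_gapfree_best_hit_rejects_two_subs_in_36(self, rng):
        rep = rand_seq(rng, 36)
        assert gapfree_best_hit(rep, rep, 0.95, 0.95) is not None
        two = mutate(rng, rep, 2)
        # coverage >= 0.95*36 needs >= 35 columns; <= 1 mismatch allowed there
        assert gapfree_best_hit(two, rep, 0.95, 0.95) is None

    def test_ungapped_identity_extremes(self, rng):
        s = rand_seq(rng, 30)
        assert ungapped_identity(s, s) == 1.0
        vals = [ungapped_identity(rand_seq(rng, 30), rand_seq(rng, 30)) for _ in range(20)]
        assert max(vals) < 0.8
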