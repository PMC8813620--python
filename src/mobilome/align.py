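"""Shared sequence-comparison kernel.

Three routes, used by different stages:

* :func:`seeded_nt_search` - k-mer seeded, gap-free nucleotide matching for
  short queries (CRISPR spacers, repeats) against large targets, with an
  end-trim search so that a query passing ``identity >= i`` over
  ``coverage >= c`` is found whenever any gap-free placement admits it.
  The seed length is pigeonhole-safe: a window of w columns with m mismatches
  contains an exact run of at least ceil((w - m) / (m + 1)) columns, which for
  the 95/95 defaults and queries >= 21 nt is always >= the default k = 10.
* :func:`dp_local_align_nt` - exhaustive Smith-Waterman with linear gaps for
  small inputs; the in-package oracle for the seeded route.
* :func:`protein_local_align` - affine-gap protein local alignment
  (BLOSUM62, BLAST-style gap open 11 / extend 1) via Bio.Align.

Identity is always matches / alignment columns (gap columns count in the
denominator); query coverage is the aligned query span / query length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SeqRecord, revcomp


@dataclass
class AlignmentRecord:
    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    matches: int
    alignment_length: int
    identity: float
    query_coverage: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 1 + 1e-12):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if not (0 <= self.query_coverage <= 1 + 1e-12):
            raise ValueError(f"query_coverage {self.query_coverage} outside [0, 1]")


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------


@dataclass
class KmerIndex:
    """Exact k-mer -> [(contig_id, position)] lookup over target + strands."""

    k: int
    map: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)  # contig_id -> sequence

    @classmethod
    def build(cls, targets: Iterable[SeqRecord], k: int) -> "KmerIndex":
        idx = cls(k=k)
        for rec in targets:
            if rec.id in idx.targets:
                raise ValueError(f"duplicate target id {rec.id!r}")
            idx.targets[rec.id] = rec.seq
            seq = rec.seq
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                idx.map.setdefault(kmer, []).append((rec.id, pos))
        return idx


# ---------------------------------------------------------------------------
# Gap-free placement evaluation
# ---------------------------------------------------------------------------


def _window_caps(qlen: int, min_identity: float, min_coverage: float) -> int:
    return math.ceil(min_coverage * qlen - 1e-9)


def best_window_on_diagonal(
    query: str,
    target: str,
    diag: int,
    min_identity: float,
    min_coverage: float,
) -> tuple[int, int, int, int] | None:
    """Best accepted gap-free window of ``query`` placed at target offset ``diag``.

    Considers every contiguous query sub-window long enough to satisfy
    ``min_coverage`` and returns ``(q_start, q_end, matches, columns)`` for the
    best one (max identity, then longest, then leftmost), or None.
    """
    qlen = len(query)
    q0 = max(0, -diag)
    q1 = min(qlen, len(target) - diag)
    wmin = _window_caps(qlen, min_identity, min_coverage)
    if q1 - q0 < wmin:
        return None
    mism = np.fromiter(
        (
            query[i] != target[i + diag] or query[i] == "N" or target[i + diag] == "N"
            for i in range(q0, q1)
        ),
        dtype=np.int32,
        count=q1 - q0,
    )
    cum = np.concatenate(([0], np.cumsum(mism)))
    span = q1 - q0
    best = None  # (identity, w, -s, matches)
    for w in range(span, wmin - 1, -1):
        max_m = math.floor((1 - min_identity) * w + 1e-9)
        mm = cum[w:] - cum[: span - w + 1]  # mismatches of each window of size w
        ok = np.flatnonzero(mm <= max_m)
        if len(ok) == 0:
            continue
        idents = (w - mm[ok]) / w
        order = np.lexsort((ok, -idents))  # identity desc, start asc
        s_rel = int(ok[order[0]])
        ident = float(idents[order[0]])
        cand = (ident, w, -s_rel, w - int(mm[s_rel]))
        if best is None or cand > best:
            best = cand
    if best is None:
        return None
    ident, w, neg_s, matches = best
    s = q0 - neg_s
    return (s, s + w, matches, w)


def _placements_for_diagonals(
    query_id: str,
    query: str,
    target_id: str,
    target: str,
    strand: str,
    diagonals: Iterable[int],
    min_identity: float,
    min_coverage: float,
) -> list[AlignmentRecord]:
    qlen = len(query)
    out = []
    for diag in diagonals:
        hit = best_window_on_diagonal(query, target, diag, min_identity, min_coverage)
        if hit is None:
            continue
        qs, qe, matches, cols = hit
        ts, te = qs + diag, qe + diag
        if strand == "-":
            oqs, oqe = qlen - qe, qlen - qs  # back to original query coords
        else:
            oqs, oqe = qs, qe
        out.append(
            AlignmentRecord(
                query_id=query_id,
                target_id=target_id,
                query_start=oqs,
                query_end=oqe,
                target_start=ts,
                target_end=te,
                strand=strand,
                matches=matches,
                alignment_length=cols,
                identity=matches / cols,
                query_coverage=cols / qlen,
                score=float(matches),
            )
        )
    return out


def merge_placements(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Collapse overlapping accepted placements on the same target+strand.

    One record per locus: within each overlap chain keep the best by
    (identity desc, alignment_length desc, target_start asc).
    """
    by_key: dict[tuple[str, str, str], list[AlignmentRecord]] = {}
    for r in records:
        by_key.setdefault((r.query_id, r.target_id, r.strand), []).append(r)
    merged: list[AlignmentRecord] = []
    for recs in by_key.values():
        recs.sort(key=lambda r: (r.target_start, r.target_end))
        group: list[AlignmentRecord] = []
        group_end = -1
        for r in recs:
            if group and r.target_start >= group_end:
                merged.append(_best_of(group))
                group = []
            group.append(r)
            group_end = max(group_end, r.target_end)
        if group:
            merged.append(_best_of(group))
    merged.sort(key=lambda r: (r.target_id, r.target_start, r.strand, r.query_id))
    return merged


def _best_of(group: list[AlignmentRecord]) -> AlignmentRecord:
    return min(group, key=lambda r: (-r.identity, -r.alignment_length, r.target_start))


# ---------------------------------------------------------------------------
# Seeded nucleotide search
# ---------------------------------------------------------------------------


def seeded_nt_search(
    query: SeqRecord | str,
    targets: Iterable[SeqRecord] | None = None,
    index: KmerIndex | None = None,
    k: int = 10,
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
    allow_gaps: bool = False,
    query_id: str | None = None,
) -> list[AlignmentRecord]:
    """Find gap-free (default) matches of a short query on both target strands.

    Every reported record satisfies ``identity >= min_identity`` and
    ``query_coverage >= min_coverage``; overlapping placements of the same
    query are merged to one record per locus.  With ``allow_gaps=True``
    candidate loci are rescored with :func:`dp_local_align_nt`.
    """
    if isinstance(query, SeqRecord):
        qseq, qid = query.seq, query.id
    else:
        qseq, qid = query.upper(), query_id or "query"
    if index is None:
        if targets is None:
            raise ValueError("provide targets or a prebuilt index")
        index = KmerIndex.build(targets, k)
    k = index.k
    if len(qseq) < k:
        raise ValueError(f"query {qid!r} shorter than seed k={k}")

    records: list[AlignmentRecord] = []
    for strand, q in (("+", qseq), ("-", revcomp(qseq))):
        diagonals: dict[str, set[int]] = {}
        for i in range(len(q) - k + 1):
            kmer = q[i : i + k]
            for tid, pos in index.map.get(kmer, ()):
                diagonals.setdefault(tid, set()).add(pos - i)
        for tid, diags in diagonals.items():
            target = index.targets[tid]
            if allow_gaps:
                records.extend(
                    _gapped_candidates(
                        qid, q, tid, target, strand, diags, min_identity, min_coverage
                    )
                )
            else:
                records.extend(
                    _placements_for_diagonals(
                        qid, q, tid, target, strand, sorted(diags),
                        min_identity, min_coverage,
                    )
                )
    return merge_placements(records)


def _gapped_candidates(
    qid: str,
    q: str,
    tid: str,
    target: str,
    strand: str,
    diags: set[int],
    min_identity: float,
    min_coverage: float,
    pad: int = 12,
) -> list[AlignmentRecord]:
    qlen = len(q)
    out = []
    # group nearby diagonals into one candidate window
    spans = sorted((max(0, d - pad), min(len(target), d + qlen + pad)) for d in diags)
    windows: list[list[int]] = []
    for s, e in spans:
        if windows and s <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], e)
        else:
            windows.append([s, e])
    for s, e in windows:
        rec = dp_local_align_nt(q, target[s:e])
        if rec is None or rec.alignment_length == 0:
            continue
        coverage = (rec.query_end - rec.query_start) / qlen
        if rec.identity >= min_identity and coverage >= min_coverage:
            oqs, oqe = rec.query_start, rec.query_end
            if strand == "-":
                oqs, oqe = qlen - rec.query_end, qlen - rec.query_start
            out.append(
                AlignmentRecord(
                    query_id=qid,
                    target_id=tid,
                    query_start=oqs,
                    query_end=oqe,
                    target_start=s + rec.target_start,
                    target_end=s + rec.target_end,
                    strand=strand,
                    matches=rec.matches,
                    alignment_length=rec.alignment_length,
                    identity=rec.identity,
                    query_coverage=coverage,
                    score=rec.score,
                )
            )
    return out


def gapfree_best_hit(
    a: str,
    b: str,
    min_identity: float,
    min_coverage_of_shorter: float,
    both_strands: bool = True,
) -> AlignmentRecord | None:
    """Exhaustive gap-free comparison of two short sequences.

    Coverage is measured against the shorter sequence.  Used for
    repeat-vs-repeat recruitment where both sides are ~25-50 nt.
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    best: AlignmentRecord | None = None
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        recs = _placements_for_diagonals(
            "a", q, "b", target, strand,
            range(-(len(q) - 1), len(target)),
            min_identity, min_coverage_of_shorter,
        )
        for r in recs:
            if best is None or (r.identity, r.alignment_length) > (
                best.identity,
                best.alignment_length,
            ):
                best = r
    return best


def ungapped_identity(a: str, b: str) -> float:
    """Best-diagonal matches / max(len a, len b); a blunt global-ish similarity.

    1.0 for identical sequences, ~0.3 for unrelated random DNA.  Used to score
    spacer-vs-spacer similarity when separating CRISPR from tandem arrays.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    denom = max(len(a), len(b))
    best = 0
    for diag in range(-(len(a) - 1), len(b)):
        lo = max(0, -diag)
        hi = min(len(a), len(b) - diag)
        m = sum(1 for i in range(lo, hi) if a[i] == b[i + diag] and a[i] != "N")
        if m > best:
            best = m
    return best / denom


# ---------------------------------------------------------------------------
# Smith-Waterman oracle (linear gaps)
# ---------------------------------------------------------------------------


def dp_local_align_nt(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap: float = -2.5,
    budget: int = 4_000_000,
) -> AlignmentRecord | None:
    """Optimal local alignment of two nucleotide sequences, exhaustively.

    Linear gap penalty; ties broken deterministically to the first maximal
    cell in row-major order (earliest end, hence lowest start among equals)
    and, in the traceback, diagonal > up > left.  Intended as the oracle for
    the seeded search on small inputs; raises if len(a)*len(b) exceeds
    ``budget`` (use the seeded search for big problems).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    n, m = len(a), len(b)
    if n * m > budget:
        raise ValueError(
            f"DP budget exceeded ({n}x{m} > {budget}); use seeded_nt_search"
        )
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up, 3 left
    best_score, best_cell = 0.0, (0, 0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        Hi, Hp, Pi = H[i], H[i - 1], ptr[i]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            diag = Hp[j - 1] + s
            up = Hp[j] + gap
            left = Hi[j - 1] + gap
            v = diag
            p = 1
            if up > v:
                v, p = up, 2
            if left > v:
                v, p = left, 3
            if v <= 0:
                v, p = 0.0, 0
            Hi[j] = v
            Pi[j] = p
            if v > best_score:
                best_score, best_cell = v, (i, j)
    if best_score <= 0:
        return None
    i, j = best_cell
    matches = 0
    cols = 0
    end_i, end_j = i, j
    while ptr[i, j] != 0:
        p = ptr[i, j]
        cols += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return AlignmentRecord(
        query_id="a",
        target_id="b",
        query_start=i,
        query_end=end_i,
        target_start=j,
        target_end=end_j,
        strand="+",
        matches=matches,
        alignment_length=cols,
        identity=matches / cols if cols else 0.0,
        query_coverage=(end_i - i) / n,
        score=best_score,
    )


# ---------------------------------------------------------------------------
# Protein local alignment
# ---------------------------------------------------------------------------

_PROT_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _protein_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (matrix, gap_open, gap_extend)
    if key not in _PROT_ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(matrix)
        # BLAST convention: a gap of length g costs open + g*extend
        aligner.open_gap_score = -(gap_open + gap_extend)
        aligner.extend_gap_score = -gap_extend
        _PROT_ALIGNER_CACHE[key] = aligner
    return _PROT_ALIGNER_CACHE[key]


def protein_local_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "a",
    target_id: str = "b",
) -> AlignmentRecord | None:
    """Local protein alignment; identity counts gap columns in the denominator.

    The pair is canonicalized by (length, lexicographic) order before
    alignment so that scoring (a, b) and (b, a) picks the same co-optimal
    alignment: matches, columns and identity are then symmetric.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if (len(a), a) > (len(b), b):
        rec = protein_local_align(
            b, a, matrix, gap_open, gap_extend, query_id=target_id, target_id=query_id
        )
        if rec is None:
            return None
        return AlignmentRecord(
            query_id=query_id,
            target_id=target_id,
            query_start=rec.target_start,
            query_end=rec.target_end,
            target_start=rec.query_start,
            target_end=rec.query_end,
            strand="+",
            matches=rec.matches,
            alignment_length=rec.alignment_length,
            identity=rec.identity,
            query_coverage=(rec.target_end - rec.target_start) / len(a),
            score=rec.score,
        )
    aligner = _protein_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = aligner.align(a, b)[0]
    qblocks, tblocks = aln.aligned
    matches = 0
    block_cols = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        block_cols += qe - qs
        matches += sum(1 for x, y in zip(a[qs:qe], b[ts:te]) if x == y)
    gap_cols = 0
    for idx in range(1, len(qblocks)):
        gap_cols += qblocks[idx][0] - qblocks[idx - 1][1]
        gap_cols += tblocks[idx][0] - tblocks[idx - 1][1]
    cols = block_cols + gap_cols
    qs0, qe1 = int(qblocks[0][0]), int(qblocks[-1][1])
    ts0, te1 = int(tblocks[0][0]), int(tblocks[-1][1])
    return AlignmentRecord(
        query_id=query_id,
        target_id=target_id,
        query_start=qs0,
        query_end=qe1,
        target_start=ts0,
        target_end=te1,
        strand="+",
        matches=matches,
        alignment_length=cols,
        identity=matches / cols if cols else 0.0,
        query_coverage=(qe1 - qs0) / len(a),
        score=float(score),
    )


def alignment_fraction_vs_shorter(rec: AlignmentRecord, len_a: int, len_b: int) -> float:
    """Aligned span on the shorter sequence / shorter length."""
    if len_a <= len_b:
        span = rec.query_end - rec.query_start
        return span / len_a
    span = rec.target_end - rec.target_start
    return span / len_b
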