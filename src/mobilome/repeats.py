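"""Non-tandem repeat landscape of a genome.

Finds pairs of dispersed duplicated segments (>= 100 bp at >= 95% identity
by default), excluding tandem/CRISPR array loci, and reports the genomic
footprint: the merged length of all repeat intervals over the genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crispr import CrisprArray
from .io import Interval, SeqRecord, merge_intervals, revcomp


@dataclass
class RepeatPair:
    first: Interval
    second: Interval
    identity: float
    alignment_length: int


def _diagonal_runs(seq_a: str, seq_b: str, k: int, self_compare: bool):
    """Seed positions grouped by diagonal, merged into runs.

    Yields (a_start, b_start, run_len) for chains of shared k-mers on one
    diagonal where consecutive seeds are <= k apart (allowing mismatches
    between seeds is handled later by identity scoring over the run).
    """
    pos_b: dict[str, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        kmer = seq_b[j : j + k]
        if "N" not in kmer:
            pos_b.setdefault(kmer, []).append(j)
    diagonals: dict[int, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        kmer = seq_a[i : i + k]
        if "N" in kmer:
            continue
        for j in pos_b.get(kmer, ()):
            if self_compare and j <= i:
                continue  # self-diagonal and mirrored pairs
            diagonals.setdefault(j - i, []).append(i)
    max_gap = 3 * k
    for diag, starts in diagonals.items():
        starts.sort()
        run_start, prev = starts[0], starts[0]
        for i in starts[1:]:
            if i - prev <= max_gap:
                prev = i
            else:
                yield run_start, run_start + diag, prev + k - run_start
                run_start, prev = i, i
        yield run_start, run_start + diag, prev + k - run_start


def _run_identity(seq_a: str, seq_b: str, a0: int, b0: int, length: int) -> float:
    m = sum(
        1
        for x, y in zip(seq_a[a0 : a0 + length], seq_b[b0 : b0 + length])
        if x == y and x != "N"
    )
    return m / length


def find_nontandem_repeats(
    genome: SeqRecord,
    min_len: int = 100,
    min_identity: float = 0.95,
    arrays: list[CrisprArray] | None = None,
    k: int = 16,
    include_reverse: bool = True,
) -> list[RepeatPair]:
    """Dispersed duplications within one genome (self-comparison).

    The trivial self-diagonal is excluded; symmetric pairs are reported once
    with the left interval first; pairs overlapping detected tandem/CRISPR
    arrays are removed.  Circular genomes are scanned with a k-wrap so
    origin-spanning repeats are caught.
    """
    seq = genome.seq
    L = len(seq)
    wrap = min(L, min_len + k) if genome.is_circular else 0
    ext = seq + seq[:wrap]

    pairs: list[RepeatPair] = []

    for a0, b0, length in _diagonal_runs(ext, ext, k, self_compare=True):
        if a0 >= L:  # left copy must start on the real sequence
            continue
        ident = _run_identity(ext, ext, a0, b0, length)
        if length >= min_len and ident >= min_identity:
            s1, s2 = a0 % L, b0 % L
            iv1 = Interval(genome.id, s1, min(s1 + length, L), "+")
            iv2 = Interval(genome.id, s2, min(s2 + length, L), "+")
            if (iv1.start, iv1.end) == (iv2.start, iv2.end):
                continue  # wrap artifact: same locus twice
            if iv2.start < iv1.start:
                iv1, iv2 = iv2, iv1
            if iv1.overlaps(iv2):
                continue  # tandem-adjacent overlap, not a dispersed pair
            pairs.append(RepeatPair(iv1, iv2, ident, length))

    if include_reverse:
        rc = revcomp(ext)
        for a0, b0, length in _diagonal_runs(ext, rc, k, self_compare=False):
            if a0 >= L:
                continue
            # map the rc interval back to forward coordinates
            fwd_b0 = len(ext) - (b0 + length)
            if fwd_b0 <= a0:  # report each inverted pair once
                continue
            ident = _run_identity(ext, rc, a0, b0, length)
            if length >= min_len and ident >= min_identity:
                s1, s2 = a0 % L, fwd_b0 % L
                iv1 = Interval(genome.id, s1, min(s1 + length, L), "+")
                iv2 = Interval(genome.id, s2, min(s2 + length, L), "-")
                if not iv1.overlaps(iv2):
                    pairs.append(RepeatPair(iv1, iv2, ident, length))

    if arrays:
        spans = [(a.contig_id, a.span.start % L, min(a.span.end, L)) for a in arrays]

        def in_array(iv: Interval) -> bool:
            return any(
                c == iv.contig_id and iv.start < e and s < iv.end for c, s, e in spans
            )

        pairs = [p for p in pairs if not (in_array(p.first) or in_array(p.second))]

    # deduplicate (same pair found from multiple seeds/runs)
    seen = set()
    unique = []
    for p in sorted(pairs, key=lambda p: (p.first.start, p.second.start, -p.alignment_length)):
        key = (p.first.start, p.first.end, p.second.start, p.second.end, p.second.strand)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def repeat_fraction(pairs: list[RepeatPair], genome_length: int) -> dict:
    """Repeat footprint of a genome.

    ``footprint`` is the merged coverage of all repeat intervals divided by
    the genome length (the headline value); ``summed_alignment`` is the sum
    of pair alignment lengths x2 over the genome length, for comparison.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    spans = []
    total_aln = 0
    for p in pairs:
        spans.append((p.first.start, p.first.end))
        spans.append((p.second.start, p.second.end))
        total_aln += 2 * p.alignment_length
    merged = merge_intervals(spans)
    footprint = sum(e - s for s, e in merged) / genome_length
    return {
        "footprint": footprint,
        "summed_alignment": total_aln / genome_length,
        "merged_bp": sum(e - s for s, e in merged),
        "n_pairs": len(pairs),
    }
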