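"""CRISPR-like tandem repeat array detection and spacer extraction.

The detector follows the CRT/MinCED recipe: slide an exact k-mer window,
look for recurrences of that window at spacings compatible with one repeat
plus one spacer, chain the recurrences, then extend the repeat boundaries
outward column-by-column while most instances agree, and finally validate
repeat/spacer length bounds.  Arrays whose spacers are near-identical are
pure tandem repeats, not CRISPR; arrays fully contained in a CDS are
additionally flagged intragenic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .align import ungapped_identity
from .io import DetectorParams, Interval, SeqRecord

KIND_CRISPR = "CRISPR"
KIND_TANDEM = "tandem"
KIND_UNCLASSIFIED = "unclassified"


@dataclass
class CrisprArray:
    array_id: str
    contig_id: str
    span: Interval
    repeat_instances: list[Interval]
    spacers: list[tuple[Interval, str]]
    consensus_repeat: str
    kind: str = KIND_UNCLASSIFIED
    intragenic: bool = False
    wrapped: bool = False  # spans the origin of a circular contig

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_instances)

    def validate(self, params: DetectorParams) -> "CrisprArray":
        if self.n_repeats < params.min_repeats:
            raise ValueError(f"{self.array_id}: fewer than {params.min_repeats} repeats")
        if len(self.spacers) != self.n_repeats - 1:
            raise ValueError(f"{self.array_id}: repeats and spacers do not alternate")
        for iv in self.repeat_instances:
            if not (params.min_repeat_len <= len(iv) <= params.max_repeat_len):
                raise ValueError(f"{self.array_id}: repeat length {len(iv)} out of bounds")
        for iv, _ in self.spacers:
            if not (params.min_spacer_len <= len(iv) <= params.max_spacer_len):
                raise ValueError(f"{self.array_id}: spacer length {len(iv)} out of bounds")
        return self


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def find_arrays(
    record: SeqRecord, params: DetectorParams | None = None
) -> list[CrisprArray]:
    """Detect repeat-spacer arrays on one contig, left to right, deterministically.

    Circular contigs are scanned across the origin by appending a bounded
    wrap; arrays that straddle the origin keep genome coordinates modulo L
    and are marked ``wrapped``.
    """
    params = (params or DetectorParams()).validate()
    L = len(record)
    wrap = 0
    seq = record.seq
    if record.is_circular and L > params.k:
        wrap = min(L, 4 * (params.max_repeat_len + params.max_spacer_len))
        seq = seq + seq[:wrap]

    k = params.k
    min_period = params.min_repeat_len + params.min_spacer_len
    max_period = params.max_repeat_len + params.max_spacer_len
    arrays: list[CrisprArray] = []
    n_found = 0
    i = 0
    limit = len(seq) - k
    while i <= limit:
        if i >= L:  # seeds must start on the real sequence, not the wrap copy
            break
        seed = seq[i : i + k]
        if "N" in seed:
            i += 1
            continue
        j = seq.find(seed, i + min_period, i + max_period + 1)
        if j == -1:
            i += 1
            continue
        chain = [i, j]
        cur = j
        while True:
            nxt = seq.find(seed, cur + min_period, cur + max_period + 1)
            if nxt == -1:
                break
            chain.append(nxt)
            cur = nxt
        if len(chain) >= params.min_repeats:
            arr = _extend_and_validate(seq, chain, record, n_found, params, L, wrap)
            if arr is not None:
                arrays.append(arr)
                n_found += 1
                i = arr.span.end + 1
                continue
        i += 1
    return _drop_wrap_duplicates(arrays, L)


def _drop_wrap_duplicates(arrays: list[CrisprArray], L: int) -> list[CrisprArray]:
    """Remove non-wrapped arrays whose span re-reports part of a wrapped one."""
    wrapped = [a for a in arrays if a.wrapped]
    if not wrapped:
        return arrays
    out = []
    for a in arrays:
        dup = False
        if not a.wrapped:
            for w in wrapped:
                tail = w.span.end - L  # wrapped portion covers [0, tail)
                if a.span.start >= w.span.start or a.span.end <= tail:
                    dup = True
                    break
        if not dup:
            out.append(a)
    return out


def _extend_and_validate(
    seq: str,
    chain: list[int],
    record: SeqRecord,
    ordinal: int,
    params: DetectorParams,
    L: int,
    wrap: int,
) -> CrisprArray | None:
    k = params.k
    n = len(chain)
    gaps = [chain[t + 1] - chain[t] for t in range(n - 1)]

    def col_ok(off: int) -> bool:
        chars = []
        for p in chain:
            q = p + off
            if q < 0 or q >= len(seq):
                return False
            chars.append(seq[q])
        modal = max(chars.count(c) for c in set(chars))
        return modal / n >= params.agreement

    # Right extension is capped so no inter-repeat gap drops below the minimum
    # spacer length (pure tandem units would otherwise swallow their spacers),
    # and left extension so the repeat cannot run into the previous instance.
    max_right = min(
        params.max_repeat_len,
        min(g for g in gaps) - params.min_spacer_len,
    )
    max_left = min(
        params.max_repeat_len - k,
        min(g for g in gaps) - k - params.min_spacer_len,
        chain[0],
    )

    def extend(direction: int, cap: int) -> int:
        # direction -1: columns -1, -2, ... ; +1: columns k, k+1, ...
        ext = 0
        skipped = False
        while ext < cap:
            off = (-(ext + 1)) if direction < 0 else (k + ext)
            if col_ok(off):
                ext += 1
                skipped = False
            elif not skipped:
                # rescue an isolated divergent column if the next one agrees
                off2 = (-(ext + 2)) if direction < 0 else (k + ext + 1)
                if ext + 2 <= cap and col_ok(off2):
                    ext += 2
                    skipped = True
                else:
                    break
            else:
                break
        return ext

    left = extend(-1, max(0, max_left))
    right_cap = max(0, max_right - k - left)
    right = extend(+1, right_cap)

    rep_len = k + left + right
    if rep_len < params.min_repeat_len:
        return None

    starts = [p - left for p in chain]
    # trim trailing instances whose preceding spacer violates the bounds
    keep = [starts[0]]
    for s in starts[1:]:
        spacer_len = s - (keep[-1] + rep_len)
        if params.min_spacer_len <= spacer_len <= params.max_spacer_len:
            keep.append(s)
        else:
            break

    # Chain completion: the exact-seed chain misses instances whose seed
    # k-mer is mutated.  Recover them by scanning the admissible spacer range
    # on both flanks for segments close to the current consensus.
    cons = _consensus([seq[s : s + rep_len] for s in keep])
    max_mm = int(0.25 * rep_len)

    def best_candidate(lo: int, hi: int) -> int | None:
        best_pos, best_mm = None, max_mm + 1
        for pos in range(max(0, lo), hi + 1):
            if pos + rep_len > len(seq):
                break
            window = seq[pos : pos + rep_len]
            mm = sum(1 for x, y in zip(cons, window) if x != y)
            if mm < best_mm:
                best_pos, best_mm = pos, mm
        return best_pos

    while True:
        base = keep[-1] + rep_len
        pos = best_candidate(base + params.min_spacer_len, base + params.max_spacer_len)
        if pos is None:
            break
        keep.append(pos)
    while keep[0] - rep_len - params.min_spacer_len >= 0:
        hi = keep[0] - rep_len - params.min_spacer_len
        lo = keep[0] - rep_len - params.max_spacer_len
        pos = best_candidate(lo, hi)
        if pos is None:
            break
        keep.insert(0, pos)

    # Prune edge instances that diverge from the consensus: a chance seed
    # k-mer in the flank one period away can start the chain early, and the
    # majority vote across the true instances then tolerates the junk copy.
    def inst_mm(s: int) -> int:
        return sum(1 for x, y in zip(cons, seq[s : s + rep_len]) if x != y)

    while keep and inst_mm(keep[0]) > max_mm:
        keep.pop(0)
    while keep and inst_mm(keep[-1]) > max_mm:
        keep.pop()

    if len(keep) < params.min_repeats:
        return None

    contig = record.id
    # Wrapped arrays keep extended coordinates (end may exceed L); the
    # ``wrapped`` flag tells consumers to interpret positions modulo L.
    wrapped = record.is_circular and keep[-1] + rep_len > L

    repeats = []
    spacers = []
    for idx, s in enumerate(keep):
        repeats.append(Interval(contig, s, s + rep_len))
        if idx + 1 < len(keep):
            sp_s, sp_e = s + rep_len, keep[idx + 1]
            spacers.append((Interval(contig, sp_s, sp_e), seq[sp_s:sp_e]))

    consensus = _consensus([seq[s : s + rep_len] for s in keep])
    arr = CrisprArray(
        array_id=f"{contig}_arr{ordinal:03d}",
        contig_id=contig,
        span=Interval(contig, keep[0], keep[-1] + rep_len),
        repeat_instances=repeats,
        spacers=spacers,
        consensus_repeat=consensus,
        wrapped=wrapped,
    )
    try:
        return arr.validate(params)
    except ValueError:
        return None


def _consensus(instances: list[str]) -> str:
    out = []
    for col in zip(*instances):
        out.append(max(set(col), key=lambda c: (col.count(c), c)))
    return "".join(out)


# ---------------------------------------------------------------------------
# Classification & spacer extraction
# ---------------------------------------------------------------------------


def classify_array(
    array: CrisprArray,
    cds_intervals: list[Interval] | None = None,
    params: DetectorParams | None = None,
) -> str:
    """Label an array CRISPR vs tandem from spacer diversity.

    Near-identical spacers mean the locus is one repeated unit (a pure tandem
    repeat); diverse spacers are the CRISPR signature.  With CDS intervals
    provided, a tandem array fully inside one CDS is flagged intragenic.
    """
    params = (params or DetectorParams()).validate()
    seqs = [s for _, s in array.spacers]
    if len(seqs) < 2:
        array.kind = KIND_UNCLASSIFIED
        return array.kind
    idents = [
        ungapped_identity(a, b) for a, b in itertools.combinations(seqs, 2)
    ]
    mean_ident = sum(idents) / len(idents)
    array.kind = (
        KIND_TANDEM if mean_ident >= params.tandem_spacer_identity else KIND_CRISPR
    )
    if array.kind == KIND_TANDEM and cds_intervals:
        for cds in cds_intervals:
            if (
                cds.contig_id == array.contig_id
                and cds.start <= array.span.start
                and array.span.end <= cds.end
            ):
                array.intragenic = True
                break
    return array.kind


def extract_spacers(array: CrisprArray) -> list[tuple[str, str]]:
    """Spacer (id, sequence) pairs in contig orientation, ids stable per array."""
    if array.kind != KIND_CRISPR:
        raise ValueError(
            f"{array.array_id}: spacers are only extracted from CRISPR arrays "
            f"(kind={array.kind})"
        )
    return [
        (f"{array.array_id}_sp{idx:03d}", seq)
        for idx, (_, seq) in enumerate(array.spacers)
    ]
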