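"""Protospacer discovery: mask source arrays, then match the spacerome.

Self-matches are avoided by replacing every source CRISPR array span
(repeats and spacers, end to end) with Ns in its own assembly before the
search; N positions produce no k-mer seeds and never count as matches, so
the invariant "no hit overlaps a masked interval" holds by construction and
is asserted on every run anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import AlignmentRecord, KmerIndex, seeded_nt_search
from .crispr import CrisprArray
from .io import Interval, SeqRecord
from .spacerome import Spacerome

logger = logging.getLogger("mobilome")


@dataclass
class ProtospacerHit:
    spacer_id: str
    target: Interval  # strand carries match orientation
    identity: float
    query_coverage: float
    matches: int
    alignment_length: int

    @classmethod
    def from_alignment(cls, rec: AlignmentRecord) -> "ProtospacerHit":
        return cls(
            spacer_id=rec.query_id,
            target=Interval(rec.target_id, rec.target_start, rec.target_end, rec.strand),
            identity=rec.identity,
            query_coverage=rec.query_coverage,
            matches=rec.matches,
            alignment_length=rec.alignment_length,
        )


def mask_arrays(
    assembly: list[SeqRecord], arrays: list[CrisprArray]
) -> list[SeqRecord]:
    """Replace every array span with Ns; lengths and other positions unchanged."""
    by_contig: dict[str, list[CrisprArray]] = {}
    for arr in arrays:
        by_contig.setdefault(arr.contig_id, []).append(arr)
    known = {rec.id for rec in assembly}
    for contig in by_contig:
        if contig not in known:
            raise ValueError(f"array references absent contig {contig!r}")
    out = []
    for rec in assembly:
        seq = rec.seq
        L = len(seq)
        buf = None
        for arr in by_contig.get(rec.id, []):
            if buf is None:
                buf = bytearray(seq, "ascii")
            s, e = arr.span.start, arr.span.end
            if arr.wrapped and e > L:
                buf[s:L] = b"N" * (L - s)
                buf[0 : e - L] = b"N" * (e - L)
            else:
                buf[s:e] = b"N" * (e - s)
        out.append(
            SeqRecord(rec.id, buf.decode("ascii") if buf else seq, rec.topology)
        )
    return out


def find_protospacers(
    spacerome: Spacerome,
    targets: list[SeqRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
    k: int = 10,
    allow_gaps: bool = False,
    known_arrays: list[CrisprArray] | None = None,
) -> list[ProtospacerHit]:
    """Match every spacerome entry against the (masked) targets, both strands.

    One hit per (spacer, locus).  If ``known_arrays`` is given, any hit that
    falls inside a known array span means the target was not masked: a
    warning names the offending array.
    """
    index = KmerIndex.build(targets, k)
    hits: list[ProtospacerHit] = []
    for spacer_id, seq in spacerome.sequences():
        if len(seq) < k:
            logger.warning("spacer %s shorter than seed k=%d; skipped", spacer_id, k)
            continue
        for rec in seeded_nt_search(
            seq,
            index=index,
            min_identity=min_identity,
            min_coverage=min_coverage,
            allow_gaps=allow_gaps,
            query_id=spacer_id,
        ):
            hits.append(ProtospacerHit.from_alignment(rec))
    if known_arrays:
        spans = [
            Interval(a.contig_id, a.span.start, min(a.span.end, 10**12))
            for a in known_arrays
        ]
        for h in hits:
            for sp in spans:
                if h.target.overlaps(sp):
                    logger.warning(
                        "hit %s overlaps known array span %s:%d-%d - target "
                        "appears unmasked",
                        h.spacer_id, sp.contig_id, sp.start, sp.end,
                    )
    return hits


def assert_no_masked_overlap(
    hits: list[ProtospacerHit], arrays: list[CrisprArray]
) -> None:
    """Hard invariant check: zero hits may overlap a masked array interval."""
    for h in hits:
        for arr in arrays:
            if arr.contig_id != h.target.contig_id:
                continue
            if h.target.start < arr.span.end and arr.span.start < h.target.end:
                raise AssertionError(
                    f"hit {h.spacer_id} at {h.target.contig_id}:{h.target.start}"
                    f"-{h.target.end} overlaps masked array {arr.array_id}"
                )
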