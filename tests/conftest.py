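"""Shared fixtures and the independent brute-force matching oracle.

The oracle enumerates EVERY gap-free placement of a query on a target
(including partially overhanging ones) via a padded sliding-window view and
accepts any sub-window satisfying the identity/coverage thresholds.  It
shares no code with the seeded search path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest

from mobilome.io import SeqRecord, revcomp

NT = np.array(list("ACGT"))
AA20 = "ACDEFGHIKLMNPQRSTVWY"


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, n)])


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    buf = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        buf[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[buf[p]]
    return "".join(buf)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Brute-force gap-free oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleHit:
    target_id: str
    strand: str
    target_start: int
    target_end: int
    identity: float


def _oracle_one_strand(q: str, tid: str, t: str, strand: str, min_id: float, min_cov: float):
    qlen = len(q)
    wmin = math.ceil(min_cov * qlen - 1e-9)
    pad = "X" * (qlen - 1)
    padded = np.frombuffer((pad + t + pad).encode(), dtype="S1")
    qarr = np.frombuffer(q.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(padded, qlen)
    mism = (windows != qarr) | (windows == b"X") | (windows == b"N") | (qarr == b"N")
    cum = np.zeros((mism.shape[0], qlen + 1), dtype=np.int32)
    np.cumsum(mism, axis=1, out=cum[:, 1:])
    accepted = []  # (row, s, w, mm)
    for w in range(wmin, qlen + 1):
        max_m = math.floor((1 - min_id) * w + 1e-9)
        mm = cum[:, w:] - cum[:, : qlen - w + 1]
        rows, starts = np.nonzero(mm <= max_m)
        for r, s in zip(rows, starts):
            accepted.append((int(r), int(s), w, int(mm[r, s])))
    hits = []
    for r, s, w, m in accepted:
        diag = r - (qlen - 1)  # placement offset of q[0] on t
        ts, te = diag + s, diag + s + w
        hits.append((ts, te, (w - m) / w, w))
    # merge overlapping accepted placements: best identity, longest, leftmost
    hits.sort(key=lambda h: (h[0], h[1]))
    merged = []
    group = []
    group_end = -(10**9)
    for h in hits:
        if group and h[0] >= group_end:
            merged.append(_pick(group))
            group = []
        group.append(h)
        group_end = max(group_end, h[1])
    if group:
        merged.append(_pick(group))
    return [
        OracleHit(tid, strand, ts, te, round(ident, 10)) for ts, te, ident, _ in merged
    ]


def _pick(group):
    return min(group, key=lambda h: (-h[2], -(h[1] - h[0]), h[0]))


def brute_force_hits(
    query: str,
    targets: list[SeqRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> set[OracleHit]:
    out: set[OracleHit] = set()
    for rec in targets:
        for strand, q in (("+", query), ("-", revcomp(query))):
            out.update(
                _oracle_one_strand(q, rec.id, rec.seq, strand, min_identity, min_coverage)
            )
    return out
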