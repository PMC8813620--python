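"""Mobile-element cataloguing: collect hit-bearing contigs, dereplicate,
apply the minimum-length filter, and summarize.

Dereplication is single-linkage over contig pairs matching at >= 95%
identity across >= 80% of the shorter contig (containment), measured by
tiling the shorter contig with windows and requiring the accepted-window
fraction to reach the containment threshold.  The representative of each
cluster is its longest member (ties by lexicographic id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import KmerIndex, seeded_nt_search
from .io import SeqRecord
from .protospacer import ProtospacerHit


@dataclass
class MgeCandidate:
    contig: SeqRecord
    hits: list[ProtospacerHit] = field(default_factory=list)
    cluster_id: int | None = None
    representative: bool = False

    @property
    def length(self) -> int:
        return len(self.contig)

    @property
    def id(self) -> str:
        return self.contig.id


def collect_candidates(
    hits: list[ProtospacerHit], assemblies: list[SeqRecord]
) -> list[MgeCandidate]:
    """One candidate per distinct hit-bearing contig, hits grouped."""
    by_id = {rec.id: rec for rec in assemblies}
    grouped: dict[str, list[ProtospacerHit]] = {}
    for h in hits:
        cid = h.target.contig_id
        if cid not in by_id:
            raise ValueError(f"hit references absent contig {cid!r}")
        grouped.setdefault(cid, []).append(h)
    return [
        MgeCandidate(contig=by_id[cid], hits=grouped[cid]) for cid in sorted(grouped)
    ]


def contig_containment(
    short: SeqRecord,
    index: KmerIndex,
    long_id: str,
    min_identity: float,
    window: int = 100,
    k: int = 16,
) -> float:
    """Fraction of the shorter contig's windows matching the longer contig."""
    seq = short.seq
    n_win = max(1, len(seq) // window)
    matched = 0
    for w in range(n_win):
        sub = seq[w * window : (w + 1) * window]
        recs = seeded_nt_search(
            sub,
            index=index,
            min_identity=min_identity,
            min_coverage=0.9,
            query_id=f"{short.id}_w{w}",
        )
        if any(r.target_id == long_id for r in recs):
            matched += 1
    return matched / n_win


def dereplicate_contigs(
    candidates: list[MgeCandidate],
    min_identity: float = 0.95,
    min_containment: float = 0.80,
) -> list[MgeCandidate]:
    """Single-linkage clustering by identity/containment; marks representatives.

    Order-independent: the cluster partition depends only on the pairwise
    containment relation, and cluster ids are assigned by sorted member ids.
    """
    n = len(candidates)
    cands = sorted(candidates, key=lambda c: c.id)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    indexes = {
        c.id: KmerIndex.build([c.contig], 16) for c in cands
    }
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cands[i], cands[j]
            short, long_ = (a, b) if a.length <= b.length else (b, a)
            cont = contig_containment(
                short.contig, indexes[long_.id], long_.id, min_identity
            )
            if cont >= min_containment:
                union(i, j)

    roots = sorted({find(i) for i in range(n)})
    root_to_cluster = {r: idx for idx, r in enumerate(roots)}
    clusters: dict[int, list[MgeCandidate]] = {}
    for i, c in enumerate(cands):
        cid = root_to_cluster[find(i)]
        c.cluster_id = cid
        c.representative = False
        clusters.setdefault(cid, []).append(c)
    for members in clusters.values():
        rep = min(members, key=lambda c: (-c.length, c.id))
        rep.representative = True
    return cands


def representatives(candidates: list[MgeCandidate]) -> list[MgeCandidate]:
    return [c for c in candidates if c.representative]


def filter_min_length(
    candidates: list[MgeCandidate], min_len: int = 2800
) -> list[MgeCandidate]:
    """Drop contigs strictly smaller than ``min_len`` bp; order preserved."""
    return [c for c in candidates if c.length >= min_len]


def summarize_catalog(candidates: list[MgeCandidate]) -> pd.DataFrame:
    """Element table sorted by length descending (id, bp, kbp, hits, cluster)."""
    rows = [
        {
            "element_id": c.id,
            "length_bp": c.length,
            "length_kbp": int(round(c.length / 1000)),
            "n_hits": len(c.hits),
            "cluster_id": c.cluster_id,
            "representative": c.representative,
        }
        for c in candidates
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "element_id", "length_bp", "length_kbp", "n_hits",
            "cluster_id", "representative",
        ],
    )
    if len(df):
        df = df.sort_values(
            ["length_bp", "element_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
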