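"""Eukaryote-related-protein (ERP) candidate families.

All-vs-all protein local alignment scores every pair by identity and by
alignment fraction relative to the shorter protein; a pair is connected iff
alignment_fraction >= 0.80 AND identity x alignment_fraction >= 0.24 (both
inclusive, both on the 0-1 scale).  Families are the connected components of
that threshold graph; singletons are retained.  A family is an ERP candidate
when at least one member's closest-taxon label is Eukaryota.  Family sharing
between genomes is summarized as a presence matrix and Venn cell counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .align import alignment_fraction_vs_shorter, protein_local_align
from .io import SeqRecord


@dataclass(frozen=True)
class PairScore:
    a: str
    b: str
    identity: float
    alignment_fraction: float

    @property
    def composite(self) -> float:
        return self.identity * self.alignment_fraction


@dataclass
class ErpFamily:
    family_id: str
    members: list[tuple[str, str]]  # (protein_id, genome_id)
    erp_flag: bool = False

    @property
    def genomes(self) -> frozenset:
        return frozenset(g for _, g in self.members)


def score_pairs(proteins: list[SeqRecord]) -> list[PairScore]:
    """One score per unordered pair that produces a positive local alignment."""
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    scores = []
    for pa, pb in itertools.combinations(proteins, 2):
        rec = protein_local_align(pa.seq, pb.seq, query_id=pa.id, target_id=pb.id)
        if rec is None:
            continue
        af = alignment_fraction_vs_shorter(rec, len(pa.seq), len(pb.seq))
        scores.append(PairScore(pa.id, pb.id, rec.identity, min(af, 1.0)))
    return scores


def build_clusters(
    scores: list[PairScore],
    protein_ids: list[str],
    min_alignment_fraction: float = 0.80,
    min_composite: float = 0.24,
) -> list[list[str]]:
    """Connected components of the threshold graph (singletons retained).

    Edge iff alignment_fraction >= min_alignment_fraction AND
    identity x alignment_fraction >= min_composite, both inclusive.
    """
    idx = {pid: i for i, pid in enumerate(protein_ids)}
    parent = list(range(len(protein_ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in scores:
        if (
            s.alignment_fraction >= min_alignment_fraction - 1e-12
            and s.composite >= min_composite - 1e-12
        ):
            ra, rb = find(idx[s.a]), find(idx[s.b])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    comps: dict[int, list[str]] = {}
    for pid in protein_ids:
        comps.setdefault(find(idx[pid]), []).append(pid)
    return [sorted(members) for _, members in sorted(comps.items())]


def flag_and_count(
    families: list[list[str]],
    taxon_labels: dict[str, str],
    genome_ids: dict[str, str],
) -> tuple[list[ErpFamily], pd.DataFrame, dict[str, int]]:
    """Flag ERP families and count family sharing between genomes.

    Returns (families, genome x family presence matrix, Venn cells).  Venn
    cells are keyed by the sorted '&'-joined genome subset each family's
    membership spans; cell counts sum to the number of families.
    """
    out: list[ErpFamily] = []
    for i, members in enumerate(families):
        pairs = []
        for pid in members:
            if pid not in genome_ids:
                raise ValueError(f"protein {pid!r} has no genome id")
            pairs.append((pid, genome_ids[pid]))
        erp = any(taxon_labels.get(pid) == "Eukaryota" for pid in members)
        out.append(ErpFamily(family_id=f"fam{i:04d}", members=pairs, erp_flag=erp))

    genomes = sorted(set(genome_ids.values()))
    presence = pd.DataFrame(
        False, index=genomes, columns=[f.family_id for f in out], dtype=bool
    )
    for f in out:
        for g in f.genomes:
            presence.loc[g, f.family_id] = True

    venn: dict[str, int] = {}
    for f in out:
        key = "&".join(sorted(f.genomes))
        venn[key] = venn.get(key, 0) + 1
    return out, presence, venn


def shared_family_counts(
    families: list[ErpFamily], genomes: tuple[str, ...], erp_only: bool = True
) -> dict[str, int]:
    """Venn cells restricted to a genome subset (e.g. a three-way comparison)."""
    gset = set(genomes)
    venn: dict[str, int] = {}
    for f in families:
        if erp_only and not f.erp_flag:
            continue
        present = f.genomes & gset
        if not present:
            continue
        key = "&".join(sorted(present))
        venn[key] = venn.get(key, 0) + 1
    return venn
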