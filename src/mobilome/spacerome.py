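"""Spacerome construction: recruit arrays by repeat homology, pool and
dereplicate their spacers.

Arrays from any number of metagenome datasets are recruited when their
consensus repeat matches a host repeat at 95% identity over 95% of the
shorter repeat (strand-agnostic).  Pooled spacers are then collapsed at
100% identity after strand canonicalization (the lexicographic minimum of
a spacer and its reverse complement), keeping full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import gapfree_best_hit
from .crispr import CrisprArray
from .io import revcomp


@dataclass
class SpaceromeEntry:
    canonical_sequence: str
    provenance: list[tuple[str, str, int]]  # (dataset, array_id, ordinal)


@dataclass
class Spacerome:
    entries: list[SpaceromeEntry] = field(default_factory=list)
    dataset_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def total_provenance(self) -> int:
        return sum(len(e.provenance) for e in self.entries)

    def sequences(self) -> list[tuple[str, str]]:
        """(spacer_id, sequence) pairs with stable ids."""
        return [
            (f"spacer{idx:05d}", e.canonical_sequence)
            for idx, e in enumerate(self.entries)
        ]


def recruit_arrays(
    host_repeat_consensuses: list[str],
    candidate_arrays: list[CrisprArray],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> list[CrisprArray]:
    """Arrays whose consensus repeat matches any host repeat at the 95/95 gate."""
    if not host_repeat_consensuses:
        raise ValueError("no host repeat consensuses given")
    recruited = []
    for arr in candidate_arrays:
        for host_rep in host_repeat_consensuses:
            hit = gapfree_best_hit(
                arr.consensus_repeat, host_rep, min_identity, min_coverage
            )
            if hit is not None:
                recruited.append(arr)
                break
    return recruited


def dereplicate_spacers(
    spacers: list[tuple[str, str, int, str]],
    canonicalize_strand: bool = True,
) -> Spacerome:
    """Collapse exact-duplicate spacers into a Spacerome.

    ``spacers`` rows are (dataset, array_id, ordinal, sequence).  With strand
    canonicalization (default) a spacer and its reverse complement collapse
    into one entry.  Dataset partition counts report unique entries per
    dataset (an entry seen in two datasets counts in both).
    """
    merged: dict[str, SpaceromeEntry] = {}
    for dataset, array_id, ordinal, seq in spacers:
        seq = seq.upper()
        canon = min(seq, revcomp(seq)) if canonicalize_strand else seq
        if canon not in merged:
            merged[canon] = SpaceromeEntry(canon, [])
        merged[canon].provenance.append((dataset, array_id, ordinal))
    entries = sorted(merged.values(), key=lambda e: e.canonical_sequence)
    counts: dict[str, int] = {}
    for e in entries:
        for ds in {p[0] for p in e.provenance}:
            counts[ds] = counts.get(ds, 0) + 1
    return Spacerome(entries=entries, dataset_counts=counts)


def pool_spacers(
    arrays_by_dataset: dict[str, list[CrisprArray]],
) -> list[tuple[str, str, int, str]]:
    """Flatten CRISPR arrays into provenance-tagged spacer rows."""
    rows = []
    for dataset in sorted(arrays_by_dataset):
        for arr in arrays_by_dataset[dataset]:
            for ordinal, (_, seq) in enumerate(arr.spacers):
                rows.append((dataset, arr.array_id, ordinal, seq))
    return rows
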