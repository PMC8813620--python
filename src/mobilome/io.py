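"""Readers/writers, coordinate conventions, configuration and the SR4 recoder.

All coordinates are 0-based half-open internally.  BED output stays 0-based
half-open; GFF3 output converts to 1-based inclusive at the boundary.  Depth
input accepts both a 3-column depth TSV (contig, 1-based position, depth, as
produced by ``samtools depth``) and 4-column bedGraph (0-based half-open);
the dialect is auto-detected from the column count.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

LINEAR = "linear"
CIRCULAR = "circular"

_NT_ALPHABET = frozenset("ACGTN")

logger = logging.getLogger("mobilome")


def configure_logging(level: int = logging.INFO) -> None:
    """Log to stderr with timestamps and stage names."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SeqRecord:
    """A named sequence with topology.

    Nucleotide records contain only A/C/G/T/N (uppercase); protein records
    are free-text amino acids.  ``topology`` is ``"circular"`` for closed
    replicons; operations that honour wrap-around state so explicitly.
    """

    id: str
    seq: str
    topology: str = LINEAR

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"record {self.id!r}: bad topology {self.topology!r}")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def validate_nucleotide(self) -> "SeqRecord":
        bad = set(self.seq) - _NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal nucleotide characters {sorted(bad)}"
            )
        return self


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class DepthTrack:
    """Dense per-base read depth for one contig (positions 0..L-1)."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError(f"{self.contig_id}: negative depth values")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class DetectorParams:
    """CRISPR-array detector parameters (CRT/MinCED-style defaults)."""

    k: int = 8
    min_repeats: int = 3
    min_repeat_len: int = 23
    max_repeat_len: int = 47
    min_spacer_len: int = 26
    max_spacer_len: int = 50
    agreement: float = 0.75  # modal-column fraction required to extend a repeat
    tandem_spacer_identity: float = 0.80  # mean pairwise spacer identity => tandem

    def validate(self) -> "DetectorParams":
        if not (0 < self.min_repeat_len <= self.max_repeat_len):
            raise ValueError("repeat length bounds out of order")
        if not (0 < self.min_spacer_len <= self.max_spacer_len):
            raise ValueError("spacer length bounds out of order")
        if self.k > self.min_repeat_len:
            raise ValueError("search window k exceeds min repeat length")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if not (0 < self.agreement <= 1):
            raise ValueError("agreement must be in (0, 1]")
        if not (0 <= self.tandem_spacer_identity <= 1):
            raise ValueError("tandem_spacer_identity must be in [0, 1]")
        return self


@dataclass
class PipelineConfig:
    """Every numeric threshold used downstream, in one serializable place."""

    # spacer/repeat homology gate (identity and alignment coverage)
    match_min_identity: float = 0.95
    match_min_coverage: float = 0.95
    # spacer dereplication
    spacer_dedup_identity: float = 1.0
    canonicalize_strand: bool = True
    # MGE catalogue
    mge_min_length: int = 2800
    derep_min_identity: float = 0.95
    derep_min_containment: float = 0.80
    # coverage profiling
    coverage_bin: int = 1000
    flank: int = 20000
    delta_min: float = 6.0
    ratio_min: float = 1.25
    # genomic repeat landscape
    repeat_min_len: int = 100
    repeat_min_identity: float = 0.95
    # ERP clustering
    erp_min_alignment_fraction: float = 0.80
    erp_min_composite: float = 0.24
    # alignment engine
    seed_k: int = 10
    allow_gaps: bool = False
    # detector
    detector: DetectorParams = field(default_factory=DetectorParams)
    # bookkeeping
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def validate(self) -> "PipelineConfig":
        for name in (
            "match_min_identity",
            "match_min_coverage",
            "spacer_dedup_identity",
            "derep_min_identity",
            "derep_min_containment",
            "repeat_min_identity",
            "erp_min_alignment_fraction",
            "erp_min_composite",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in ("mge_min_length", "coverage_bin", "flank", "repeat_min_len", "seed_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.detector.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        det = d.pop("detector", {})
        cfg = cls(**d, detector=DetectorParams(**det) if isinstance(det, dict) else det)
        return cfg.validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(
    path: str | Path,
    topology: str = LINEAR,
    alphabet: str | None = None,
) -> list[SeqRecord]:
    """Read FASTA into :class:`SeqRecord` objects (order preserved, uppercased).

    ``alphabet="nt"`` additionally validates that sequences contain only
    A/C/G/T/N and raises naming the record and offending characters.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out = SeqRecord(rec.id, str(rec.seq), topology=topology)
        if alphabet == "nt":
            out.validate_nucleotide()
        records.append(out)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------


def read_depth(path: str | Path, contig_lengths: dict[str, int]) -> list[DepthTrack]:
    """Read a depth TSV (1-based positions) or bedGraph (0-based half-open).

    Positions absent from the file get depth 0.  The dialect is detected from
    the column count: 3 columns = depth TSV, 4 columns = bedGraph.
    """
    path = Path(path)
    dense = {c: np.zeros(L, dtype=np.int64) for c, L in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) == 3:
                contig, pos_s, depth_s = parts
                pos = int(pos_s) - 1  # 1-based convention
                depth = int(depth_s)
                if contig not in dense:
                    raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
                if depth < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth {depth}")
                if not (0 <= pos < len(dense[contig])):
                    raise ValueError(
                        f"{path}:{lineno}: position {pos + 1} exceeds length "
                        f"of contig {contig!r}"
                    )
                dense[contig][pos] = depth
            elif len(parts) == 4:
                contig, start_s, end_s, depth_s = parts
                start, end = int(start_s), int(end_s)
                depth = int(float(depth_s))
                if contig not in dense:
                    raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
                if depth < 0:
                    raise ValueError(f"{path}:{lineno}: negative depth {depth}")
                if not (0 <= start < end <= len(dense[contig])):
                    raise ValueError(
                        f"{path}:{lineno}: span [{start},{end}) exceeds length "
                        f"of contig {contig!r}"
                    )
                dense[contig][start:end] = depth
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 (depth TSV) or 4 (bedGraph) "
                    f"columns, got {len(parts)}"
                )
    return [DepthTrack(c, arr) for c, arr in dense.items()]


def write_bedgraph(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    """Write run-length-encoded bedGraph (0-based half-open)."""
    with open(path, "w") as fh:
        for t in tracks:
            d = np.asarray(t.depth)
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                fh.write(f"{t.contig_id}\t{s}\t{e}\t{int(d[s])}\n")


# ---------------------------------------------------------------------------
# BED / GFF / TSV
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[tuple[Interval, str, float]], path: str | Path
) -> None:
    """Write BED6 rows from (interval, name, score) triples."""
    with open(path, "w") as fh:
        for iv, name, score in intervals:
            strand = iv.strand if iv.strand != "." else "."
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


def read_bed(path: str | Path) -> list[tuple[Interval, str, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append((Interval(contig, start, end, strand), name, score))
    return out


def write_gff3(
    features: Iterable[tuple[Interval, str, str, dict]], path: str | Path
) -> None:
    """Write GFF3 rows from (interval, source, type, attributes) tuples.

    Converts internal 0-based half-open coordinates to GFF's 1-based
    inclusive at this boundary only.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, source, ftype, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            strand = iv.strand if iv.strand != "." else "."
            fh.write(
                f"{iv.contig_id}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# SR4 recoding
# ---------------------------------------------------------------------------

#: Four-state amino-acid recoding (Susko-Roger compositional classes).
#: Classes of sizes 6/4/5/5 mapped onto the symbols A/C/G/T so recoded
#: alignments can be analysed with nucleotide-style 4-state models.
SR4_CLASSES: dict[str, str] = {
    **{aa: "A" for aa in "AGNPST"},
    **{aa: "C" for aa in "CHWY"},
    **{aa: "G" for aa in "DEKQR"},
    **{aa: "T" for aa in "FILMV"},
}

_SR4_PASSTHROUGH = frozenset("-X")


def sr4_recode(protein_sequence: str, table: dict[str, str] | None = None) -> str:
    """Recode an amino-acid sequence (gaps ``-`` and ``X`` preserved) to 4 states."""
    table = SR4_CLASSES if table is None else table
    seq = protein_sequence.upper()
    unknown = sorted(set(seq) - set(table) - _SR4_PASSTHROUGH)
    if unknown:
        raise ValueError(f"unknown residues for SR4 recoding: {unknown}")
    return "".join(c if c in _SR4_PASSTHROUGH else table[c] for c in seq)


# ---------------------------------------------------------------------------
# Small sequence helpers shared across modules
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def merge_intervals(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent (start, end) spans; returns sorted disjoint spans."""
    if not spans:
        return []
    spans = sorted(spans)
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]
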