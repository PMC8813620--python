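"""Synthetic data with ground-truth manifests for every pipeline input.

Generators are pure functions of (seed, parameters).  Defaults emulate the
study conditions the pipeline was designed for: host genomes carrying a
handful of CRISPR arrays (repeats 23-47 nt, spacers 26-50 nt) plus pure
tandem-repeat decoy arrays; mobile-element contigs (>= ~3 kb, some below the
2.8 kb catalogue floor) carrying protospacers with 0-3 substitutions;
coverage tracks from explicitly simulated replicating circular elements;
gene tables with a flat ~900-gene archaeal component and linearly scaling
bacterial/eukaryotic/unassigned components; and protein families at
controlled pairwise identity tiers over a random background.

Background composition is uniform A/C/G/T; substitution-only mutations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CIRCULAR, DepthTrack, Interval, SeqRecord, revcomp
from .replication import simulate_molecules

NT = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class TruthManifest:
    arrays: list = field(default_factory=list)
    protospacers: list = field(default_factory=list)
    contigs: list = field(default_factory=list)
    replication: list = field(default_factory=list)
    gene_params: dict = field(default_factory=dict)
    protein_tiers: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, src: str | Path) -> "TruthManifest":
        text = Path(src).read_text() if isinstance(src, Path) else src
        return cls(**json.loads(text))

    # ---- funnel truths -------------------------------------------------
    @property
    def n_crispr_arrays(self) -> int:
        return sum(1 for a in self.arrays if a["kind"] == "CRISPR")

    @property
    def n_tandem_arrays(self) -> int:
        return sum(1 for a in self.arrays if a["kind"] == "tandem")

    @property
    def all_spacers(self) -> list[str]:
        return [s for a in self.arrays if a["kind"] == "CRISPR" for s in a["spacers"]]

    @property
    def unique_spacers(self) -> set[str]:
        return {min(s, revcomp(s)) for s in self.all_spacers}

    def expected_final_mges(self, min_len: int = 2800) -> set[str]:
        """Representative contigs expected in the final catalogue."""
        hit_contigs = {p["contig"] for p in self.protospacers if p["n_subs"] == 0}
        reps = set()
        for c in self.contigs:
            if c["id"] in hit_contigs and c["duplicate_of"] is None:
                if c["length"] >= min_len:
                    reps.add(c["id"])
        return reps


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, n)])


def _mutate_nt(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    buf = list(seq)
    for p in pos:
        choices = [c for c in "ACGT" if c != buf[p]]
        buf[p] = choices[rng.integers(0, 3)]
    return "".join(buf)


# ---------------------------------------------------------------------------
# Hosts + MGEs
# ---------------------------------------------------------------------------


def gen_host_and_mges(
    seed: int,
    n_arrays: int = 5,
    n_mges: int = 6,
    n_decoys: int = 4,
    mutation_rate: float = 0.0,
    n_tandem: int = 3,
    n_short_mges: int = 1,
    n_duplicates: int = 1,
    host_length: int = 40000,
    repeat_len_bounds: tuple[int, int] = (28, 40),
    spacer_len_bounds: tuple[int, int] = (30, 46),
    repeats_per_array: tuple[int, int] = (4, 7),
    repeat_mutations: int = 0,
    seed_k: int = 10,
) -> tuple[list[SeqRecord], list[SeqRecord], TruthManifest]:
    """Host genome with implanted arrays + MGE/decoy contigs + truth manifest.

    A stated subset of CRISPR spacers is implanted as protospacers in the MGE
    contigs with ``min(3, Binomial(len, mutation_rate))`` substitutions each;
    decoy contigs carry none.  ``repeat_mutations`` > 0 substitutes up to that
    many positions independently in every repeat instance (diverged arrays;
    1 keeps pairwise instance identity >= ~0.93 for typical repeat lengths).
    """
    if spacer_len_bounds[0] < seed_k:
        raise ValueError("spacers would be shorter than the seed k")
    rng = np.random.default_rng(seed)
    manifest = TruthManifest()

    genome = list(_rand_seq(rng, host_length))
    n_slots = n_arrays + n_tandem
    slot_width = host_length // (n_slots + 1)
    if slot_width < 800:
        raise ValueError("host too short for the requested number of arrays")

    spacer_pool: list[str] = []
    for slot in range(n_slots):
        pos = slot_width * (slot + 1) - slot_width // 4
        is_tandem = slot >= n_arrays
        rep_len = int(rng.integers(*repeat_len_bounds))
        repeat = _rand_seq(rng, rep_len)
        n_rep = int(rng.integers(repeats_per_array[0], repeats_per_array[1] + 1))
        spacers = []
        if is_tandem:
            sp = _rand_seq(rng, int(rng.integers(*spacer_len_bounds)))
            spacers = [sp] * (n_rep - 1)
        else:
            # Spacer boundary bases are cycled so no column adjacent to the
            # repeat is shared by all instances: the repeat/spacer boundary
            # is then well-defined and the manifest coordinates are exact.
            for s_idx in range(n_rep - 1):
                sp = _rand_seq(rng, int(rng.integers(*spacer_len_bounds)))
                b = "ACGT"
                sp = (
                    b[s_idx % 4] + b[(s_idx + 1) % 4]
                    + sp[2:-2]
                    + b[(s_idx + 2) % 4] + b[(s_idx + 3) % 4]
                )
                spacers.append(sp)
        parts = []
        for ridx in range(n_rep):
            inst = repeat
            if repeat_mutations > 0:
                inst = _mutate_nt(rng, repeat, int(rng.integers(0, repeat_mutations + 1)))
            parts.append(inst)
            if ridx < n_rep - 1:
                parts.append(spacers[ridx])
        block = "".join(parts)
        genome[pos : pos + len(block)] = list(block)
        manifest.arrays.append(
            {
                "dataset": "host",
                "contig": "host1",
                "start": pos,
                "end": pos + len(block),
                "kind": "tandem" if is_tandem else "CRISPR",
                "repeat": repeat,
                "spacers": spacers,
            }
        )
        if not is_tandem:
            spacer_pool.extend(spacers)

    hosts = [SeqRecord("host1", "".join(genome), CIRCULAR)]

    # MGE and decoy contigs
    contigs: list[SeqRecord] = []
    order = rng.permutation(len(spacer_pool))
    pool_iter = iter(order)

    def next_spacer() -> str:
        try:
            return spacer_pool[next(pool_iter)]
        except StopIteration as exc:  # pragma: no cover - parameter error
            raise ValueError("more protospacers requested than spacers exist") from exc

    for m in range(n_mges):
        short = m < n_short_mges
        length = int(rng.integers(2000, 2500)) if short else int(rng.integers(3200, 9000))
        cid = f"mge{m:02d}"
        seq = list(_rand_seq(rng, length))
        n_ps = int(rng.integers(1, 3))
        used_spans: list[tuple[int, int]] = []
        for _ in range(n_ps):
            sp = next_spacer()
            n_subs = int(min(3, rng.binomial(len(sp), mutation_rate)))
            placed = _mutate_nt(rng, sp, n_subs)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                placed = revcomp(placed)
            while True:  # implants must not overlap each other
                pos = int(rng.integers(100, length - len(sp) - 100))
                if all(
                    pos + len(placed) + 20 <= s or e + 20 <= pos
                    for s, e in used_spans
                ):
                    used_spans.append((pos, pos + len(placed)))
                    break
            seq[pos : pos + len(placed)] = list(placed)
            manifest.protospacers.append(
                {
                    "spacer": sp,
                    "contig": cid,
                    "start": pos,
                    "end": pos + len(placed),
                    "strand": strand,
                    "n_subs": n_subs,
                }
            )
        contigs.append(SeqRecord(cid, "".join(seq)))
        manifest.contigs.append(
            {"id": cid, "length": length, "is_mge": True, "duplicate_of": None}
        )

    long_mges = list(range(n_short_mges, n_mges)) or list(range(n_mges))
    for d in range(n_duplicates if n_mges else 0):
        src = contigs[long_mges[d % len(long_mges)]]
        cid = f"{src.id}dup{d}"
        contigs.append(SeqRecord(cid, src.seq))
        manifest.contigs.append(
            {
                "id": cid,
                "length": len(src),
                "is_mge": True,
                "duplicate_of": src.id,
            }
        )
        for p in [p for p in manifest.protospacers if p["contig"] == src.id]:
            manifest.protospacers.append({**p, "contig": cid})

    for d in range(n_decoys):
        cid = f"decoy{d:02d}"
        length = int(rng.integers(3000, 9000))
        contigs.append(SeqRecord(cid, _rand_seq(rng, length)))
        manifest.contigs.append(
            {"id": cid, "length": length, "is_mge": False, "duplicate_of": None}
        )

    return hosts, contigs, manifest


def gen_external_arrays(
    seed: int,
    host_repeats: list[str],
    n_related: int = 3,
    n_unrelated: int = 3,
    spacer_len_bounds: tuple[int, int] = (30, 46),
) -> tuple[list[SeqRecord], TruthManifest]:
    """Metagenome contigs carrying arrays for recruitment tests.

    Related arrays reuse a host repeat verbatim; unrelated decoy arrays get
    random repeats (recruitment must reject them: precision 1.0).
    """
    rng = np.random.default_rng(seed)
    manifest = TruthManifest()
    contigs = []
    for i in range(n_related + n_unrelated):
        related = i < n_related
        repeat = (
            host_repeats[int(rng.integers(0, len(host_repeats)))]
            if related
            else _rand_seq(rng, int(rng.integers(28, 40)))
        )
        n_rep = int(rng.integers(4, 7))
        parts = []
        spacers = []
        for ridx in range(n_rep):
            parts.append(repeat)
            if ridx < n_rep - 1:
                sp = _rand_seq(rng, int(rng.integers(*spacer_len_bounds)))
                spacers.append(sp)
                parts.append(sp)
        block = "".join(parts)
        flank_l = _rand_seq(rng, 400)
        flank_r = _rand_seq(rng, 400)
        cid = f"ext{i:02d}"
        contigs.append(SeqRecord(cid, flank_l + block + flank_r))
        manifest.arrays.append(
            {
                "dataset": "external",
                "contig": cid,
                "start": 400,
                "end": 400 + len(block),
                "kind": "CRISPR",
                "repeat": repeat,
                "spacers": spacers,
                "related": related,
            }
        )
    return contigs, manifest


# ---------------------------------------------------------------------------
# Replication tracks
# ---------------------------------------------------------------------------


def gen_replication_tracks(
    seed: int,
    specs: list[dict],
    flank: int = 20000,
) -> tuple[list[DepthTrack], list[Interval], TruthManifest]:
    """Embed simulated element coverage in host contigs with baseline flanks.

    Each spec is a dict with keys L, o, a, depth and optional n_molecules.
    Returns (tracks, element intervals, manifest).
    """
    manifest = TruthManifest()
    tracks = []
    elements = []
    for i, spec in enumerate(specs):
        L, o, a, depth = spec["L"], spec["o"], spec["a"], spec["depth"]
        n_mol = spec.get("n_molecules", 20000)
        sub_seed = seed * 1009 + i
        elem = simulate_molecules(L, o, a, n_mol, depth, seed=sub_seed)
        rng = np.random.default_rng(sub_seed + 7)
        left = rng.poisson(depth, flank)
        right = rng.poisson(depth, flank)
        cid = f"track{i:02d}"
        tracks.append(DepthTrack(cid, np.concatenate([left, elem.depth, right])))
        elements.append(Interval(cid, flank, flank + L))
        manifest.replication.append(
            {"contig": cid, "L": L, "o": o, "a": a, "depth": depth, "shape": "linear"}
        )
    return tracks, elements, manifest


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

COG_WEIGHTS = {
    "Archaea": {"J": 0.18, "K": 0.14, "L": 0.13, "C": 0.05, "E": 0.05, "G": 0.04,
                "P": 0.04, "U": 0.02, "Z": 0.01, "O": 0.05, "S": 0.29},
    "Bacteria": {"J": 0.04, "K": 0.05, "L": 0.04, "C": 0.14, "E": 0.13, "G": 0.11,
                 "P": 0.10, "U": 0.02, "Z": 0.01, "O": 0.05, "S": 0.31},
    "Eukaryota": {"J": 0.05, "K": 0.05, "L": 0.05, "C": 0.04, "E": 0.04, "G": 0.03,
                  "P": 0.03, "U": 0.20, "Z": 0.12, "O": 0.15, "S": 0.24},
}


def gen_gene_tables(
    seed: int,
    n_genomes: int = 8,
    archaea_base: float = 900.0,
    slopes: dict | None = None,
    noise_sigma: float = 30.0,
    g_range: tuple[int, int] = (1800, 4600),
) -> tuple[pd.DataFrame, dict[str, int], TruthManifest]:
    """Gene taxonomy tables under the domain-specific scaling model.

    Archaeal counts are flat at ``archaea_base``; Bacteria and Eukaryota scale
    linearly with the planned total G (``slopes`` maps group ->
    (intercept, slope)); Unassigned absorbs the remainder so counts partition
    G.  Genome sizes are G x 1000 bp.  Returns (table, genome sizes, manifest).
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    slopes = slopes or {"Bacteria": (-300.0, 0.45), "Eukaryota": (0.0, 0.10)}
    for grp, (_, sl) in slopes.items():
        if sl < 0:
            raise ValueError(f"negative slope for {grp}")
    rng = np.random.default_rng(seed)
    # planned totals: evenly spaced multiples of 100 across a ~2.5x range
    G_planned = np.linspace(g_range[0], g_range[1], n_genomes)
    G_planned = (np.round(G_planned / 100) * 100).astype(int)

    rows = []
    sizes: dict[str, int] = {}
    warned = False
    for gi, G in enumerate(G_planned):
        gid = f"genome{gi:02d}"
        sizes[gid] = int(G) * 1000
        nA = archaea_base + (rng.normal(0, noise_sigma) if noise_sigma else 0.0)
        nB = slopes["Bacteria"][0] + slopes["Bacteria"][1] * G + (
            rng.normal(0, noise_sigma) if noise_sigma else 0.0
        )
        nE = slopes["Eukaryota"][0] + slopes["Eukaryota"][1] * G + (
            rng.normal(0, noise_sigma) if noise_sigma else 0.0
        )
        nA, nB, nE = int(round(nA)), int(round(nB)), int(round(nE))
        nU = int(G) - nA - nB - nE
        counts = {"Archaea": nA, "Bacteria": nB, "Eukaryota": nE, "Unassigned": nU}
        for grp, n in counts.items():
            if n < 0:
                if not warned:
                    import logging

                    logging.getLogger("mobilome").warning(
                        "negative generated count clipped for %s/%s", gid, grp
                    )
                    warned = True
                counts[grp] = 0
        gene_no = 0
        for grp in ("Archaea", "Bacteria", "Eukaryota", "Unassigned"):
            n = counts[grp]
            weights = COG_WEIGHTS.get(grp)
            if weights:
                cats = list(weights)
                p = np.array([weights[c] for c in cats])
                draws = rng.choice(cats, size=n, p=p / p.sum())
            else:
                draws = np.full(n, None, dtype=object)
            lengths = rng.integers(200, 2500, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "genome_id": gid,
                        "gene_id": [f"{gid}_g{i:05d}" for i in range(gene_no, gene_no + n)],
                        "gene_length_nt": lengths,
                        "taxon_group": grp,
                        "cog_category": draws,
                    }
                )
            )
            gene_no += n

    manifest = TruthManifest(
        gene_params={
            "archaea_base": archaea_base,
            "slopes": {
                "Archaea": (archaea_base, 0.0),
                "Bacteria": list(slopes["Bacteria"]),
                "Eukaryota": list(slopes["Eukaryota"]),
                "Unassigned": (
                    -archaea_base - slopes["Bacteria"][0] - slopes["Eukaryota"][0],
                    1.0 - slopes["Bacteria"][1] - slopes["Eukaryota"][1],
                ),
            },
            "noise_sigma": noise_sigma,
            "G": [int(g) for g in G_planned],
        }
    )
    table = pd.concat(rows, ignore_index=True)
    return table, sizes, manifest


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------


def gen_protein_families(
    seed: int,
    tiers: list[tuple[float, int, int]] | None = None,
    n_background: int = 6,
    background_len: int = 300,
    genomes: tuple[str, ...] = ("g1", "g2", "g3", "g4"),
    identity_tolerance: float = 0.02,
) -> tuple[list[SeqRecord], dict[str, str], dict[str, str], TruthManifest]:
    """Protein families at controlled pairwise identity tiers.

    Each tier is (target pairwise identity, family size, protein length).
    Members are the family ancestor with an exact number of substituted
    positions chosen so realized pairwise Hamming identities land within
    ``identity_tolerance`` of the target (resampled until they do).  Returns
    (proteins, genome ids, taxon labels, manifest); the first member of every
    even-indexed family is labelled Eukaryota.
    """
    tiers = tiers if tiers is not None else [
        (1.0, 4, 300), (0.6, 5, 280), (0.3, 5, 320), (0.15, 4, 260)
    ]
    rng = np.random.default_rng(seed)
    proteins: list[SeqRecord] = []
    genome_ids: dict[str, str] = {}
    labels: dict[str, str] = {}
    manifest = TruthManifest()

    def mutate_exact(ancestor: str, k: int) -> str:
        pos = rng.choice(len(ancestor), size=k, replace=False)
        buf = list(ancestor)
        for p in pos:
            options = [c for c in AA if c != buf[p]]
            buf[p] = options[rng.integers(0, len(options))]
        return "".join(buf)

    def hamming_identity(x: str, y: str) -> float:
        return sum(1 for a, b in zip(x, y) if a == b) / len(x)

    for t_idx, (target, size, length) in enumerate(tiers):
        ancestor = "".join(AA[rng.integers(0, len(AA), length)])
        k = int(round((1.0 - np.sqrt(target)) * length))
        members: list[str] = []
        for _ in range(size):
            for _attempt in range(500):
                cand = mutate_exact(ancestor, k) if k else ancestor
                if all(
                    abs(hamming_identity(cand, m) - target) <= identity_tolerance
                    for m in members
                ):
                    members.append(cand)
                    break
            else:
                raise RuntimeError(
                    f"could not hit identity {target} within tolerance"
                )
        ids = []
        for m_idx, seq in enumerate(members):
            pid = f"tier{t_idx}_p{m_idx}"
            proteins.append(SeqRecord(pid, seq))
            genome_ids[pid] = genomes[m_idx % len(genomes)]
            if t_idx % 2 == 0 and m_idx == 0:
                labels[pid] = "Eukaryota"
            else:
                labels[pid] = "Archaea"
            ids.append(pid)
        manifest.protein_tiers.append(
            {"target_identity": target, "members": ids, "length": length}
        )

    for b in range(n_background):
        pid = f"bg_p{b}"
        proteins.append(
            SeqRecord(pid, "".join(AA[rng.integers(0, len(AA), background_len)]))
        )
        genome_ids[pid] = genomes[b % len(genomes)]
        labels[pid] = "Unassigned"
    return proteins, genome_ids, labels, manifest
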