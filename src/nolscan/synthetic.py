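"""Synthetic genomes with planted nucleosome-inhibitory boundary elements.

The generator emits everything the analysis consumes — genome FASTA,
genePred annotation, gene-category map, and separable training sets for
the NOL scorer — together with a ground-truth ledger, so the whole
pipeline can be exercised and validated without downloading a genome.

What it emulates
----------------
* multi-exon gene structures with canonical GT/AG splice dinucleotides,
  ~half of the genes on the minus strand;
* a "planted" gene category whose introns carry a nucleosome-inhibitory
  (AT-rich) element positioned so the 50 bp scoring window centered at a
  fixed offset into the intron (default 26 nt, both boundary sides)
  uniquely captures it;
* the planted category's distinct genomic characteristics: elevated exon
  counts (median ~35 vs ~7 background) and shorter introns;
* decoy categories (random gene sets) for enrichment specificity checks;
* nucleosome-forming (GC-rich, ~10 bp periodic) versus inhibitory
  (AT-rich) training 50-mers, linearly separable by construction.

Element layout
--------------
Within a planted intron, the donor-side design (transcript-sense offsets,
0 = boundary exonic base) is::

    exon ...[G/C wall]G | GT A [T-rich core] TTT C [G/C wall]... intron
                      0   12 3   4..o+21    ^o+22..o+24 ^o+25 o+26..

and the acceptor-side design is its mirror around the AG acceptor, whose G
(offset -1) conveniently falls just outside the 50 bp window centered at
-o.  On the donor side the window centered at +o unavoidably contains the
donor G (offset +1), and the window one step further into the intron can
never hold fewer A/T bases — so the 26-vs-27 decision rests on k-mer
*identities* at the window edges.  The training sets are therefore
composition-asymmetric (forming: C-biased G/C; inhibitory: T-biased A/T,
poly(dT)-tract-like), which gives the edge comparisons a systematic sign:
stepping the window from +o to +o+1 swaps {C, TC, TTC} in for {G, GT, GTA}
(margin > 0 for every training draw), while stepping to +o-1 swaps
{T, TT, TTT} in for {G, GG, GGT} (margin << 0), pinning the score minimum
exactly at the planted offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genome_io import (GeneModel, reverse_complement, write_fasta,
                        write_genepred)
from .stats_enrichment import CategoryMap

PLANTED_CATEGORY = "planted_inhibitory_element"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic genome; defaults are the study conditions."""

    n_genes: int = 2000
    planted_fraction: float = 0.15
    planted_offset_upstream: int = 26    # nt into the intron, acceptor side
    planted_offset_downstream: int = 26  # nt into the intron, donor side
    plant_sides: tuple[str, ...] = ("exon_start", "exon_end")
    #: fraction of a planted gene's introns that carry the element (always
    #: >=1 per gene); keeps feature-positive boundaries a minority so
    #: equal-size control samples of other boundaries exist
    plant_intron_fraction: float = 0.4
    # exon-count distributions: value = min + NegBinom(r, r/(r+mean-min))
    exon_count_background: tuple[int, float, float] = (1, 2.0, 6.0)   # median ~7
    exon_count_planted: tuple[int, float, float] = (2, 8.0, 33.0)     # median ~35
    # length distributions: log-normal (median, sigma) with a hard floor
    exon_len: tuple[float, float, int] = (150.0, 0.35, 80)
    intron_len_background: tuple[float, float, int] = (420.0, 0.5, 170)
    intron_len_planted: tuple[float, float, int] = (240.0, 0.4, 170)
    intergenic_len: tuple[float, float, int] = (300.0, 0.3, 100)
    gc_background: float = 0.50
    gc_exon: float = 0.52
    n_decoy_categories: int = 20
    genes_per_chrom: int = 250
    # planted-element composition (sense strand)
    core_t_fraction: float = 0.65    # T vs A within the inhibitory core
    wall_c_fraction: float = 0.70    # C vs G within the guard walls
    # training sets
    n_train_per_class: int = 300
    train_c_fraction: float = 0.70   # C vs G in forming examples
    train_t_fraction: float = 0.65   # T vs A in inhibitory examples
    train_periodic_dinuc: str = "TT"
    train_period: int = 10
    seed: int = 1

    def validate(self) -> None:
        for name, o in (("upstream", self.planted_offset_upstream),
                        ("downstream", self.planted_offset_downstream)):
            if o < 26:
                raise ValueError(f"planted {name} offset {o} < 26: the designed "
                                 "element would collide with the splice site")
        need = (self.planted_offset_upstream + 50 +
                self.planted_offset_downstream + 50 + 2)
        floor = self.intron_len_planted[2]
        if floor < need:
            raise ValueError(f"planted intron floor {floor} cannot hold both "
                             f"designed edges ({need} nt required)")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.exon_len[2] < 42:
            raise ValueError("exon floor too short for the designed exon walls")


@dataclass
class GroundTruthLedger:
    """What was planted where, for recovery tests."""

    categories: dict[str, list[str]] = field(default_factory=dict)
    planted_genes: list[str] = field(default_factory=list)
    #: per planted boundary: chrom, genomic_pos, strand, side, offset, core span
    planted_boundaries: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    models: list[GeneModel]
    category_map: CategoryMap
    ledger: GroundTruthLedger
    spec: SyntheticSpec

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": str(outdir / "genome.fa"),
            "genes": str(outdir / "genes.genePred"),
            "categories": str(outdir / "categories.tsv"),
            "ledger": str(outdir / "ledger.json"),
        }
        write_fasta(self.genome, paths["genome"])
        write_genepred(self.models, paths["genes"])
        self.category_map.write_tsv(paths["categories"])
        self.ledger.to_json(paths["ledger"])
        return paths


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _choice(rng, n: int, letters: str) -> np.ndarray:
    return rng.choice(np.frombuffer(letters.encode(), dtype="S1"), size=n)


def _wall(rng, n: int, spec: "SyntheticSpec") -> np.ndarray:
    """Guard wall: G/C with a C bias (matches the forming training set)."""
    p = spec.wall_c_fraction
    return rng.choice(np.frombuffer(b"CG", dtype="S1"), size=n, p=[p, 1 - p])


def _core(rng, n: int, spec: "SyntheticSpec") -> np.ndarray:
    """Inhibitory core: A/T with a T bias (poly(dT)-tract-like)."""
    p = spec.core_t_fraction
    return rng.choice(np.frombuffer(b"TA", dtype="S1"), size=n, p=[p, 1 - p])


def _lognormal_len(rng, median: float, sigma: float, floor: int, n: int) -> np.ndarray:
    vals = rng.lognormal(mean=np.log(median), sigma=sigma, size=n)
    return np.maximum(np.rint(vals).astype(int), floor)


def _nbinom_count(rng, minimum: int, r: float, mean: float) -> int:
    p = r / (r + (mean - minimum))
    return minimum + int(rng.negative_binomial(r, p))


# ---------------------------------------------------------------------------
# planted element design

def _plant_donor_edge(arr: np.ndarray, b: int, o: int, rng,
                      spec: "SyntheticSpec") -> tuple[int, int]:
    """Write the donor-side design around sense index ``b`` (= offset 0).

    Returns the (start, end) half-open sense span of the A/T core.  The
    intron begins with the canonical GT at offsets +1,+2; the scoring
    window centered at +o covers offsets [o-25, o+24] = the G/T donor plus
    the core plus one C guard.
    """
    arr[b - 20:b] = _wall(rng, 20, spec)            # exon tail wall
    arr[b] = b"G"                                   # forced exon last base
    arr[b + 1], arr[b + 2] = b"G", b"T"             # donor (canonical)
    arr[b + 3] = b"A"
    arr[b + 4:b + o + 22] = _core(rng, o + 18, spec)     # T-rich core interior
    arr[b + o + 22:b + o + 25] = b"T"               # forced TTT core end
    arr[b + o + 25] = b"C"                          # guard: first wall base
    arr[b + o + 26:b + o + 51] = _wall(rng, 25, spec)    # intronic wall
    return b + 3, b + o + 25  # A/T core span (sense, half-open)


def _plant_acceptor_edge(arr: np.ndarray, b: int, o: int, rng,
                         spec: "SyntheticSpec") -> tuple[int, int]:
    """Write the acceptor-side design around sense index ``b`` (= offset 0).

    The scoring window centered at -o covers [-o-25, -o+24]; at o=26 that
    is the A/T core plus the acceptor A, with the acceptor G just outside.
    """
    arr[b - o - 50:b - o - 25] = _wall(rng, 25, spec)    # intronic wall
    arr[b - o - 25:b - 2] = _core(rng, o + 23, spec)     # T-rich core
    arr[b - 2], arr[b - 1] = b"A", b"G"                  # acceptor (canonical)
    arr[b:b + 21] = _wall(rng, 21, spec)                 # exon head wall
    arr[b] = b"G"
    return b - o - 25, b - 1


# ---------------------------------------------------------------------------

def _build_gene(rng, spec: SyntheticSpec, planted: bool):
    """Sense-strand gene sequence + relative exon intervals + planted spans."""
    if planted:
        n_exons = _nbinom_count(rng, *spec.exon_count_planted)
        intron_median, intron_sigma, intron_floor = spec.intron_len_planted
    else:
        n_exons = _nbinom_count(rng, *spec.exon_count_background)
        intron_median, intron_sigma, intron_floor = spec.intron_len_background
    exon_lens = _lognormal_len(rng, *spec.exon_len[:2], spec.exon_len[2], n_exons)
    intron_lens = _lognormal_len(rng, intron_median, intron_sigma, intron_floor,
                                 max(n_exons - 1, 0))
    parts: list[np.ndarray] = []
    exon_rel: list[tuple[int, int]] = []
    pos = 0
    for i, el in enumerate(exon_lens):
        parts.append(_random_seq(rng, int(el), spec.gc_exon))
        exon_rel.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            il = int(intron_lens[i])
            intron = _random_seq(rng, il, spec.gc_background)
            intron[0], intron[1] = b"G", b"T"
            intron[-2], intron[-1] = b"A", b"G"
            parts.append(intron)
            pos += il
    arr = np.concatenate(parts)
    planted_spans = []  # (side, boundary_rel_pos, core_lo, core_hi)
    if planted and n_exons >= 2:
        chosen = [i for i in range(n_exons - 1)
                  if rng.random() < spec.plant_intron_fraction]
        if not chosen:
            chosen = [int(rng.integers(n_exons - 1))]
        for i in chosen:
            donor_b = exon_rel[i][1] - 1          # last exonic base of exon i
            acceptor_b = exon_rel[i + 1][0]       # first exonic base of exon i+1
            if "exon_end" in spec.plant_sides:
                lo, hi = _plant_donor_edge(arr, donor_b,
                                           spec.planted_offset_downstream,
                                           rng, spec)
                planted_spans.append(("exon_end", donor_b, lo, hi))
            if "exon_start" in spec.plant_sides:
                lo, hi = _plant_acceptor_edge(arr, acceptor_b,
                                              spec.planted_offset_upstream,
                                              rng, spec)
                planted_spans.append(("exon_start", acceptor_b, lo, hi))
    return arr, exon_rel, planted_spans


def simulate_genome(spec: SyntheticSpec | None = None) -> SimulatedDataset:
    """Generate a genome + annotation + categories + ground-truth ledger.

    Deterministic for a given spec (byte-identical outputs per seed).
    Genes are non-overlapping, placed on chromosomes of
    ``spec.genes_per_chrom`` genes each; ~half are on the minus strand
    (the annotation stores ascending genomic exon coordinates either way).
    """
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_planted = int(round(spec.n_genes * spec.planted_fraction))
    planted_idx = set(rng.choice(spec.n_genes, size=n_planted, replace=False).tolist())

    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    ledger = GroundTruthLedger()
    chrom_parts: list[np.ndarray] = []
    chrom_pos = 0
    chrom_id = 1

    def flush_chrom():
        nonlocal chrom_parts, chrom_pos, chrom_id
        if chrom_parts:
            genome[f"chr{chrom_id}"] = b"".join(
                p.tobytes() for p in chrom_parts).decode()
            chrom_id += 1
            chrom_parts = []
            chrom_pos = 0

    for gi in range(spec.n_genes):
        planted = gi in planted_idx
        gene_name = f"GENE{gi:05d}"
        tx_name = f"TX{gi:05d}.1"
        arr, exon_rel, spans = _build_gene(rng, spec, planted)
        strand = "+" if rng.random() < 0.5 else "-"
        gap = int(_lognormal_len(rng, *spec.intergenic_len[:2],
                                 spec.intergenic_len[2], 1)[0])
        chrom_parts.append(_random_seq(rng, gap, spec.gc_background))
        chrom_pos += gap
        gene_start = chrom_pos
        L = len(arr)
        if strand == "+":
            chrom_parts.append(arr)
            exons = [(gene_start + s, gene_start + e) for s, e in exon_rel]
        else:
            rc = np.frombuffer(
                reverse_complement(arr.tobytes().decode()).encode(), dtype="S1")
            chrom_parts.append(rc.copy())
            exons = sorted((gene_start + L - e, gene_start + L - s)
                           for s, e in exon_rel)
        chrom_pos += L
        chrom = f"chr{chrom_id}"
        models.append(GeneModel(
            name=tx_name, gene=gene_name, chrom=chrom, strand=strand,
            exon_starts=tuple(s for s, _ in exons),
            exon_ends=tuple(e for _, e in exons)))
        if planted:
            ledger.planted_genes.append(gene_name)
            for side, b_rel, lo, hi in spans:
                if strand == "+":
                    gpos = gene_start + b_rel
                    core = (gene_start + lo, gene_start + hi)
                else:
                    gpos = gene_start + L - 1 - b_rel
                    core = (gene_start + L - hi, gene_start + L - lo)
                offset = (spec.planted_offset_upstream if side == "exon_start"
                          else spec.planted_offset_downstream)
                ledger.planted_boundaries.append({
                    "gene": gene_name, "chrom": chrom, "genomic_pos": int(gpos),
                    "strand": strand, "side": side,
                    "offset": -offset if side == "exon_start" else offset,
                    "core_start": int(core[0]), "core_end": int(core[1])})
        if (gi + 1) % spec.genes_per_chrom == 0:
            tail = int(_lognormal_len(rng, *spec.intergenic_len[:2],
                                      spec.intergenic_len[2], 1)[0])
            chrom_parts.append(_random_seq(rng, tail, spec.gc_background))
            flush_chrom()
    if chrom_parts:
        chrom_parts.append(_random_seq(rng, spec.intergenic_len[2],
                                       spec.gc_background))
        flush_chrom()

    all_genes = [m.gene for m in models]
    mapping: dict[str, set[str]] = {}
    for g in ledger.planted_genes:
        mapping.setdefault(g, set()).add(PLANTED_CATEGORY)
    ledger.categories[PLANTED_CATEGORY] = sorted(ledger.planted_genes)
    decoy_size = max(len(ledger.planted_genes), 1)
    for d in range(spec.n_decoy_categories):
        label = f"decoy_{d + 1:02d}"
        members = rng.choice(len(all_genes), size=min(decoy_size, len(all_genes)),
                             replace=False)
        ledger.categories[label] = sorted(all_genes[i] for i in members)
        for i in members:
            mapping.setdefault(all_genes[i], set()).add(label)
    category_map = CategoryMap(mapping, set(all_genes))
    return SimulatedDataset(genome=genome, models=models,
                            category_map=category_map, ledger=ledger, spec=spec)


def make_training_set(spec: SyntheticSpec | None = None):
    """Nucleosome-forming vs inhibitory training 50-mers.

    Forming examples are G/C sequences (C-biased, ``train_c_fraction``)
    with a short T dinucleotide placed every ``train_period`` bp — the
    classic ~10 bp rotational periodicity of forming sequences.
    Inhibitory examples are T-biased A/T tracts (``train_t_fraction``),
    matching the poly(dT)-like composition of the planted element.  The
    sets are linearly separable under k<=3 composition features by
    construction.  Deterministic per seed (a fixed offset of the genome
    seed, so genome and training draws are independent streams).
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng((spec.seed + 101_393) % 2**31)
    gc = np.frombuffer(b"CG", dtype="S1")
    at = np.frombuffer(b"TA", dtype="S1")
    pC, pT = spec.train_c_fraction, spec.train_t_fraction
    pos, neg = [], []
    for _ in range(spec.n_train_per_class):
        s = rng.choice(gc, size=50, p=[pC, 1 - pC])
        for start in range(spec.train_period // 2, 50 - 1, spec.train_period):
            for j, ch in enumerate(spec.train_periodic_dinuc):
                s[start + j] = ch.encode()
        pos.append(s.tobytes().decode())
        neg.append(rng.choice(at, size=50, p=[pT, 1 - pT]).tobytes().decode())
    return pos, neg


def write_training_fastas(pos, neg, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"train_pos": str(outdir / "train_pos.fa"),
             "train_neg": str(outdir / "train_neg.fa")}
    write_fasta({f"forming_{i:04d}": s for i, s in enumerate(pos)}, paths["train_pos"])
    write_fasta({f"inhibitory_{i:04d}": s for i, s in enumerate(neg)}, paths["train_neg"])
    return paths
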