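"""Readers/writers for the formats the pipeline touches and boundary extraction.

Coordinates are 0-based half-open throughout (UCSC table convention).
Boundary-relative offsets, produced downstream, are the only signed
coordinates in the package.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

COMPLEMENT = str.maketrans("ACGTNacgtnRYSWKMBDHVryswkmbdhv",
                           "TGCANtgcanYRSWMKVHDByrswmkvhdb")


class FormatError(ValueError):
    """A malformed input file."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One transcript's exon structure (genePred semantics).

    Exon intervals are half-open, sorted in ascending genomic order
    regardless of strand.
    """

    name: str
    gene: str
    chrom: str
    strand: str
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.name}")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ValueError(f"{self.name}: exon start/end lists inconsistent")
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if e <= s:
                raise ValueError(f"{self.name}: empty/inverted exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.name}: exons overlap or unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_starts)

    @property
    def tx_start(self) -> int:
        return self.exon_starts[0]

    @property
    def tx_end(self) -> int:
        return self.exon_ends[-1]

    def exon_sizes(self) -> list[int]:
        return [e - s for s, e in zip(self.exon_starts, self.exon_ends)]

    def intron_sizes(self) -> list[int]:
        return [s - e for e, s in zip(self.exon_ends[:-1], self.exon_starts[1:])]


@dataclass(frozen=True)
class BoundarySite:
    """An intron-exon junction, in transcript (sense-strand) orientation.

    ``side="exon_start"`` is the splice-acceptor side: the transcript-sense
    5' edge of an internal exon; ``genomic_pos`` is the first exonic base on
    that side (the genomically last exonic base for minus-strand models).
    ``side="exon_end"`` is the splice-donor side.
    """

    gene_model: GeneModel
    exon_index: int
    side: str
    genomic_pos: int
    strand: str

    @property
    def chrom(self) -> str:
        return self.gene_model.chrom

    @property
    def gene(self) -> str:
        return self.gene_model.gene

    def dedup_key(self) -> tuple[str, int, str, str]:
        """Key identifying the physical junction (shared across isoforms)."""
        return (self.chrom, self.genomic_pos, self.strand, self.side)


@dataclass
class SignalTrack:
    """Per-base signal values; positions without data carry NaN."""

    values: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions outside coverage are NaN."""
        out = np.full(end - start, np.nan)
        arr = self.values.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start:hi - start] = arr[lo:hi]
        return out


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into {name: uppercase sequence}.

    Duplicate record names and headerless content are rejected.
    """
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header")
                if name in genome:
                    raise FormatError(f"{path}: duplicate record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header")
                chunks.append(line)
    if name is None:
        raise FormatError(f"{path}: empty FASTA file")
    genome[name] = "".join(chunks).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# genePred

#: UCSC genePred core columns (refGene layout drops the leading bin field;
#: both are accepted on read).
GENEPRED_COLUMNS = [
    "name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd",
    "exonCount", "exonStarts", "exonEnds",
]


def _parse_int_list(text: str) -> tuple[int, ...]:
    return tuple(int(x) for x in text.rstrip(",").split(",") if x != "")


def read_genepred(path) -> list[GeneModel]:
    """Read a UCSC genePred(-extended) table into GeneModels.

    The gene field is taken from the gene-symbol column (name2, column 12 of
    refGene) when present, else the transcript name.  Rows may carry a
    leading numeric ``bin`` column (as refGene dumps do); it is detected and
    skipped.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            # refGene dumps prepend an integer bin; strand is col 3 then.
            if len(fields) > 3 and fields[2] in ("+", "-") and fields[1] not in ("+", "-"):
                pass  # plain genePred: name chrom strand ...
            elif len(fields) > 4 and fields[3] in ("+", "-"):
                fields = fields[1:]  # binned refGene layout
            if len(fields) < 10:
                raise FormatError(f"{path}:{lineno}: expected >=10 genePred columns")
            try:
                name, chrom, strand = fields[0], fields[1], fields[2]
                exon_count = int(fields[7])
                starts = _parse_int_list(fields[8])
                ends = _parse_int_list(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if len(starts) != exon_count or len(ends) != exon_count:
                raise FormatError(
                    f"{path}:{lineno}: exonCount={exon_count} but "
                    f"{len(starts)} starts / {len(ends)} ends")
            gene = fields[11] if len(fields) > 11 and fields[11] else name
            try:
                models.append(GeneModel(name=name, gene=gene, chrom=chrom,
                                        strand=strand, exon_starts=starts,
                                        exon_ends=ends))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return models


def write_genepred(models: Iterable[GeneModel], path) -> None:
    """Write genePred-extended rows (12 columns, name2 = gene symbol)."""
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            row = [m.name, m.chrom, m.strand, str(m.tx_start), str(m.tx_end),
                   str(m.tx_start), str(m.tx_end), str(m.n_exons),
                   starts, ends, "0", m.gene]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Boundary extraction

def extract_boundaries(models: Iterable[GeneModel]) -> list[BoundarySite]:
    """All intron-exon junctions of multi-exon models, in sense orientation.

    A model with E exons yields E-1 acceptor-side (exon_start) and E-1
    donor-side (exon_end) sites; the transcript's outermost edges (TSS/TES)
    are not intron-exon boundaries and are excluded.  For minus-strand
    models the transcript-sense 5' edge of an exon is its genomic *end*
    side, and exon_index counts exons in transcript order.
    """
    sites: list[BoundarySite] = []
    for m in models:
        e = m.n_exons
        if e < 2:
            continue
        if m.strand == "+":
            for i in range(1, e):  # acceptor at the start of exons 2..E
                sites.append(BoundarySite(m, i, "exon_start", m.exon_starts[i], "+"))
            for i in range(0, e - 1):  # donor at the end of exons 1..E-1
                sites.append(BoundarySite(m, i, "exon_end", m.exon_ends[i] - 1, "+"))
        else:
            # transcript order is reversed genomic order
            for ti in range(1, e):  # acceptor side of transcript exons 2..E
                gi = e - 1 - ti
                sites.append(BoundarySite(m, ti, "exon_start", m.exon_ends[gi] - 1, "-"))
            for ti in range(0, e - 1):
                gi = e - 1 - ti
                sites.append(BoundarySite(m, ti, "exon_end", m.exon_starts[gi], "-"))
    return sites


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path) -> SignalTrack:
    """Expand a 4-column bedGraph into per-base values.

    Overlapping intervals are ambiguous and rejected; touching intervals
    are fine.  Positions never covered are NaN.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: bad interval [{start},{end})")
            if not np.isfinite(value):
                raise FormatError(f"{path}:{lineno}: non-finite value")
            intervals.setdefault(chrom, []).append((start, end, value))
    track = SignalTrack()
    for chrom, ivs in intervals.items():
        ivs.sort()
        prev_end = 0
        for start, end, _ in ivs:
            if start < prev_end:
                raise FormatError(f"{path}: overlapping intervals on {chrom} at {start}")
            prev_end = end
        arr = np.full(ivs[-1][1], np.nan)
        for start, end, value in ivs:
            arr[start:end] = value
        track.values[chrom] = arr
    return track


def write_bedgraph(track: SignalTrack, path) -> None:
    """Write NaN-free runs of equal value as bedGraph intervals.

    Values are written with full float64 precision so a read/write cycle
    is lossless.
    """
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            finite = np.isfinite(arr)
            i = 0
            n = len(arr)
            while i < n:
                if not finite[i]:
                    i += 1
                    continue
                j = i + 1
                while j < n and finite[j] and arr[j] == arr[i]:
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{arr[i]:.17g}\n")
                i = j


def write_bed6(sites_and_scores, path) -> None:
    """Export called feature sites as BED6.

    ``sites_and_scores`` yields (BoundarySite, score) pairs; name is
    ``gene:side`` and score is the minimum's signed offset.
    """
    with open(path, "w") as fh:
        for site, score in sites_and_scores:
            fh.write("\t".join([
                site.chrom, str(site.genomic_pos), str(site.genomic_pos + 1),
                f"{site.gene}:{site.side}", str(score), site.strand,
            ]) + "\n")


def log_warning(msg: str) -> None:
    print(f"[nolscan] WARNING: {msg}", file=sys.stderr)
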