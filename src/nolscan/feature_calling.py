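"""Minima histograms, feature groups (U-26 / D+26) and their overlap.

A *feature group* collects the boundaries whose score minimum falls at a
target signed offset — by default 26 nt into the intron upstream of exon
starts (U-26) or downstream of exon ends (D+26) — and the genes owning
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundary_profiles import DEFAULT_HALF_WIDTH, MinimumCall, dedup_calls


@dataclass
class MinimaHistogram:
    side: str
    offsets: np.ndarray            # [-half_width, +half_width]
    counts: np.ndarray             # integer counts, same length
    n_boundaries: int

    def modal_offset(self) -> int | None:
        """Offset with the highest count (smallest offset wins exact ties)."""
        if self.n_boundaries == 0:
            return None
        best = np.flatnonzero(self.counts == self.counts.max())
        return int(self.offsets[best[np.argmin(np.abs(self.offsets[best]))]])

    def as_dict(self) -> dict[int, int]:
        return {int(o): int(c) for o, c in zip(self.offsets, self.counts)}


@dataclass
class FeatureGroup:
    label: str
    side: str
    offset: int
    boundaries: set = field(default_factory=set)     # dedup keys
    genes: set = field(default_factory=set)
    fraction_of_genes: float = 0.0


def minima_histogram(calls, side: str,
                     half_width: int = DEFAULT_HALF_WIDTH) -> MinimaHistogram:
    """Histogram of minimum offsets for one boundary side.

    Calls are deduplicated by physical junction first; every offset in
    [-half_width, +half_width] appears, with count 0 if never called.
    """
    calls = dedup_calls([c for c in calls if c.site.side == side])
    offsets = np.arange(-half_width, half_width + 1)
    counts = np.zeros(len(offsets), dtype=int)
    for c in calls:
        if abs(c.offset) <= half_width:
            counts[c.offset + half_width] += 1
    return MinimaHistogram(side=side, offsets=offsets, counts=counts,
                           n_boundaries=int(counts.sum()))


def eligible_genes(models) -> set[str]:
    """Genes with at least one intron-exon boundary (multi-exon genes)."""
    return {m.gene for m in models if m.n_exons >= 2}


def select_feature_group(calls, side: str, offset: int, models=None,
                         label: str | None = None,
                         tolerance: int = 0) -> FeatureGroup:
    """Boundaries (and their genes) whose minimum sits exactly at ``offset``.

    A gene belongs to the group iff at least one of its boundaries of the
    given side is called at the target offset (within ``tolerance`` nt;
    default exact).  ``fraction_of_genes`` is computed against the genes
    with >=1 eligible boundary when ``models`` is given.
    """
    if label is None:
        prefix = "U" if side == "exon_start" else "D"
        label = f"{prefix}{offset:+d}"
    group = FeatureGroup(label=label, side=side, offset=offset)
    for c in dedup_calls([c for c in calls if c.site.side == side]):
        if abs(c.offset - offset) <= tolerance:
            group.boundaries.add(c.site.dedup_key())
            group.genes.add(c.site.gene)
    if models is not None:
        universe = eligible_genes(models)
        group.fraction_of_genes = (len(group.genes & universe) / len(universe)
                                   if universe else 0.0)
    return group


def group_overlap(group_a: FeatureGroup, group_b: FeatureGroup):
    """Venn counts (only_a, shared, only_b) over the two groups' genes.

    The shared fraction quoted alongside is shared / |A union B|.
    """
    a, b = group_a.genes, group_b.genes
    shared = len(a & b)
    only_a, only_b = len(a - b), len(b - a)
    union = only_a + shared + only_b
    return {
        "only_a": only_a, "shared": shared, "only_b": only_b,
        "label_a": group_a.label, "label_b": group_b.label,
        "shared_fraction_of_union": shared / union if union else 0.0,
    }
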