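"""Strand-symmetric dinucleotide composition around acceptor-side boundaries.

The 16 dinucleotides collapse to 10 classes when each is identified with
its reverse complement (6 complementary pairs plus the 4 self-complementary
singletons AT, CG, GC, TA).  Profiles count overlapping sense-strand
dinucleotides over offsets -40..+10 around exon-start boundaries and
compare a feature group against seeded random samples of the remaining
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import log_warning, reverse_complement

DEFAULT_REGION = (-40, 10)


def _build_classes() -> dict[str, str]:
    mapping = {}
    for a in "ACGT":
        for b in "ACGT":
            d = a + b
            rc = reverse_complement(d)
            lo = min(d, rc)
            mapping[d] = lo if d == rc else f"{lo}/{reverse_complement(lo)}"
    return mapping


#: dinucleotide -> class label (reverse-complement equivalence)
DINUC_CLASS = _build_classes()
#: the 10 class labels, sorted
DINUC_CLASSES = sorted(set(DINUC_CLASS.values()))


def dinuc_classify(dinuc: str) -> str | None:
    """Class label of a dinucleotide; None for ambiguous letters."""
    return DINUC_CLASS.get(dinuc.upper())


@dataclass
class DinucProfile:
    label: str
    region: tuple[int, int]
    n_boundaries: int
    counts: dict[str, int]               # whole region, per class
    intron_counts: dict[str, int]        # sub-region -40..-1 (pair start intronic)
    exon_counts: dict[str, int]          # sub-region 0..+10

    def total(self) -> int:
        return sum(self.counts.values())


def _window_seq(genome, site, region):
    from .boundary_profiles import _genomic_window
    lo, hi = region
    flank = max(abs(lo), abs(hi))
    got = _genomic_window(genome, site, flank, 0)
    if got is None:
        return None
    seq, _, _ = got
    center = flank
    return seq[center + lo: center + hi + 1]


def dinuc_profile(boundaries, genome, region=DEFAULT_REGION,
                  label: str = "target") -> DinucProfile:
    """Overlapping dinucleotide class counts over ``region`` around boundaries.

    Counts use the transcript-sense sequence; the dinucleotide starting at
    offset i belongs to the intronic sub-region when i < 0 (so the
    boundary-spanning pair at (-1, 0) counts as intronic) and to the
    exonic sub-region otherwise.  N-containing pairs are excluded.
    Out-of-chromosome boundaries are dropped with a warning.
    """
    lo, hi = region
    counts = {c: 0 for c in DINUC_CLASSES}
    intron = {c: 0 for c in DINUC_CLASSES}
    exon = {c: 0 for c in DINUC_CLASSES}
    n_used = 0
    n_dropped = 0
    for site in boundaries:
        seq = _window_seq(genome, site, region)
        if seq is None:
            n_dropped += 1
            continue
        n_used += 1
        for i in range(len(seq) - 1):
            cls = dinuc_classify(seq[i:i + 2])
            if cls is None:
                continue
            counts[cls] += 1
            if lo + i < 0:
                intron[cls] += 1
            else:
                exon[cls] += 1
    if n_dropped:
        log_warning(f"dinuc_profile dropped {n_dropped} out-of-range boundaries")
    return DinucProfile(label=label, region=region, n_boundaries=n_used,
                        counts=counts, intron_counts=intron, exon_counts=exon)


def random_control_profiles(all_boundaries, exclude, genome, n_samples: int = 5,
                            seed: int = 0, region=DEFAULT_REGION):
    """Dinucleotide profiles of seeded random boundary samples.

    Draws ``n_samples`` samples without replacement, each of the size of
    the excluded (feature) set, from boundaries outside it.
    """
    exclude_keys = {s.dedup_key() for s in exclude}
    pool = [s for s in all_boundaries if s.dedup_key() not in exclude_keys]
    size = len(exclude)
    if len(pool) < size:
        raise ValueError("not enough non-member boundaries for controls of "
                         f"size {size} (pool {len(pool)})")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_samples):
        idx = rng.choice(len(pool), size=size, replace=False)
        sample = [pool[j] for j in idx]
        profiles.append(dinuc_profile(sample, genome, region=region,
                                      label=f"control_{i + 1}"))
    return profiles


def compare_profiles(target: DinucProfile, controls) -> dict:
    """Per-class deviation of the target from the control distribution.

    For each class and sub-region (whole / intron / exon) reports the
    target count, control mean and sd, and the z-like deviation
    (target - mean) / sd (0 where sd is 0 and the target equals the mean).
    Needs >= 2 controls for a defined sd.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control profiles for an sd")
    for c in controls:
        if c.region != target.region or c.n_boundaries != target.n_boundaries:
            raise ValueError("controls must match the target's region and size")
    out = {}
    for part in ("counts", "intron_counts", "exon_counts"):
        rows = {}
        for cls in DINUC_CLASSES:
            t = getattr(target, part)[cls]
            cvals = np.sort(np.array([getattr(c, part)[cls]
                                      for c in controls], dtype=float))
            mean, sd = cvals.mean(), cvals.std(ddof=1)  # order-canonical
            if sd > 0:
                dev = (t - mean) / sd
            else:
                dev = 0.0 if t == mean else np.inf * np.sign(t - mean)
            rows[cls] = {"target": int(t), "control_mean": float(mean),
                         "control_sd": float(sd), "deviation": float(dev)}
        out[part.replace("_counts", "") if part != "counts" else "whole"] = rows
    return out
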