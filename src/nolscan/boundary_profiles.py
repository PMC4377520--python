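"""Boundary-centered score windows, metaprofiles and minimum localization.

All windows are expressed on a signed, transcript-sense axis: offset 0 is
the boundary exonic base; for acceptor-side (exon_start) windows negative
offsets are intronic, for donor-side (exon_end) windows positive offsets
are intronic.  Minus-strand windows are reverse-complemented so the axis
always runs transcript 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import BoundarySite, SignalTrack, log_warning, reverse_complement
from .nol_model import CENTER, NucleosomeOccupancyModel, ScoreTrack, signal_to_scoretrack

DEFAULT_FLANK = 500
DEFAULT_HALF_WIDTH = 50


@dataclass
class BoundaryWindow:
    site: BoundarySite
    seq: str                  # sense-strand, length 2*flank+1, boundary base at index flank
    track: ScoreTrack         # boundary-relative offsets -flank..+flank
    flank: int = DEFAULT_FLANK


@dataclass(frozen=True)
class MinimumCall:
    """The location of the lowest score within +/-half_width of a boundary."""

    site: BoundarySite
    offset: int
    value: float
    n_candidates: int = 1


def _genomic_window(genome, site: BoundarySite, flank: int, pad: int):
    """Sense-strand sequence of [-flank-pad, +flank+pad] around the site."""
    chrom_seq = genome[site.chrom]
    lo = site.genomic_pos - flank - pad
    hi = site.genomic_pos + flank + pad + 1
    if lo < 0 or hi > len(chrom_seq):
        return None
    seq = chrom_seq[lo:hi]
    if site.strand == "-":
        seq = reverse_complement(seq)
    return seq, lo, hi


def build_windows(genome, sites, model_or_signal, flank: int = DEFAULT_FLANK,
                  signal_center_aligned: bool = False):
    """Boundary-centered windows with NOL or in-vivo signal tracks.

    With a :class:`NucleosomeOccupancyModel`, each window's sequence is
    extended by 25 bp on both sides before sliding-window scoring so all
    2*flank+1 positions can carry a valid center-assigned score.  With a
    :class:`SignalTrack`, per-base values are copied directly.  Sites whose
    padded window does not fit the chromosome are dropped with a warning.

    ``signal_center_aligned`` declares that the signal track holds
    window-center-assigned scores (as the package's own bedGraph export
    does) rather than genuinely per-base measurements: the center of an
    even 50 bp window lies between two bases, so such a strandless track
    must be read with a +1 shift on minus-strand windows to recover the
    identical window score.  Leave False for real per-base occupancy maps.
    """
    use_model = isinstance(model_or_signal, NucleosomeOccupancyModel)
    pad = CENTER if use_model else 0
    offsets = np.arange(-flank, flank + 1)
    windows: list[BoundaryWindow] = []
    n_dropped = 0
    for site in sites:
        got = _genomic_window(genome, site, flank, pad)
        if got is None:
            n_dropped += 1
            continue
        seq_ext, lo, hi = got
        if use_model:
            ext_track = model_or_signal.score_sliding(seq_ext)
            sl = slice(pad, pad + 2 * flank + 1)
            track = ScoreTrack(offsets=offsets,
                               values=ext_track.values[sl],
                               mask=ext_track.mask[sl])
            seq = seq_ext[pad:pad + 2 * flank + 1]
        else:
            shift = 1 if (signal_center_aligned and site.strand == "-") else 0
            track = signal_to_scoretrack(model_or_signal, site.chrom,
                                         lo + shift, hi + shift,
                                         strand=site.strand, offsets=offsets)
            seq = seq_ext
        windows.append(BoundaryWindow(site=site, seq=seq, track=track, flank=flank))
    if n_dropped:
        log_warning(f"dropped {n_dropped} boundary sites whose window "
                    f"(flank={flank}, pad={pad}) exceeds the chromosome")
    return windows


def mean_profile(windows) -> ScoreTrack:
    """Per-offset mean score over unmasked values (the Fig-1-style metaprofile).

    Offsets where no window has data are masked in the result.
    """
    if not windows:
        raise ValueError("mean_profile needs at least one window")
    offsets = windows[0].track.offsets
    stack = np.array([w.track.values for w in windows])
    masks = np.array([w.track.mask for w in windows])
    n = masks.sum(axis=0)
    with np.errstate(invalid="ignore"):
        total = np.where(masks, stack, 0.0).sum(axis=0)
    mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return ScoreTrack(offsets=offsets, values=mean, mask=n > 0)


def base_composition(windows, region: tuple[int, int] = (-50, 50)):
    """Per-offset A/C/G/T fractions over ``region`` (inclusive ends).

    Ambiguous letters are excluded from the denominator; fractions at each
    offset with data sum to 1.  Returns ``(offsets, {base: fractions})``.
    """
    if not windows:
        raise ValueError("base_composition needs at least one window")
    lo, hi = region
    offsets = np.arange(lo, hi + 1)
    counts = {b: np.zeros(len(offsets)) for b in "ACGT"}
    for w in windows:
        center = w.flank
        for j, o in enumerate(offsets):
            idx = center + o
            if 0 <= idx < len(w.seq):
                b = w.seq[idx]
                if b in counts:
                    counts[b][j] += 1
    totals = sum(counts.values())
    fractions = {b: np.where(totals > 0, c / np.maximum(totals, 1), np.nan)
                 for b, c in counts.items()}
    return offsets, fractions


def _tie_key(side: str):
    def key(item):
        offset, value = item
        intronic = (offset < 0) if side == "exon_start" else (offset > 0)
        return (value, abs(offset), 0 if intronic else 1, offset)
    return key


def locate_minimum(window: BoundaryWindow,
                   half_width: int = DEFAULT_HALF_WIDTH) -> MinimumCall | None:
    """Offset of the smallest unmasked score within [-half_width, +half_width].

    Ties (exactly equal minima) are broken by smallest absolute offset,
    then by the intronic side of the boundary, then by signed offset.  An
    all-masked search window yields None (no-call).
    """
    track = window.track
    sel = (np.abs(track.offsets) <= half_width) & track.mask
    if not sel.any():
        return None
    offs = track.offsets[sel]
    vals = track.values[sel]
    vmin = vals.min()
    tied = [(int(o), float(v)) for o, v in zip(offs, vals) if v == vmin]
    offset, value = min(tied, key=_tie_key(window.site.side))
    return MinimumCall(site=window.site, offset=offset, value=value,
                       n_candidates=len(tied))


def call_minima(windows, half_width: int = DEFAULT_HALF_WIDTH) -> list[MinimumCall]:
    """locate_minimum over many windows, logging and skipping no-calls."""
    calls = []
    n_nocall = 0
    for w in windows:
        call = locate_minimum(w, half_width=half_width)
        if call is None:
            n_nocall += 1
        else:
            calls.append(call)
    if n_nocall:
        log_warning(f"{n_nocall} boundary windows had no unmasked score "
                    f"in +/-{half_width} and were excluded")
    return calls


def recenter_on_minimum(windows, calls) -> list[BoundaryWindow]:
    """Shift each window so its called minimum sits at offset 0.

    Sequence and score track shift together; positions shifted in from
    beyond the original window are masked ('N' in sequence).  Feeding the
    result back through :func:`locate_minimum` returns offset 0 for every
    window.
    """
    if len(windows) != len(calls):
        raise ValueError("one call per window required")
    out = []
    for w, call in zip(windows, calls):
        L = len(w.seq)
        shift = call.offset  # old offset `shift` becomes new offset 0
        values = np.full(L, np.nan)
        mask = np.zeros(L, dtype=bool)
        seq = ["N"] * L
        src_lo, src_hi = max(0, shift), min(L, L + shift)
        dst_lo, dst_hi = max(0, -shift), min(L, L - shift)
        values[dst_lo:dst_hi] = w.track.values[src_lo:src_hi]
        mask[dst_lo:dst_hi] = w.track.mask[src_lo:src_hi]
        seq[dst_lo:dst_hi] = w.seq[src_lo:src_hi]
        track = ScoreTrack(offsets=w.track.offsets, values=values, mask=mask)
        out.append(BoundaryWindow(site=w.site, seq="".join(seq), track=track,
                                  flank=w.flank))
    return out


def dedup_calls(calls) -> list[MinimumCall]:
    """Keep one call per physical junction (chrom, position, strand, side).

    Isoforms sharing an exon edge produce identical windows; they are
    counted once in histograms and group selection.
    """
    seen = set()
    out = []
    for c in calls:
        key = c.site.dedup_key()
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out
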