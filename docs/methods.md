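# Methods

## The NOL model

The nucleosome occupancy likelihood (NOL) scorer is a linear max-margin
classifier (SVM, linear kernel, C = 1, not tuned) over position-independent
k-mer composition features of 50 bp windows: counts of all k-mers for
k = 1..k_max (default 3, so 4 + 16 + 64 = 84 features; for each k the
counts sum to 50 − k + 1). It is trained discriminatively on two sequence
sets — strong nucleosome-forming versus strongly inhibitory 50-mers — and
oriented after fitting so that forming examples score positive. Applied to
a sequence of length L ≥ 50 it slides the window in 1 bp steps and assigns
each window's score to the window's 26th base (0-based offset 25), leaving
the first 25 and last 24 positions, and any center whose window contains a
non-ACGT base, masked. Masking rather than imputation is deliberate: the
minimum-finder inspects exactly these positions, and imputed scores would
fabricate minima.

Published weight sets for this family of scorers are generally not
redistributable, so the model here is re-trainable by construction and the
whole pipeline is validated by parameter recovery on synthetic data rather
than by matching any particular weight vector's numeric output.

**Exact arithmetic.** Fitted weights are snapped to a dyadic grid
(multiples of 2⁻³²; quantization error ~10⁻¹⁰ per weight, orders of
magnitude below the decision scale). Sliding-window accumulation then runs
in int64 on that grid, so (i) sliding scores equal brute-force per-window
scores bit-for-bit, (ii) a window's score never depends on how much
surrounding sequence was scored in the same call, and (iii) model
serialization (JSON) round-trips to bit-identical scores. This is what
makes "the same minimum, exactly" a meaningful contract across pipeline
paths.

An optional `strand_symmetric` flag (default off) averages each window's
features with those of its reverse complement, making scores
strand-invariant. The default scores the given (sense) strand only.

## Boundary windows and minima

Gene models follow UCSC genePred semantics (0-based half-open exon
intervals in ascending genomic order regardless of strand). Every internal
exon edge yields a boundary site: `exon_start` (splice-acceptor side) and
`exon_end` (donor side), defined in transcript orientation; a transcript
with E exons contributes E−1 of each, and TSS/TES edges are excluded.
Windows of ±500 bp (sequence extended 25 bp each way before scoring, so
all 1001 positions can carry a score) are expressed on a signed axis with
offset 0 at the boundary exonic base; minus-strand windows are
reverse-complemented so the axis runs transcript 5′→3′.

The per-boundary minimum is the smallest unmasked score in the closed
interval [−50, +50] (101 positions). Exact ties are broken by smallest
|offset|, then the intronic side, then signed offset — deterministic and
favoring the boundary-proximal biology under study. Windows sharing a
physical junction across isoforms are deduplicated by
(chromosome, position, strand, side) before histogramming and group
selection. Feature groups use exact offset equality (a `tolerance`
parameter exists for sensitivity analysis, default 0); a gene joins a
group if at least one of its boundaries is called at the target offset,
and the Venn overlap percentage is reported against the union of the two
groups.

**Edge accumulation (a real property, often overlooked).** Adjacent
sliding-window scores share 49 of their 50 bases, so the score profile is
smooth at a ~50 nt scale. The argmin of such a profile truncated to a
±50 search is *not* uniform even on fully random sequence: minima
accumulate at the search edges (we measure 4–6× the uniform expectation in
the ±50 bins, with a flat interior). Interpreting edge-bin counts of a
minima histogram as features would be a mistake; the acceptance suite
keeps a deliberately failing test documenting this behavior.

## Statistics

*Enrichment.* Target-versus-background category enrichment is the exact
hypergeometric upper tail P[X ≥ k] with X ~ Hypergeom(N, K, n), BH-adjusted
across categories. This deliberately replaces the minimum-hypergeometric
statistic of GOrilla-style tools: the question answered is the same, but
p-values are not numerically interchangeable with mHG outputs, and result
files carry a header note saying so.

*Genomic characteristics.* Exon sizes, intron sizes and exon counts are
computed per gene from its longest transcript (by genomic span; ties by
name). A category is compared to the genome by filtering both value sets
with a 1×IQR fence (values outside the closed interval
[Q1 − IQR, Q3 + IQR] are excluded; quartiles by linear interpolation,
"type 7"; the conventional 1.5× fence is available via `multiplier`),
drawing a seeded same-size sample without replacement from the retained
genome values, and applying Welch's unequal-variance two-sided t-test
(α = 0.05). Welch over pooled variance because category and genome
variances differ by construction; two-sided because direction is reported
separately from significance.

**Calibration caveat.** The 1×IQR fence actively trims ~4–5% of
normal-tailed data at sample-estimated cut points, and this makes the
downstream t-test mildly anticonservative: measured type-I error is ~0.08
at n = 100 under a normal null (alternative filter orderings are worse;
the unfiltered machinery is calibrated at 0.05). Power is excellent (>0.99
for a 5σ shift at n = 50). p-values near 0.05 from this procedure should
therefore be read with a grain of salt; the pipeline reports them as the
procedure defines them.

*Dinucleotides.* The 16 dinucleotides collapse to 10 classes under
reverse-complement identification (6 pairs + the 4 self-complementary
singletons AT, CG, GC, TA). Profiles count overlapping, sense-strand
dinucleotides over −40..+10 around acceptor boundaries; the pair starting
at offset i is assigned to the intron when i < 0 (so the boundary-spanning
pair at (−1, 0) counts as intronic). A feature group's profile is compared
to 5 seeded equal-size samples of non-member boundaries via the z-like
deviation (target − control mean)/control sd, reported for the whole
region and the intron/exon sub-regions. Control values are sorted before
mean/sd so the comparison is exactly invariant to control order.

## The synthetic-data generator

The generator emits what the analysis consumes — FASTA, genePred,
gene→category TSV, training FASTAs — plus a ground-truth ledger of planted
elements. Defaults define the study conditions:

* 2000 genes, ~half on the minus strand, non-overlapping, on chromosomes
  of 250 genes; log-normal exon lengths (median 150 bp, floor 80) and
  intron lengths; background exon counts 1 + NegBinom (median ≈ 7),
  background intron median 420 bp.
* a planted category (15% of genes) with elevated exon counts
  (2 + NegBinom, median ≈ 35) and shorter introns (median 240 bp,
  floor 170) — so the category tests shorter-intron / more-exon against
  the genome;
* every planted gene carries the nucleosome-inhibitory element in ≥1
  intron (each intron with probability 0.4) on both boundary sides, 26 nt
  into the intron; 20 decoy categories (random gene sets of the planted
  size) for enrichment specificity;
* training sets: 300 forming 50-mers (G/C, C-biased 0.7, with a TT
  dinucleotide every 10 bp — the classic rotational periodicity signal)
  and 300 inhibitory 50-mers (A/T, T-biased 0.65, poly(dT)-tract-like).
  The sets are linearly separable under k ≤ 3 composition by construction.

**Element design and its guarantee.** A minimum that recovers *exactly* at
offset 26 is a geometric constraint, not just a composition one. The
acceptor side is clean: the 50 bp window centered at −26 spans
[−51, −2] — an A/T tract ending in the acceptor's A, with the acceptor G
just outside — and every 1 nt shift of the window swaps an A/T k-mer for a
G/C guard k-mer, so the score strictly increases away from −26 under any
trained weights that rank G/C-richer k-mers above A/T-richer ones. The
donor side is not: the window centered at +26 necessarily contains the
donor G at +1, and the window one step deeper into the intron can never
contain fewer A/T bases, forcing a composition tie between +26 and +27.
The tie is resolved through k-mer *identities*: with C-biased forming and
T-biased inhibitory training sets, the step from +26 to +27 swaps
{C, TC, TTC} in for {G, GT, GTA}, each bracket systematically positive
(TC/TTC are forming-class indicators, GT/GTA are not), while the step to
+25 swaps {T, TT, TTT} in for {G, GG, GGT}, strongly negative. These
margins are structural consequences of the training composition, verified
across 20 independent training draws at design time; with them, every
planted boundary's minimum lands exactly at ±26 and the histogram mode is
essentially deterministic.

What the generator does **not** emulate: realistic splicing grammar
(branchpoints, polypyrimidine tracts), isoforms, GC isochores,
conservation, assembly gaps, or noisy in-vivo occupancy. Passing recovery
tests therefore demonstrates that the *pipeline machinery* is correct and
that the planted signal is recoverable under the stated conditions — not
that any particular real genome exhibits the signal.

## The in-vivo (signal) pathway

`mode=signal` replaces model scoring with an external per-base bedGraph
track pushed through the identical window/minimum/grouping machinery
(missing data masked; all-missing windows become logged no-calls). One
subtlety: the center of an even 50 bp window lies *between* two bases, so
a strandless track of window-center-assigned scores (as the package's own
genome-wide export writes) reads back one base off on minus-strand sense
windows. Ingestion therefore takes `signal_center_aligned=True` for such
tracks, applying the +1 minus-strand shift; genuine per-base occupancy
maps use the default natural mapping. With a strand-symmetric model,
exporting genome-wide scores and re-ingesting them in signal mode
reproduces every minimum call bit-for-bit — the acceptance suite checks
this exactly.

## Problem sizes

Defaults were chosen so the full study-condition run (2000 genes, ~10 Mb,
~37k boundary windows of 1001 scored positions) completes in well under a
minute on one CPU, and the whole test suite in well under a
minute more; statistical calibration uses 1000 replicates per check.

## Known limitations

* The scorer is a composition model (k ≤ 3 by default); it cannot express
  longer-range positional structure within the 50 bp window.
* Minima histogram edge bins (±50) are dominated by truncation artifacts
  (see above) and should not be interpreted as features.
* The 1×IQR/Welch procedure is mildly anticonservative (see above).
* Enrichment p-values are plain hypergeometric, not mHG; no GO-DAG
  propagation is performed on category maps.
* genePred is the only annotation format read (no GTF/GFF); bedGraph the
  only signal format.
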