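"""End-to-end orchestration: score -> call minima -> groups -> statistics.

``run_full`` composes the library stages into one reproducible run
directory.  Two scoring modes exist: ``nol`` (sequence-based, a trained
:class:`~nolscan.nol_model.NucleosomeOccupancyModel`) and ``signal``
(an externally supplied per-base occupancy track, e.g. an in-vivo
nucleosome map, pushed through the identical minima pipeline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .genome_io import (extract_boundaries, read_bedgraph, read_fasta,
                        read_genepred, write_bedgraph, SignalTrack)
from .nol_model import NucleosomeOccupancyModel, train
from .boundary_profiles import (build_windows, call_minima, dedup_calls,
                                mean_profile)
from .feature_calling import (eligible_genes, group_overlap, minima_histogram,
                              select_feature_group)
from .stats_enrichment import (CategoryMap, category_vs_genome_test,
                               compute_gene_stats, hypergeometric_enrichment)
from .dinucleotide import (compare_profiles, dinuc_profile,
                           random_control_profiles)

DEVIATION_NOTE = ("category enrichment uses the exact hypergeometric upper "
                  "tail with BH adjustment, not GOrilla's mHG statistic")


@dataclass
class RunConfig:
    genome_fa: str
    genepred: str
    outdir: str
    mode: str = "nol"                    # "nol" or "signal"
    model_json: str | None = None        # pre-trained model (nol mode)
    train_pos_fa: str | None = None      # or train from these (nol mode)
    train_neg_fa: str | None = None
    signal_bedgraph: str | None = None   # required in signal mode
    signal_center_aligned: bool = False  # True when re-ingesting NOL exports
    categories_tsv: str | None = None
    flank: int = 500
    half_width: int = 50
    feature_offset_upstream: int = -26
    feature_offset_downstream: int = 26
    strand_symmetric: bool = False
    n_dinuc_controls: int = 5
    min_category_size: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("nol", "signal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "signal" and not self.signal_bedgraph:
            raise ValueError("mode=signal requires a signal track")
        if self.mode == "nol" and not (
                self.model_json or (self.train_pos_fa and self.train_neg_fa)):
            raise ValueError("mode=nol requires a model or training FASTAs")


def _tsv(path, header, rows, meta=None):
    with open(path, "w") as fh:
        for line in meta or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_scorer(config: RunConfig):
    """Model (nol mode) or SignalTrack (signal mode) per the config."""
    if config.mode == "signal":
        return read_bedgraph(config.signal_bedgraph)
    if config.model_json:
        return NucleosomeOccupancyModel.from_json(config.model_json)
    pos = list(read_fasta(config.train_pos_fa).values())
    neg = list(read_fasta(config.train_neg_fa).values())
    return train(pos, neg, seed=config.seed,
                 strand_symmetric=config.strand_symmetric)


def export_scores_bedgraph(genome, model: NucleosomeOccupancyModel, path) -> None:
    """Genome-wide plus-strand NOL scores as bedGraph (masked positions omitted).

    bedGraph is strandless; with a strand-symmetric model this export is
    lossless for minus-strand windows too, so re-ingesting it in signal
    mode reproduces the nol-mode minima exactly.
    """
    track = SignalTrack()
    for chrom, seq in genome.items():
        if len(seq) < 50:
            continue
        st = model.score_sliding(seq)
        vals = np.where(st.mask, st.values, np.nan)
        track.values[chrom] = vals
    write_bedgraph(track, path)


def run_full(config: RunConfig) -> dict:
    """Run the complete analysis; returns the manifest dict.

    Emits into ``config.outdir``: minima calls TSV, per-side minima
    histograms, feature groups with Venn counts, category enrichment,
    genomic-characteristic tests, dinucleotide profiles, the mean
    metaprofile, and ``manifest.json``.  Any stage failure leaves a
    ``FAILED`` marker naming the stage.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "deviations": [DEVIATION_NOTE],
        "artifacts": {},
        "warnings": {},
    }
    stage = "setup"
    try:
        stage = "inputs"
        genome = read_fasta(config.genome_fa)
        models = read_genepred(config.genepred)
        scorer = load_scorer(config)
        if isinstance(scorer, NucleosomeOccupancyModel):
            scorer.to_json(out / "model.json")
            manifest["artifacts"]["model"] = "model.json"

        stage = "boundaries"
        sites = extract_boundaries(models)
        manifest["n_transcripts"] = len(models)
        manifest["n_boundary_sites"] = len(sites)

        stage = "score_windows"
        windows = build_windows(
            genome, sites, scorer, flank=config.flank,
            signal_center_aligned=config.signal_center_aligned)
        manifest["n_windows"] = len(windows)
        manifest["warnings"]["dropped_sites"] = len(sites) - len(windows)

        stage = "metaprofile"
        prof = mean_profile(windows)
        _tsv(out / "mean_profile.tsv", ["offset", "mean_score", "n"],
             [(int(o), f"{v:.6g}" if m else "NA",
               int(sum(1 for w in windows if w.track.mask[i])))
              for i, (o, v, m) in enumerate(zip(prof.offsets, prof.values,
                                                prof.mask))][::1],
             meta=[f"mean NOL metaprofile, flank={config.flank}"])
        manifest["artifacts"]["mean_profile"] = "mean_profile.tsv"

        stage = "call_minima"
        calls = call_minima(windows, half_width=config.half_width)
        calls = dedup_calls(calls)
        _tsv(out / "minima_calls.tsv",
             ["chrom", "genomic_pos", "strand", "gene", "transcript", "side",
              "offset", "value", "n_tied"],
             [(c.site.chrom, c.site.genomic_pos, c.site.strand, c.site.gene,
               c.site.gene_model.name, c.site.side, c.offset,
               f"{c.value:.6g}", c.n_candidates) for c in calls],
             meta=[f"minimum within +/-{config.half_width} of the boundary",
                   f"mode={config.mode}"])
        manifest["artifacts"]["minima_calls"] = "minima_calls.tsv"

        stage = "histograms"
        hists = {}
        for side in ("exon_start", "exon_end"):
            h = minima_histogram(calls, side, half_width=config.half_width)
            hists[side] = h
            name = f"minima_hist_{side}.tsv"
            _tsv(out / name, ["offset", "count"],
                 zip(h.offsets, h.counts),
                 meta=[f"side={side} n={h.n_boundaries} "
                       f"modal_offset={h.modal_offset()}"])
            manifest["artifacts"][f"hist_{side}"] = name
        manifest["modal_offsets"] = {s: h.modal_offset()
                                     for s, h in hists.items()}

        stage = "feature_groups"
        group_u = select_feature_group(calls, "exon_start",
                                       config.feature_offset_upstream, models)
        group_d = select_feature_group(calls, "exon_end",
                                       config.feature_offset_downstream, models)
        venn = group_overlap(group_u, group_d)
        groups_payload = {
            g.label: {"side": g.side, "offset": g.offset,
                      "n_boundaries": len(g.boundaries),
                      "n_genes": len(g.genes),
                      "fraction_of_eligible_genes": g.fraction_of_genes,
                      "genes": sorted(g.genes)}
            for g in (group_u, group_d)}
        with open(out / "feature_groups.json", "w") as fh:
            json.dump({"groups": groups_payload, "venn": venn}, fh, indent=1)
        manifest["artifacts"]["feature_groups"] = "feature_groups.json"
        manifest["venn"] = venn

        category_map = None
        if config.categories_tsv:
            universe = {m.gene for m in models}
            category_map = CategoryMap.read_tsv(config.categories_tsv,
                                                universe=universe)

        stage = "enrichment"
        if category_map is not None:
            rows = []
            for g in (group_u, group_d):
                for r in hypergeometric_enrichment(g.genes, category_map):
                    rows.append((g.label, r.category, r.n_universe,
                                 r.n_category, r.n_target, r.n_overlap,
                                 f"{r.p_raw:.4g}", f"{r.p_adj:.4g}"))
            _tsv(out / "enrichment.tsv",
                 ["group", "category", "n_universe", "n_category", "n_target",
                  "n_overlap", "p_raw", "p_adj"], rows,
                 meta=[DEVIATION_NOTE])
            manifest["artifacts"]["enrichment"] = "enrichment.tsv"

        stage = "genomic_stats"
        if category_map is not None:
            gstats = compute_gene_stats(models)
            multi = eligible_genes(models)
            rows = []
            for cat, genes in sorted(category_map.category_to_genes().items()):
                genes = genes & multi
                if len(genes) < config.min_category_size:
                    continue
                for statistic in ("exon_size", "intron_size", "exon_count"):
                    cat_vals = gstats.pooled(statistic, genes)
                    gen_vals = gstats.pooled(statistic)
                    res = category_vs_genome_test(cat_vals, gen_vals,
                                                  seed=config.seed)
                    rows.append((cat, statistic, res.n_a, res.n_b,
                                 f"{res.mean_a:.4g}", f"{res.mean_b:.4g}",
                                 f"{np.median(cat_vals):.4g}",
                                 f"{np.median(gen_vals):.4g}",
                                 f"{res.t_stat:.4g}", f"{res.p_value:.4g}",
                                 "*" if res.significant else ""))
            _tsv(out / "genomic_stats.tsv",
                 ["category", "statistic", "n_category", "n_sample",
                  "mean_category", "mean_sample", "median_category",
                  "median_genome", "t", "p", "significant"], rows,
                 meta=["IQR(1x) outlier exclusion, seeded same-size genome "
                       "sample, Welch two-sided t-test, alpha=0.05"])
            manifest["artifacts"]["genomic_stats"] = "genomic_stats.tsv"

        stage = "dinucleotides"
        u_keys = group_u.boundaries
        u_sites = [s for s in sites if s.side == "exon_start"
                   and s.dedup_key() in u_keys]
        # one site per physical junction
        seen = set()
        u_sites = [s for s in u_sites
                   if not (s.dedup_key() in seen or seen.add(s.dedup_key()))]
        all_acceptors = []
        seen = set()
        for s in sites:
            if s.side == "exon_start" and s.dedup_key() not in seen:
                seen.add(s.dedup_key())
                all_acceptors.append(s)
        if u_sites and len(all_acceptors) >= 2 * len(u_sites):
            target = dinuc_profile(u_sites, genome, label=group_u.label)
            controls = random_control_profiles(
                all_acceptors, u_sites, genome,
                n_samples=config.n_dinuc_controls, seed=config.seed)
            controls = [c for c in controls
                        if c.n_boundaries == target.n_boundaries]
            comparison = compare_profiles(target, controls)
            rows = []
            for part, table in comparison.items():
                for cls, row in table.items():
                    rows.append((part, cls, row["target"],
                                 f"{row['control_mean']:.4g}",
                                 f"{row['control_sd']:.4g}",
                                 f"{row['deviation']:.4g}"))
            _tsv(out / "dinucleotide.tsv",
                 ["region", "class", "target_count", "control_mean",
                  "control_sd", "deviation"], rows,
                 meta=[f"{config.n_dinuc_controls} random control samples, "
                       f"region -40..+10, seed={config.seed}"])
            manifest["artifacts"]["dinucleotide"] = "dinucleotide.tsv"

        stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
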