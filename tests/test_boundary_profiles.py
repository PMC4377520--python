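"""Boundary windows, metaprofiles, minimum localization and re-centering."""

import numpy as np
import pytest

from nolscan.genome_io import BoundarySite, GeneModel, reverse_complement
from nolscan.nol_model import ScoreTrack
from nolscan.boundary_profiles import (BoundaryWindow, base_composition,
                                       build_windows, call_minima,
                                       dedup_calls, locate_minimum,
                                       mean_profile, recenter_on_minimum)


def _site(side="exon_start", strand="+", pos=500, exon_index=1):
    first_start = max(0, pos - 100)
    m = GeneModel("tx", "g", "chrT", strand,
                  (first_start, pos), (first_start + 5, pos + 100))
    return BoundarySite(m, exon_index, side, pos, strand)


def _window(values, side="exon_start", mask=None, flank=None):
    values = np.asarray(values, dtype=float)
    flank = flank if flank is not None else (len(values) - 1) // 2
    offsets = np.arange(-flank, flank + 1)
    mask = np.ones(len(values), bool) if mask is None else np.asarray(mask)
    return BoundaryWindow(site=_site(side=side), seq="A" * len(values),
                          track=ScoreTrack(offsets=offsets, values=values,
                                           mask=mask), flank=flank)


class TestBuildWindows:
    def test_plus_strand_centering(self, toy_genome, toy_models, small_model):
        from nolscan.genome_io import extract_boundaries
        sites = [s for s in extract_boundaries([toy_models[0]])
                 if s.side == "exon_start"]
        wins = build_windows(toy_genome, sites, small_model, flank=100)
        for w in wins:
            assert len(w.seq) == 201
            assert w.seq[100] == toy_genome["chrT"][w.site.genomic_pos]
            assert w.track.mask.all()

    def test_minus_strand_window_is_reverse_complement(self, toy_genome,
                                                       small_model):
        site = _site(strand="-", pos=500)
        (w,) = build_windows(toy_genome, [site], small_model, flank=50)
        genomic = toy_genome["chrT"][500 - 50:500 + 51]
        assert w.seq == reverse_complement(genomic)

    def test_out_of_range_site_dropped(self, toy_genome, small_model):
        near_edge = _site(pos=10)
        assert build_windows(toy_genome, [near_edge], small_model,
                             flank=50) == []


class TestMeanProfile:
    def test_identical_windows_mean_is_any_one(self):
        w = _window([1.0, 2.0, 3.0])
        prof = mean_profile([w, w, w])
        assert prof.values.tolist() == [1.0, 2.0, 3.0]

    def test_opposite_windows_cancel(self):
        w1 = _window([1.0, -2.0, 3.0])
        w2 = _window([-1.0, 2.0, -3.0])
        assert np.allclose(mean_profile([w1, w2]).values, 0.0)

    def test_matches_bruteforce_per_offset_loop(self):
        rng = np.random.default_rng(0)
        wins = []
        for _ in range(10):
            vals = rng.normal(size=21)
            mask = rng.random(21) > 0.2
            wins.append(_window(vals, mask=mask))
        prof = mean_profile(wins)
        for j in range(21):
            got = [w.track.values[j] for w in wins if w.track.mask[j]]
            if got:
                assert prof.mask[j]
                assert prof.values[j] == pytest.approx(np.mean(got))
            else:
                assert not prof.mask[j]

    def test_count_weighted_linearity(self):
        rng = np.random.default_rng(1)
        a = [_window(rng.normal(size=11)) for _ in range(3)]
        b = [_window(rng.normal(size=11)) for _ in range(5)]
        merged = mean_profile(a + b).values
        weighted = (3 * mean_profile(a).values + 5 * mean_profile(b).values) / 8
        assert np.allclose(merged, weighted)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_profile([])


class TestBaseComposition:
    def test_uniform_base_fraction_one(self):
        w = _window([0.0] * 11)  # seq is all A
        offsets, frac = base_composition([w], region=(-5, 5))
        assert np.allclose(frac["A"], 1.0)
        assert np.allclose(frac["C"], 0.0)

    def test_fractions_sum_to_one(self, small_dataset, small_model):
        from nolscan.genome_io import extract_boundaries
        sites = extract_boundaries(small_dataset.models)[:40]
        wins = build_windows(small_dataset.genome, sites, small_model)
        _, frac = base_composition(wins, region=(-50, 50))
        total = sum(frac[b] for b in "ACGT")
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_acceptor_consensus_recovered(self, small_dataset, small_model):
        """Planted acceptors show the canonical A,G at offsets -2,-1."""
        from nolscan.genome_io import extract_boundaries
        sites = [s for s in extract_boundaries(small_dataset.models)
                 if s.side == "exon_start"][:60]
        wins = build_windows(small_dataset.genome, sites, small_model)
        offsets, frac = base_composition(wins, region=(-5, 0))
        i2, i1 = list(offsets).index(-2), list(offsets).index(-1)
        assert frac["A"][i2] == 1.0
        assert frac["G"][i1] == 1.0

    def test_matches_hand_tally(self):
        w1 = _window([0.0] * 5)
        w2 = _window([0.0] * 5)
        w2.seq = "CCGTA"
        offsets, frac = base_composition([w1, w2], region=(-2, 2))
        # offset -2: A (w1) + C (w2)
        assert frac["A"][0] == 0.5 and frac["C"][0] == 0.5


class TestLocateMinimum:
    def test_unique_vshape_vertex(self):
        vals = np.abs(np.arange(-50, 51) + 26).astype(float)
        call = locate_minimum(_window(vals))
        assert call.offset == -26 and call.n_candidates == 1

    def test_constant_profile_tie_breaks_to_zero(self):
        call = locate_minimum(_window(np.zeros(101)))
        assert call.offset == 0
        assert call.n_candidates == 101

    def test_tie_at_equal_distance_prefers_intronic_side(self):
        vals = np.zeros(101)
        vals[:] = 5.0
        vals[50 - 7] = vals[50 + 7] = -1.0
        acc = locate_minimum(_window(vals.copy(), side="exon_start"))
        don = locate_minimum(_window(vals.copy(), side="exon_end"))
        assert acc.offset == -7   # intron upstream of an exon start
        assert don.offset == +7   # intron downstream of an exon end

    def test_masked_values_ignored(self):
        vals = np.zeros(101)
        vals[10] = -9.0
        mask = np.ones(101, bool)
        mask[10] = False
        call = locate_minimum(_window(vals, mask=mask))
        assert call.offset == 0

    def test_all_masked_search_window_is_no_call(self):
        mask = np.zeros(101, bool)
        assert locate_minimum(_window(np.zeros(101), mask=mask)) is None

    def test_respects_half_width(self):
        vals = np.zeros(101)
        vals[0] = -5.0  # offset -50, outside a +/-20 search
        call = locate_minimum(_window(vals), half_width=20)
        assert call.offset == 0

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            vals = rng.normal(size=101).round(1)  # rounding forces ties
            mask = rng.random(101) > 0.05
            side = rng.choice(["exon_start", "exon_end"])
            w = _window(vals, side=side, mask=mask)
            call = locate_minimum(w)
            best = None
            for off, v, ok in zip(range(-50, 51), vals, mask):
                if not ok:
                    continue
                intronic = off < 0 if side == "exon_start" else off > 0
                key = (v, abs(off), 0 if intronic else 1, off)
                if best is None or key < best[0]:
                    best = (key, off)
            if best is None:
                assert call is None
            else:
                assert call.offset == best[1]


class TestRecenter:
    def test_call_at_zero_is_identity(self):
        w = _window(np.arange(11.0))
        (out,) = recenter_on_minimum([w], [locate_minimum(w, half_width=5)])
        # minimum of an increasing ramp is the leftmost offset (-5)
        assert out.track.values[5] == w.track.values[0]

    def test_shift_moves_minimum_to_zero(self):
        vals = np.abs(np.arange(-50, 51) + 26).astype(float)
        w = _window(vals)
        call = locate_minimum(w)
        (out,) = recenter_on_minimum([w], [call])
        assert out.track.values[50] == 0.0
        assert locate_minimum(out).offset == 0

    def test_recentred_minima_all_at_zero(self):
        rng = np.random.default_rng(4)
        wins = [_window(rng.normal(size=101)) for _ in range(50)]
        calls = [locate_minimum(w) for w in wins]
        for out in recenter_on_minimum(wins, calls):
            assert locate_minimum(out).offset == 0

    def test_overhang_masked(self):
        vals = np.zeros(11)
        vals[2] = -1.0  # offset -3
        w = _window(vals)
        call = locate_minimum(w, half_width=5)
        (out,) = recenter_on_minimum([w], [call])
        # shifting left by 3 leaves the first 3 positions without data
        assert not out.track.mask[:3].any()
        assert out.track.mask[3:].all()
        assert out.seq.startswith("NNN")


def test_dedup_keeps_one_call_per_physical_junction():
    w = _window(np.zeros(101))
    c = locate_minimum(w)
    assert len(dedup_calls([c, c, c])) == 1


def test_call_minima_skips_no_calls():
    good = _window(np.zeros(101))
    bad = _window(np.zeros(101), mask=np.zeros(101, bool))
    assert len(call_minima([good, bad])) == 1
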