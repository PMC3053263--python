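"""Profile construction: shifting, binning, smoothing, enrichment, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipcompare import profiles as pf
from chipcompare import synthetic as syn
from chipcompare.core import BinnedTrack

from conftest import flat_genome, make_readset


def track(values, bin_size=50, kind="intensity", chrom="chr1"):
    return BinnedTrack(bin_size=bin_size, values={chrom: np.asarray(values, float)},
                       value_kind=kind)


class TestShiftReads:
    def test_zero_shift_is_identity(self):
        reads = make_readset({"chr1": [(100, "+"), (1000, "-")]})
        out = pf.shift_reads(reads, 0)
        np.testing.assert_array_equal(out.positions["chr1"], [100, 1000])

    def test_strand_signs(self):
        reads = make_readset({"chr1": [(100, "+"), (1000, "-")]})
        out = pf.shift_reads(reads, 75)
        np.testing.assert_array_equal(out.positions["chr1"], [175, 925])

    def test_shift_clips_at_zero(self):
        reads = make_readset({"chr1": [(10, "-")]})
        out = pf.shift_reads(reads, 75)
        assert out.positions["chr1"][0] == 0

    def test_half_fragment_shift_aligns_strands(self):
        """Shifting by frag_len/2 makes +/− strand count tracks agree better."""
        g = flat_genome((100_000,))
        lam = g.empty_track(50, 1.0, "intensity")
        for s in range(10_000, 90_000, 10_000):
            lam.values["chr1"][s // 50: (s + 500) // 50] = 8.0
        reads = syn.simulate_reads(lam, g, depth=300_000, frag_len=200, seed=3)
        def strand_corr(shift):
            shifted = pf.shift_reads(reads, shift)
            fwd = make_readset({"chr1": []})
            corr = []
            for keep in (True, False):
                sel = shifted.strands["chr1"] == keep
                sub = make_readset({"chr1": []})
                sub.positions["chr1"] = shifted.positions["chr1"][sel]
                sub.strands["chr1"] = shifted.strands["chr1"][sel]
                corr.append(pf.bin_counts(sub, g, 50).values["chr1"])
            return np.corrcoef(corr[0], corr[1])[0, 1]
        assert strand_corr(100) > strand_corr(0)


class TestBinCounts:
    def test_empty_readset_gives_zero_track(self, small_genome):
        reads = make_readset({c: [] for c in small_genome.chrom_names})
        counts = pf.bin_counts(reads, small_genome)
        assert counts.total() == 0

    def test_half_open_bin_assignment(self):
        g = flat_genome((10_000,))
        reads = make_readset({"chr1": [(10, "+"), (49, "+"), (50, "+")]})
        counts = pf.bin_counts(reads, g, 50)
        assert counts.values["chr1"][0] == 2
        assert counts.values["chr1"][1] == 1

    def test_total_reads_conserved_per_chromosome(self, megabase_genome):
        flat = megabase_genome.empty_track(50, 1.0, "intensity")
        reads = syn.simulate_reads(flat, megabase_genome, depth=100_000, seed=2)
        counts = pf.bin_counts(reads, megabase_genome)
        for c in megabase_genome.chrom_names:
            assert counts.values[c].sum() == len(reads.positions[c])

    def test_unknown_chromosome_named_in_error(self, small_genome):
        reads = make_readset({"chrX": [(5, "+")]})
        with pytest.raises(ValueError, match="chrX"):
            pf.bin_counts(reads, small_genome)


class TestBinProbes:
    def test_probeless_bins_are_masked_out(self):
        g = flat_genome((10_000,))
        lam = g.empty_track(50, 1.0, "intensity")
        probes = syn.simulate_array(lam, None, g, noise_sd=0.0, coverage_target=0.5, seed=1)
        _, _, mask = pf.bin_probes(probes, g)
        assert not mask["chr1"].all() and mask["chr1"].any()

    def test_bin_value_is_mean_of_probe_intensities(self):
        import pandas as pd
        g = flat_genome((1_000,))
        probes = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [0, 25], "end": [25, 50],
            "probe_id": ["a", "b"], "ip_intensity": [2.0, 4.0], "input_intensity": [1.0, 1.0],
        })
        ip, inp, mask = pf.bin_probes(probes, g, 50)
        assert ip.values["chr1"][0] == pytest.approx(3.0)
        assert mask["chr1"][0]

    def test_masked_fraction_tracks_array_coverage(self, megabase_genome):
        lam = megabase_genome.empty_track(50, 1.0, "intensity")
        probes = syn.simulate_array(lam, None, megabase_genome, coverage_target=0.7, seed=2)
        _, _, mask = pf.bin_probes(probes, megabase_genome)
        frac = np.concatenate([mask[c] for c in mask]).mean()
        assert abs(frac - 0.7) < 0.02


class TestGaussianSmooth:
    def test_constant_track_is_preserved(self):
        t = track(np.full(500, 3.7))
        out = pf.gaussian_smooth(t)
        np.testing.assert_allclose(out.values["chr1"], 3.7, rtol=1e-12)

    def test_impulse_response_matches_hand_kernel(self):
        n, c = 801, 400
        vals = np.zeros(n)
        vals[c] = 1.0
        out = pf.gaussian_smooth(track(vals), bandwidth=50.0, max_neighbors=400)
        # hand evaluation: w_d = exp(-(50 d)^2 / (2*50^2)), normalizer = sum over
        # the 400 nearest bins (d = -200..200)
        w = np.exp(-((50.0 * np.arange(-200, 201)) ** 2) / (2 * 50.0**2))
        norm = w.sum()
        for d in (0, 1, 2):
            expected = np.exp(-((50.0 * d) ** 2) / (2 * 50.0**2)) / norm
            assert out.values["chr1"][c + d] == pytest.approx(expected, rel=1e-12)
            assert out.values["chr1"][c - d] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        y, z = rng.normal(size=300), rng.normal(size=300)
        sm = lambda v: pf.gaussian_smooth(track(v)).values["chr1"]
        np.testing.assert_allclose(sm(a * y + b * z), a * sm(y) + b * sm(z), atol=1e-9)

    def test_masked_bins_contribute_no_weight(self):
        vals = np.ones(100)
        vals[50] = 1000.0
        mask = {"chr1": np.ones(100, bool)}
        mask["chr1"][50] = False
        out = pf.gaussian_smooth(track(vals), mask=mask)
        np.testing.assert_allclose(out.values["chr1"][:49], 1.0, rtol=1e-9)
        np.testing.assert_allclose(out.values["chr1"][52:], 1.0, rtol=1e-9)

    def test_printed_kernel_flag_uses_literal_formula(self):
        vals = np.zeros(11)
        vals[5] = 1.0
        out = pf.gaussian_smooth(track(vals), bandwidth=50.0, max_neighbors=2,
                                 normalize=False, printed_kernel=True)
        # the literal published kernel grows with distance: exp(+(50*1)^2/50)
        assert out.values["chr1"][6] == pytest.approx(np.exp(50.0**2 / 50.0))

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            pf.gaussian_smooth(BinnedTrack(50, {}, "count"))


class TestEnrichment:
    def test_identical_tracks_give_zero(self):
        t = track(np.arange(1.0, 101.0))
        prof = pf.enrichment(t, t.copy())
        np.testing.assert_allclose(prof.track.values["chr1"], 0.0, atol=1e-12)

    def test_fourfold_intensity_ratio_gives_two(self):
        base = track(np.full(100, 2.0))
        ip = track(np.full(100, 8.0))
        prof = pf.enrichment(ip, base)
        np.testing.assert_allclose(prof.track.values["chr1"], 2.0, rtol=1e-12)

    def test_count_tracks_are_library_size_scaled(self):
        # IP has twice the input's depth but the same shape: enrichment 0
        ip = track(np.full(100, 20.0), kind="count")
        inp = track(np.full(100, 10.0), kind="count")
        prof = pf.enrichment(ip, inp, pseudocount=1e-9)
        np.testing.assert_allclose(prof.track.values["chr1"], 0.0, atol=1e-6)

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = track(rng.uniform(0.5, 4.0, 200))
        b = track(rng.uniform(0.5, 4.0, 200))
        ab = pf.enrichment(a, b).track.values["chr1"]
        ba = pf.enrichment(b, a).track.values["chr1"]
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_deep_simulation_recovers_planted_effect(self, megabase_genome):
        truth, lam = syn.plant_regions(megabase_genome, 10, narrow_fraction=0.0,
                                       broad_width=(5000, 8000),
                                       effect_range=(5.0, 5.0), seed=5)
        chip = syn.simulate_reads(lam, megabase_genome, depth=5_000_000, seed=6)
        inp = syn.simulate_reads(lam.constant_like(1.0), megabase_genome,
                                 depth=5_000_000, seed=7)
        prof = pf.seq_profile(chip, inp, megabase_genome)
        vals = []
        for row in truth.itertuples():
            # stay clear of smoothed edges
            vals.append(prof.track.values[row.chrom][row.start // 50 + 4: row.end // 50 - 4])
        mean_in = np.concatenate(vals).mean()
        # enrichment is log2(effect) minus the log of the genome-wide mean rate
        total_bases = megabase_genome.total_length
        planted = (truth.end - truth.start).sum()
        baseline = np.log2((5.0 * planted + (total_bases - planted)) / total_bases)
        assert abs(mean_in - (np.log2(5.0) - baseline)) < 0.15

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            pf.enrichment(track(np.ones(10)), track(np.ones(11)))


class TestInputProfile:
    def test_constant_input_gives_constant_profile(self):
        prof = pf.input_profile(track(np.full(50, 4.0)))
        np.testing.assert_allclose(prof.track.values["chr1"], 2.0)

    def test_doubling_input_shifts_by_one(self):
        base = track(np.arange(1.0, 51.0))
        doubled = track(2 * np.arange(1.0, 51.0))
        p1 = pf.input_profile(base).track.values["chr1"]
        p2 = pf.input_profile(doubled).track.values["chr1"]
        np.testing.assert_allclose(p2 - p1, 1.0, rtol=1e-12)


class TestAggregateBins:
    def test_factor_one_is_identity(self):
        prof = pf.input_profile(track(np.arange(1.0, 41.0)))
        out = pf.aggregate_bins(prof, 1)
        np.testing.assert_array_equal(out.track.values["chr1"], prof.track.values["chr1"])

    def test_mean_of_twenty_children(self):
        prof = pf.enrichment(track(2.0 ** np.arange(1, 21)), track(np.ones(20)))
        out = pf.aggregate_bins(prof, 20)
        assert out.track.values["chr1"][0] == pytest.approx(np.mean(np.arange(1, 21)))
        assert out.bin_size == 1000

    def test_aggregation_composes(self):
        rng = np.random.default_rng(0)
        prof = pf.enrichment(track(rng.uniform(1, 4, 400)), track(np.ones(400)))
        once = pf.aggregate_bins(prof, 20)
        twice = pf.aggregate_bins(pf.aggregate_bins(prof, 4), 5)
        np.testing.assert_allclose(once.track.values["chr1"], twice.track.values["chr1"],
                                   rtol=1e-12)

    def test_fully_masked_children_mask_parent(self):
        prof = pf.enrichment(track(np.ones(40)), track(np.ones(40)))
        prof.mask["chr1"][:20] = False
        out = pf.aggregate_bins(prof, 20)
        assert not out.mask["chr1"][0]
        assert out.mask["chr1"][1]

    def test_partial_masking_averages_survivors(self):
        vals = np.ones(20)
        vals[:10] = 100.0
        prof = pf.enrichment(track(2.0**vals), track(np.ones(20)))
        prof.mask["chr1"][:10] = False
        out = pf.aggregate_bins(prof, 20)
        assert out.track.values["chr1"][0] == pytest.approx(1.0)


class TestVariabilityMask:
    def _profiles(self, arrays):
        return [pf.input_profile(track(a)) for a in arrays]

    def test_identical_inputs_mask_nothing(self):
        arrays = [np.arange(1.0, 1001.0)] * 3
        mask = pf.variability_mask(self._profiles(arrays), quantile=0.95)
        assert mask["chr1"].all()

    def test_extreme_bin_is_masked(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 2, 2000)
        a, b = base.copy(), base.copy()
        b[137] *= 2.0**100
        mask = pf.variability_mask(self._profiles([a, b]), quantile=0.99)
        assert not mask["chr1"][137]
        assert mask["chr1"].sum() >= 1990

    def test_default_quantile_masks_about_five_percent(self):
        rng = np.random.default_rng(2)
        arrays = [np.exp(rng.normal(0, 0.3, 5000)) for _ in range(4)]
        mask = pf.variability_mask(self._profiles(arrays), quantile=0.95)
        frac = 1 - mask["chr1"].mean()
        assert 0.03 < frac < 0.07

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            pf.variability_mask(self._profiles([np.ones(100)]))
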