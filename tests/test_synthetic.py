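"""Generator determinism, null configurations, and analytic recoveries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tadscape import contact as ct
from tadscape import synthetic as syn
from tadscape.layout import GenomeLayout

from conftest import make_truth


class TestPlantTruth:
    def test_truth_satisfies_invariants(self, small_layout):
        truth = syn.plant_truth(small_layout, seed=1)
        truth.validate(small_layout)  # raises on violation

    def test_deterministic_in_seed(self, small_layout):
        t1 = syn.plant_truth(small_layout, seed=5)
        t2 = syn.plant_truth(small_layout, seed=5)
        pd.testing.assert_frame_equal(t1.domains, t2.domains)
        pd.testing.assert_frame_equal(t1.loops, t2.loops)

    def test_domains_tile_each_chromosome(self, two_chrom_layout):
        truth = syn.plant_truth(two_chrom_layout, seed=2)
        for chrom in two_chrom_layout.chrom_names:
            g = truth.domains[truth.domains["chrom"] == chrom].sort_values("start")
            assert g["start"].iloc[0] == 0
            assert g["end"].iloc[-1] == two_chrom_layout.length(chrom)
            assert (g["start"].to_numpy()[1:] == g["end"].to_numpy()[:-1]).all()


class TestContactMap:
    def test_pure_decay_oe_flat(self, small_layout):
        doms = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                             "end": [small_layout.length("chr1")], "class": ["inactive"]})
        m = syn.simulate_contact_map(
            small_layout, make_truth(doms), "chr1",
            within_domain_fold=1.0, loop_fold=1.0, mean_depth=2000.0,
            seed=3, gap_fraction=0.0,
        )
        oe = ct.observed_over_expected(m)
        per_offset = [np.nanmean(np.diagonal(oe.counts, d)) for d in range(0, 100, 5)]
        np.testing.assert_allclose(per_offset, 1.0, atol=0.05)

    def test_within_domain_fold_recovered_analytically(self):
        lay = GenomeLayout(["c"], [120 * 40_000], 40_000)
        doms = pd.DataFrame(
            {"chrom": "c", "start": np.array([0, 40, 80]) * 40_000,
             "end": np.array([40, 80, 120]) * 40_000, "class": "inactive"}
        )
        m = syn.simulate_contact_map(
            lay, make_truth(doms), "c", within_domain_fold=2.0, loop_fold=1.0,
            mean_depth=50.0, seed=4, gap_fraction=0.0,
        )
        oe = ct.observed_over_expected(m)
        dom_id = np.repeat([0, 1, 2], 40)
        same = dom_id[:, None] == dom_id[None, :]
        n = 120
        # the generative model fixes E[within]/E[cross] = fold at every
        # offset, so compare per offset and average the offset-wise ratios
        ratios = []
        for d in range(1, 40):
            i = np.arange(n - d)
            j = i + d
            vals = oe.counts[i, j]
            s = same[i, j]
            if s.any() and (~s).any():
                ratios.append(np.nanmean(vals[s]) / np.nanmean(vals[~s]))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_seeded_determinism(self, small_layout, truth):
        m1 = syn.simulate_contact_map(small_layout, truth, "chr1", seed=6)
        m2 = syn.simulate_contact_map(small_layout, truth, "chr1", seed=6)
        np.testing.assert_array_equal(m1.counts, m2.counts)
        assert m1.masked_bins == m2.masked_bins

    def test_parameter_validation(self, small_layout, truth):
        with pytest.raises(ValueError):
            syn.simulate_contact_map(small_layout, truth, "chr1", within_domain_fold=0.5)
        with pytest.raises(ValueError):
            syn.simulate_contact_map(small_layout, truth, "chr1", mean_depth=0)

    def test_loop_fold_raises_anchor_pair(self, small_layout):
        doms = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                             "end": [small_layout.length("chr1")], "class": ["inactive"]})
        loops = pd.DataFrame(
            {"chrom": ["chr1"], "startA": [400_000], "endA": [440_000],
             "startB": [4_000_000], "endB": [4_040_000]}
        )
        truth = make_truth(doms, loops=loops)
        maps = [
            syn.simulate_contact_map(
                small_layout, truth, "chr1", loop_fold=5.0, within_domain_fold=1.0,
                mean_depth=100.0, seed=s, gap_fraction=0.0,
            ).counts[10, 100]
            for s in range(30)
        ]
        i, j = 10, 100
        base = 100.0 * (abs(i - j) + 1) ** -1.0
        assert np.mean(maps) == pytest.approx(5 * base, rel=0.3)


class TestTracks:
    def test_track_lengths_match_layout(self, two_chrom_layout):
        truth = syn.plant_truth(two_chrom_layout, seed=7)
        tracks = syn.simulate_tracks(two_chrom_layout, truth, seed=8)
        for name, tr in tracks.items():
            assert len(tr) == two_chrom_layout.total_bins, name

    def test_null_effects_equalize_class_means(self):
        lay = GenomeLayout(["c"], [2000 * 40_000], 40_000)
        truth = syn.plant_truth(lay, seed=9)
        zero = {t: {c: 0.0 for c in syn.DOMAIN_CLASSES} for t in syn.DEFAULT_TRACK_MODEL}
        tracks = syn.simulate_tracks(lay, truth, class_effects=zero, seed=10)
        bs = 40_000
        cls = np.full(2000, "", dtype=object)
        for start, end, label in zip(truth.domains["start"], truth.domains["end"],
                                     truth.domains["class"]):
            cls[start // bs:(end - 1) // bs + 1] = label
        vals = tracks["ltr_density"]["value"].to_numpy()
        a = vals[cls == "HDF"]
        b = vals[cls == "active"]
        t, p = stats.ttest_ind(a, b)
        assert p > 0.01

    def test_default_ltr_shift_between_hdf_and_active(self):
        lay = GenomeLayout(["c"], [3000 * 40_000], 40_000)
        truth = syn.plant_truth(lay, seed=11)
        tracks = syn.simulate_tracks(lay, truth, seed=12)
        bs = 40_000
        cls = np.full(3000, "", dtype=object)
        for start, end, label in zip(truth.domains["start"], truth.domains["end"],
                                     truth.domains["class"]):
            cls[start // bs:(end - 1) // bs + 1] = label
        vals = tracks["ltr_density"]["value"].to_numpy()
        shift = vals[cls == "HDF"].mean() - vals[cls == "active"].mean()
        configured = (
            syn.DEFAULT_TRACK_MODEL["ltr_density"]["shifts"]["HDF"]
            - syn.DEFAULT_TRACK_MODEL["ltr_density"]["shifts"]["active"]
        )
        assert shift == pytest.approx(configured, rel=0.1)

    def test_methylation_tracks_bounded(self, small_layout, truth):
        tracks = syn.simulate_tracks(small_layout, truth, seed=13)
        for name in ("mCpG", "mCHG", "mCHH", "methylation"):
            v = tracks[name]["value"]
            assert (v >= 0).all() and (v <= 1).all()

    def test_unknown_class_rejected(self, small_layout, truth):
        with pytest.raises(ValueError):
            syn.simulate_tracks(small_layout, truth, class_effects={"ltr_density": {"bogus": 1.0}})


class TestVariants:
    @pytest.fixture
    def layout(self):
        return GenomeLayout(["c"], [20_000_000], 40_000)

    @pytest.fixture
    def boundaries(self, layout):
        s = (np.arange(500_000, 19_500_000, 200_000) // 40_000) * 40_000
        return pd.DataFrame({"chrom": "c", "start": s, "end": s + 40_000})

    def _zone_ratio(self, layout, boundaries, snps, halfwidth=20_000):
        mids = ((boundaries["start"] + boundaries["end"]) // 2).to_numpy()
        zones = np.zeros(layout.length("c"), dtype=bool)
        for m in mids:
            zones[max(0, m - halfwidth):m + halfwidth] = True
        pos = snps["pos"].to_numpy()
        in_zone = zones[pos].sum()
        zone_bp = zones.sum()
        out_bp = layout.length("c") - zone_bp
        dens_in = in_zone / zone_bp
        dens_out = (len(pos) - in_zone) / out_bp
        return dens_in / dens_out

    def test_no_depletion_ratio_near_one(self, layout, boundaries):
        v = syn.simulate_variants(layout, boundaries, background_density=1e-3,
                                  depletion_factor=1.0, seed=14)
        assert len(v["snps"]) >= 10_000
        assert 0.9 <= self._zone_ratio(layout, boundaries, v["snps"]) <= 1.1

    def test_half_depletion_ratio(self, layout, boundaries):
        v = syn.simulate_variants(layout, boundaries, background_density=1e-3,
                                  depletion_factor=0.5, seed=15)
        assert 0.4 <= self._zone_ratio(layout, boundaries, v["snps"]) <= 0.6

    def test_total_count_within_three_sd(self, layout, boundaries):
        v = syn.simulate_variants(layout, boundaries, background_density=1e-3,
                                  depletion_factor=1.0, seed=16)
        lam = 1e-3 * layout.length("c")
        assert abs(len(v["snps"]) - lam) <= 3 * np.sqrt(lam)

    def test_invalid_depletion_rejected(self, layout, boundaries):
        for bad in (0.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                syn.simulate_variants(layout, boundaries, depletion_factor=bad)

    def test_deletion_lengths_positive(self, layout, boundaries):
        v = syn.simulate_variants(layout, boundaries, background_density=1e-3, seed=17)
        d = v["deletions"]
        assert (d["end"] > d["start"]).all()


class TestSyntenyBlocks:
    def test_blocks_tile_without_overlap(self, two_chrom_layout):
        doms = syn.plant_truth(two_chrom_layout, seed=18).domains
        sim = syn.simulate_synteny_blocks(two_chrom_layout, doms, n_breaks=10, seed=19)
        for chrom, g in sim["blocks"].groupby("tname"):
            g = g.sort_values("tstart")
            assert (g["tstart"].to_numpy()[1:] >= g["tend"].to_numpy()[:-1]).all()

    def test_all_breaks_at_boundaries_when_fraction_one(self):
        lay = GenomeLayout(["c1", "c2"], [30_000_000, 30_000_000], 40_000)
        doms = syn.plant_truth(lay, seed=20).domains
        sim = syn.simulate_synteny_blocks(
            lay, doms, n_breaks=30, break_boundary_fraction=1.0, seed=21
        )
        edges = {}
        for r in doms.itertuples(index=False):
            edges.setdefault(r.chrom, []).extend([r.start, r.end])
        for r in sim["breaks"].itertuples(index=False):
            dist = min(abs(r.pos - e) for e in edges[r.chrom])
            assert dist < lay.bin_size

    def test_uniform_breaks_pass_ks(self):
        lay = GenomeLayout(["c"], [200_000_000], 40_000)
        doms = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200_000_000],
                             "class": ["inactive"]})
        sim = syn.simulate_synteny_blocks(
            lay, doms, n_breaks=500, break_boundary_fraction=0.0, seed=22,
            min_break_spacing_bp=1_000,
        )
        u = sim["breaks"]["pos"].to_numpy() / 200_000_000
        stat, p = stats.kstest(u, "uniform")
        assert p > 0.01

    def test_fraction_validation(self, two_chrom_layout):
        doms = syn.plant_truth(two_chrom_layout, seed=23).domains
        with pytest.raises(ValueError):
            syn.simulate_synteny_blocks(two_chrom_layout, doms, n_breaks=5,
                                        break_boundary_fraction=1.5)


class TestExpression:
    def test_seeded_determinism(self, small_layout):
        e1 = syn.simulate_expression(small_layout, seed=24)
        e2 = syn.simulate_expression(small_layout, seed=24)
        pd.testing.assert_frame_equal(e1["counts"], e2["counts"])

    def test_null_generator_mean_tau_low(self):
        from tadscape import expression as xp

        lay = GenomeLayout(["c"], [1000 * 40_000], 40_000)
        sim = syn.simulate_expression(lay, n_tissues=5, n_reps=3,
                                      specific_bins=0.0, effect_log2fc=0.0, seed=25)
        cpm, tissue = xp.bin_cpm(sim["counts"], sim["sample_tissue"])
        mask = xp.testable_mask(tissue)
        tau = xp.tau_per_bin(tissue, mask)
        assert np.nanmean(tau) < 0.2

    def test_specific_bins_reach_high_tau(self):
        from tadscape import expression as xp

        lay = GenomeLayout(["c"], [1000 * 40_000], 40_000)
        sim = syn.simulate_expression(lay, n_tissues=5, n_reps=3,
                                      specific_bins=0.2, effect_log2fc=4.0, seed=26)
        cpm, tissue = xp.bin_cpm(sim["counts"], sim["sample_tissue"])
        tau = xp.tau_per_bin(tissue)
        spec_bins = sim["specific"]["bin"].to_numpy()
        assert np.nanmean(tau.to_numpy()[spec_bins]) > 0.6

    def test_library_sizes_within_twofold(self, small_layout):
        sim = syn.simulate_expression(small_layout, seed=27)
        lib = sim["counts"].sum(axis=0).to_numpy(dtype=float)
        assert lib.max() / lib.min() < 2.5  # factor drawn in [1, 2] plus count noise

    def test_parameter_validation(self, small_layout):
        with pytest.raises(ValueError):
            syn.simulate_expression(small_layout, n_tissues=1)
        with pytest.raises(ValueError):
            syn.simulate_expression(small_layout, specific_bins=1.5)
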