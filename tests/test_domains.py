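"""Domain calling, comparison, classification and boundary profiles."""

import numpy as np
import pandas as pd
import pytest

from tadscape import domains as dm
from tadscape import synthetic as syn
from tadscape.contact import ContactMatrix
from tadscape.layout import GenomeLayout

from conftest import make_truth


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def track_from_values(layout, chrom, values):
    bs = layout.bin_size
    n = len(values)
    return pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n) * bs,
         "end": np.minimum((np.arange(n) + 1) * bs, layout.length(chrom)),
         "value": values}
    )


class TestCallDomains:
    def test_planted_boundaries_recovered_within_one_bin(self):
        lay = GenomeLayout(["c"], [100 * 40_000, ], 40_000)
        doms = pd.DataFrame(
            {"chrom": "c",
             "start": np.array([0, 20, 40, 60, 80]) * 40_000,
             "end": np.array([20, 40, 60, 80, 100]) * 40_000,
             "class": "inactive"}
        )
        truth = make_truth(doms)
        m = syn.simulate_contact_map(
            lay, truth, "c", within_domain_fold=2.0, loop_fold=1.0,
            mean_depth=100.0, seed=3, gap_fraction=0.0,
        )
        _, bnd = dm.call_domains(m)
        called = bnd["start"].to_numpy() // 40_000
        planted = np.array([19, 39, 59, 79])
        for p in planted:
            assert np.min(np.abs(called - p)) <= 1

    def test_constant_matrix_one_domain_no_boundaries(self):
        lay = GenomeLayout(["c"], [40 * 40_000], 40_000)
        m = ContactMatrix(lay, "c", np.ones((40, 40)))
        doms, bnd = dm.call_domains(m)
        assert len(bnd) == 0
        assert len(doms) == 1
        assert doms.iloc[0]["start"] == 0 and doms.iloc[0]["end"] == lay.length("c")

    def test_invariant_to_global_scaling(self):
        lay = GenomeLayout(["c"], [80 * 40_000], 40_000)
        doms = pd.DataFrame(
            {"chrom": "c", "start": [0, 30 * 40_000], "end": [30 * 40_000, 80 * 40_000],
             "class": "HDF"}
        )
        m = syn.simulate_contact_map(
            lay, make_truth(doms), "c", within_domain_fold=2.5,
            mean_depth=80.0, seed=4, gap_fraction=0.0,
        )
        d1, b1 = dm.call_domains(m)
        m2 = ContactMatrix(lay, "c", m.counts * 13.7, masked_bins=m.masked_bins)
        d2, b2 = dm.call_domains(m2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_boundaries_on_bin_edges_and_domains_tile(self):
        lay = GenomeLayout(["c"], [100 * 40_000], 40_000)
        truth = syn.plant_truth(lay, seed=9)
        m = syn.simulate_contact_map(lay, truth, "c", mean_depth=60.0, seed=5)
        doms, bnd = dm.call_domains(m)
        assert (bnd["start"] % 40_000 == 0).all()
        assert (bnd["end"] - bnd["start"] == 40_000).all()
        # domains tile: non-overlapping, sorted
        s = doms.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


class TestConservedDomains:
    def test_identical_sets_fully_shared(self):
        a = bed([("c", 0, 100), ("c", 100, 250)])
        pairs, frac = dm.conserved_domains(a, a.copy())
        assert frac == 1.0
        assert len(pairs) == 2

    def test_half_overlap_not_conserved_at_80(self):
        a = bed([("c", 0, 100)])
        b = bed([("c", 50, 150)])
        pairs, frac = dm.conserved_domains(a, b, reciprocal=0.8)
        assert len(pairs) == 0

    def test_ninety_bp_overlap_conserved(self):
        a = bed([("c", 0, 100)])
        b = bed([("c", 10, 105)])
        pairs, frac = dm.conserved_domains(a, b, reciprocal=0.8)
        assert len(pairs) == 1  # overlap 90 > 80 and > 76

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(10)
        starts = np.sort(rng.choice(np.arange(0, 10_000, 100), 20, replace=False))
        a = bed([("c", int(s), int(s) + int(rng.integers(80, 300))) for s in starts[:10]])
        b = bed([("c", int(s), int(s) + int(rng.integers(80, 300))) for s in starts[10:]])
        _, f_ab = dm.conserved_domains(a, b)
        _, f_ba = dm.conserved_domains(b, a)
        assert f_ab == f_ba


class TestSharedBoundaries:
    def test_identical_sets(self):
        a = bed([("c", 0, 40_000), ("c", 400_000, 440_000)])
        pairs, frac = dm.shared_boundaries(a, a.copy(), bin_size=40_000)
        assert frac == 1.0

    def test_gap_rule_strict_at_one_bin(self):
        a = bed([("c", 0, 40_000)])
        near = bed([("c", 79_999, 119_999)])   # gap 39,999 < 40,000 -> matched
        far = bed([("c", 80_000, 120_000)])    # gap 40,000 -> not matched
        _, f1 = dm.shared_boundaries(a, near, bin_size=40_000)
        _, f2 = dm.shared_boundaries(a, far, bin_size=40_000)
        assert f1 == 1.0
        assert f2 == 0.0

    def test_empty_vs_nonempty(self):
        a = bed([("c", 0, 40_000)])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        _, frac = dm.shared_boundaries(a, empty, bin_size=40_000)
        assert frac == 0.0

    def test_differing_bin_sizes_rejected(self):
        a = bed([("c", 0, 40_000)])
        b = bed([("c", 0, 10_000)])
        with pytest.raises(ValueError):
            dm.shared_boundaries(a, b, bin_size=40_000)

    def test_symmetric_in_arguments(self):
        a = bed([("c", 0, 40_000), ("c", 200_000, 240_000), ("c", 400_000, 440_000)])
        b = bed([("c", 40_000, 80_000), ("c", 600_000, 640_000)])
        _, f_ab = dm.shared_boundaries(a, b, bin_size=40_000)
        _, f_ba = dm.shared_boundaries(b, a, bin_size=40_000)
        assert f_ab == f_ba


class TestCoverageJaccard:
    def test_identical_and_disjoint(self):
        a = bed([("c", 0, 100)])
        assert dm.coverage_jaccard(a, a.copy()) == 1.0
        assert dm.coverage_jaccard(a, bed([("c", 200, 300)])) == 0.0

    def test_worked_example(self):
        a = bed([("c", 0, 100)])
        b = bed([("c", 50, 150)])
        assert dm.coverage_jaccard(a, b) == pytest.approx(50 / 150)

    def test_matches_per_bp_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = bed([("c", int(s), int(s + rng.integers(1, 400)))
                     for s in rng.integers(0, 9_000, 8)])
            b = bed([("c", int(s), int(s + rng.integers(1, 400)))
                     for s in rng.integers(0, 9_000, 8)])
            cov_a = np.zeros(10_000, bool)
            cov_b = np.zeros(10_000, bool)
            for r in a.itertuples(index=False):
                cov_a[r.start:r.end] = True
            for r in b.itertuples(index=False):
                cov_b[r.start:r.end] = True
            expect = (cov_a & cov_b).sum() / (cov_a | cov_b).sum()
            assert dm.coverage_jaccard(a, b) == pytest.approx(expect)

    def test_both_empty_undefined(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        with pytest.warns(RuntimeWarning):
            assert np.isnan(dm.coverage_jaccard(empty, empty.copy()))


FEATURES = ["gene_density", "ltr_density", "methylation", "H3K4me3", "H3K9me2", "H3K27me3"]


def synthetic_classified(seed=12, n_per_class=15):
    lay = GenomeLayout(["c"], [(n_per_class * 3 * 10) * 40_000], 40_000)
    rows = []
    classes = []
    pos = 0
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.repeat(["active", "inactive", "HDF"], n_per_class))
    for cls in order:
        length = 10
        rows.append(("c", pos * 40_000, (pos + length) * 40_000, cls))
        classes.append(cls)
        pos += length
    doms = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
    truth = make_truth(doms)
    tracks = syn.simulate_tracks(lay, truth, seed=seed)
    return lay, doms, tracks


class TestClassifyDomains:
    def test_planted_classes_recovered(self):
        lay, doms, tracks = synthetic_classified()
        res = dm.classify_domains(
            doms[["chrom", "start", "end"]],
            {k: tracks[k] for k in FEATURES}, lay, ltr_feature="ltr_density",
        )
        agreement = (res.groups.to_numpy() == doms["class"].to_numpy()).mean()
        assert agreement >= 0.9

    def test_scaling_one_track_does_not_change_groups(self):
        lay, doms, tracks = synthetic_classified(seed=13)
        t1 = {k: tracks[k] for k in FEATURES}
        t2 = {k: v.copy() for k, v in t1.items()}
        t2["H3K9me2"] = t2["H3K9me2"].assign(value=t2["H3K9me2"]["value"] * 10)
        r1 = dm.classify_domains(doms[["chrom", "start", "end"]], t1, lay, ltr_feature="ltr_density")
        r2 = dm.classify_domains(doms[["chrom", "start", "end"]], t2, lay, ltr_feature="ltr_density")
        assert (r1.groups == r2.groups).all()

    def test_duplicating_domains_keeps_assignments(self):
        lay, doms, tracks = synthetic_classified(seed=14, n_per_class=8)
        sub = doms[["chrom", "start", "end"]]
        dup = pd.concat([sub, sub], ignore_index=True)
        r1 = dm.classify_domains(sub, {k: tracks[k] for k in FEATURES}, lay, ltr_feature="ltr_density")
        r2 = dm.classify_domains(dup, {k: tracks[k] for k in FEATURES}, lay, ltr_feature="ltr_density")
        n = len(sub)
        assert (r2.groups.to_numpy()[:n] == r2.groups.to_numpy()[n:]).all()
        assert (r1.groups.to_numpy() == r2.groups.to_numpy()[:n]).all()

    def test_k_larger_than_n_rejected(self):
        lay, doms, tracks = synthetic_classified(seed=15, n_per_class=1)
        with pytest.raises(ValueError):
            dm.classify_domains(doms[["chrom", "start", "end"]].head(2),
                                {k: tracks[k] for k in FEATURES}, lay, k=5,
                                ltr_feature="ltr_density")


class TestBoundaryProfile:
    def test_constant_track_flat_profile(self):
        lay = GenomeLayout(["c"], [100 * 40_000], 40_000)
        track = track_from_values(lay, "c", np.full(100, 2.5))
        bnd = bed([("c", 40 * 40_000, 41 * 40_000)])
        prof = dm.boundary_profile(bnd, track, lay, flank_bp=200_000)
        assert np.allclose(prof["mean"], 2.5)

    def test_indicator_track_peaks_at_zero(self):
        lay = GenomeLayout(["c"], [100 * 40_000], 40_000)
        vals = np.zeros(100)
        centers = [20, 50, 80]
        vals[centers] = 1.0
        track = track_from_values(lay, "c", vals)
        bnd = bed([("c", c * 40_000, (c + 1) * 40_000) for c in centers])
        prof = dm.boundary_profile(bnd, track, lay, flank_bp=200_000)
        at0 = prof.loc[prof["offset_bp"] == 0, "mean"].iloc[0]
        assert at0 == 1.0

    def test_planted_dip_recovered_within_two_se(self):
        lay = GenomeLayout(["c"], [400 * 40_000], 40_000)
        rng = np.random.default_rng(16)
        vals = rng.normal(10.0, 1.0, size=400)
        centers = np.arange(20, 400, 20)
        dip = 3.0
        vals[centers] -= dip
        track = track_from_values(lay, "c", vals)
        bnd = bed([("c", int(c) * 40_000, (int(c) + 1) * 40_000) for c in centers])
        prof = dm.boundary_profile(bnd, track, lay, flank_bp=200_000)
        at0 = prof.loc[prof["offset_bp"] == 0]
        off = prof.loc[prof["offset_bp"].abs() > 80_000]
        est_dip = off["mean"].mean() - at0["mean"].iloc[0]
        se = float(at0["se"].iloc[0])
        assert abs(est_dip - dip) <= 2 * se + 2 * off["se"].mean()

    def test_chromosome_end_boundaries_contribute_valid_offsets(self):
        lay = GenomeLayout(["c"], [50 * 40_000], 40_000)
        track = track_from_values(lay, "c", np.arange(50, dtype=float))
        bnd = bed([("c", 0, 40_000)])
        prof = dm.boundary_profile(bnd, track, lay, flank_bp=120_000)
        left = prof.loc[prof["offset_bp"] < 0, "n"]
        assert (left == 0).all()
        assert prof.loc[prof["offset_bp"] == 0, "n"].iloc[0] == 1
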