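"""Loop calling, master merging, differential rule, anchor annotation,
APA and insulation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cyclehic import contacts as ct
from cyclehic import loops as lp
from cyclehic.genome import BinTable, ChromSizes, Interval


def flat_map_with_pixel(n=120, base=5.0, pixel=None, value=300.0):
    """Deterministic flat map (z=1 everywhere) with one extreme pixel."""
    bins = BinTable(ChromSizes([("chr1", n * 10_000)]), 10_000)
    a = np.full((n, n), base)
    if pixel is not None:
        i, j = pixel
        a[i, j] = a[j, i] = value
    cmap = ct.ContactMap(bins, sp.csr_matrix(a))
    expected = ct.expected_by_distance(cmap, use_weights=False)
    z = ct.distance_normalize(cmap, expected)
    return cmap, expected, z


def loopset(records, bin_size=10_000) -> lp.LoopSet:
    df = pd.DataFrame(records, columns=["chrom", "bin1", "bin2", "z"])
    df["p"] = 0.0
    df["q"] = 0.0
    df["sample"] = "s"
    return lp.LoopSet(df, {"bin_size": bin_size})


class TestCallLoops:
    def test_single_extreme_pixel_called_exactly_once(self):
        cmap, expected, z = flat_map_with_pixel(pixel=(40, 80))
        ls = lp.call_loops(z, cmap, expected)
        assert len(ls) == 1
        row = ls.loops.iloc[0]
        assert (row["bin1"], row["bin2"]) == (40, 80)

    def test_flat_map_yields_nothing(self):
        cmap, expected, z = flat_map_with_pixel(pixel=None)
        assert len(lp.call_loops(z, cmap, expected)) == 0

    def test_min_dist_and_span_filters(self):
        cmap, expected, z = flat_map_with_pixel(pixel=(40, 43))  # 3 bins off-diagonal
        assert len(lp.call_loops(z, cmap, expected, min_dist=5)) == 0
        cmap, expected, z = flat_map_with_pixel(pixel=(10, 100))
        assert len(lp.call_loops(z, cmap, expected, max_span=50)) == 0

    def test_scale_invariance_of_raw_counts(self):
        cmap, expected, z = flat_map_with_pixel(pixel=(40, 80))
        ls1 = lp.call_loops(z, cmap, expected)
        scaled = ct.ContactMap(cmap.bins, cmap.counts * 3)
        e2 = ct.expected_by_distance(scaled, use_weights=False)
        z2 = ct.distance_normalize(scaled, e2)
        ls2 = lp.call_loops(z2, scaled, e2)
        assert list(ls1.loops["bin1"]) == list(ls2.loops["bin1"])
        assert list(ls1.loops["bin2"]) == list(ls2.loops["bin2"])

    def test_empty_map_rejected(self, tiny_bins):
        z = ct.DistNormMap(tiny_bins, {c: np.full((5, 5), np.nan) for c in tiny_bins.sizes.names})
        cmap = ct.ContactMap(tiny_bins, sp.csr_matrix((tiny_bins.n_bins, tiny_bins.n_bins)))
        with pytest.raises(ValueError, match="empty"):
            lp.call_loops(z, cmap, ct.ExpectedProfile(tiny_bins, {}, False))


class TestMergeMaster:
    def test_merge_rule_at_25kb(self):
        near = loopset([("chr1", 100, 200, 5.0), ("chr1", 102, 202, 4.0)])  # 20 kb apart
        assert len(lp.merge_master([near], radius_bp=25_000, bin_size=10_000)) == 1
        far = loopset([("chr1", 100, 200, 5.0), ("chr1", 103, 203, 4.0)])  # 30 kb apart
        assert len(lp.merge_master([far], radius_bp=25_000, bin_size=10_000)) == 2

    def test_representative_is_highest_z(self):
        s = loopset([("chr1", 100, 200, 2.0), ("chr1", 101, 201, 9.0)])
        m = lp.merge_master([s], bin_size=10_000)
        assert m.loops.iloc[0]["z"] == 9.0

    def test_idempotent(self, rng):
        recs = [
            ("chr1", int(rng.integers(0, 300)), int(rng.integers(300, 600)), float(rng.random()))
            for _ in range(80)
        ]
        m1 = lp.merge_master([loopset(recs)], bin_size=10_000)
        m2 = lp.merge_master([m1], bin_size=10_000)
        assert len(m1) == len(m2)
        pd.testing.assert_frame_equal(
            m1.loops.sort_values(["bin1", "bin2"]).reset_index(drop=True),
            m2.loops.sort_values(["bin1", "bin2"]).reset_index(drop=True),
        )

    def test_matches_bruteforce_transitive_closure(self, rng):
        recs = [
            (str(rng.choice(["chr1", "chr2"])), int(rng.integers(0, 80)),
             int(rng.integers(80, 160)), float(rng.random()))
            for _ in range(200)
        ]
        m = lp.merge_master([loopset(recs)], radius_bp=25_000, bin_size=10_000)

        # brute-force union-find over all pairs
        parent = list(range(len(recs)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                a, b = recs[i], recs[j]
                if a[0] == b[0] and abs(a[1] - b[1]) * 10_000 <= 25_000 and abs(a[2] - b[2]) * 10_000 <= 25_000:
                    parent[find(j)] = find(i)
        n_clusters = len({find(i) for i in range(len(recs))})
        assert len(m) == n_clusters

    def test_master_not_larger_than_inputs(self, rng):
        sets = [
            loopset([("chr1", int(rng.integers(0, 100)), int(rng.integers(100, 200)), 1.0)
                     for _ in range(20)])
            for _ in range(3)
        ]
        m = lp.merge_master(sets, bin_size=10_000)
        assert len(m) <= 60


class TestDifferentialRule:
    @pytest.mark.parametrize(
        "za,zb,expect_flag,expect_dir",
        [
            (2.6, 1.0, True, "A-specific"),   # fold 2.6 >= 2.5, max > 2
            (2.6, 1.2, False, "A-specific"),  # fold ~2.17 < 2.5
            (1.0, 2.6, True, "B-specific"),
            (1.9, 0.5, False, "A-specific"),  # fold ok but max z <= 2
        ],
    )
    def test_boundaries(self, za, zb, expect_flag, expect_dir):
        fold, flagged, direction = lp.apply_differential_rule(
            np.array([za]), np.array([zb])
        )
        assert flagged[0] == expect_flag
        assert direction[0] == expect_dir

    def test_self_comparison_flags_nothing(self):
        cmap, expected, z = flat_map_with_pixel(pixel=(40, 80))
        master = loopset([("chr1", 40, 80, 50.0)])
        out = lp.diff_loops(master, z, z)
        assert not out["flagged"].any()

    def test_peak_z_reads_3x3_max(self):
        a = np.ones((20, 20))
        a[5, 11] = 7.0  # 1-bin drift from the master pixel
        assert lp.peak_z(a, 5, 10) == 7.0
        assert lp.peak_z(a, 5, 13) == 1.0


class TestAnnotateAnchors:
    def _bins(self):
        return BinTable(ChromSizes([("chr1", 3_000_000)]), 10_000)

    def test_convergent_both(self):
        bins = self._bins()
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [10], "bin2": [50]})
        atac = [Interval("chr1", 105_000, 105_400), Interval("chr1", 505_000, 505_400)]
        ctcf = [
            Interval("chr1", 104_000, 104_019, "m1", "+"),
            Interval("chr1", 504_000, 504_019, "m2", "-"),
        ]
        out = lp.annotate_anchors(loops, bins, atac, ctcf)
        assert out.iloc[0]["category"] == "both"
        assert out.iloc[0]["convergence"] == "convergent"

    @pytest.mark.parametrize(
        "s1,s2,expected",
        [("+", "-", "convergent"), ("-", "+", "divergent"), ("+", "+", "tandem"), ("-", "-", "tandem")],
    )
    def test_orientation_classes(self, s1, s2, expected):
        bins = self._bins()
        loops = pd.DataFrame({"chrom": ["chr1"], "bin1": [10], "bin2": [50]})
        ctcf = [
            Interval("chr1", 104_000, 104_019, "m1", s1),
            Interval("chr1", 504_000, 504_019, "m2", s2),
        ]
        out = lp.annotate_anchors(loops, bins, [], ctcf)
        assert out.iloc[0]["convergence"] == expected

    def test_no_annotation_all_neither(self):
        bins = self._bins()
        loops = pd.DataFrame({"chrom": ["chr1", "chr1"], "bin1": [10, 20], "bin2": [50, 90]})
        out = lp.annotate_anchors(loops, bins, [], [])
        assert (out["category"] == "neither").all()
        assert (out["convergence"] == "ambiguous").all()

    def test_synthetic_world_fully_convergent(self, demo_ds):
        out = lp.annotate_anchors(
            demo_ds.truth.loops, demo_ds.bins, demo_ds.atac, demo_ds.ctcf
        )
        assert (out["category"] == "both").all()
        assert (out["convergence"] == "convergent").all()
        comp = lp.anchor_composition(out)
        assert comp["both"] == pytest.approx(1.0)


class TestApa:
    def test_uniform_z_gives_score_one(self):
        _, _, z = flat_map_with_pixel(pixel=None)
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "bin1": [20, 30, 40], "bin2": [60, 80, 90]})
        res = lp.apa(z, sites)
        assert res["score"] == pytest.approx(1.0)
        assert res["n_sites"] == 3

    def test_sites_near_diagonal_excluded(self):
        _, _, z = flat_map_with_pixel(pixel=None)
        sites = pd.DataFrame({"chrom": ["chr1"], "bin1": [20], "bin2": [25]})
        with pytest.raises(ValueError, match="excluded"):
            lp.apa(z, sites, half_window=10)

    def test_planted_pixel_dominates_centre(self):
        _, _, z = flat_map_with_pixel(pixel=(40, 80), value=50.0)
        sites = pd.DataFrame({"chrom": ["chr1"], "bin1": [40], "bin2": [80]})
        res = lp.apa(z, sites)
        assert res["score"] > 5
        assert res["corner_ratio"] > 2


class TestInsulation:
    def _map(self, a):
        bins = BinTable(ChromSizes([("chr1", a.shape[0] * 10_000)]), 10_000)
        m = ct.ContactMap(bins, sp.csr_matrix(a))
        return ct.balance(m)

    def test_two_block_boundary_is_minimum(self):
        n = 80
        a = np.full((n, n), 1.0)
        a[:40, :40] += 30
        a[40:, 40:] += 30
        np.fill_diagonal(a, 40.0)
        ins = lp.insulation(self._map(a), window=10)["chr1"]
        valid = np.isfinite(ins)
        assert np.nanargmin(ins) in (39, 40, 41)

    def test_uniform_map_near_zero(self):
        a = np.full((60, 60), 9.0)
        ins = lp.insulation(self._map(a), window=10)["chr1"]
        assert np.nanmax(np.abs(ins)) == pytest.approx(0.0, abs=1e-6)

    def test_window_exceeding_span_rejected(self):
        a = np.full((15, 15), 4.0)
        with pytest.raises(ValueError, match="window"):
            lp.insulation(self._map(a), window=20)

    def test_aggregate_domains_interior_enriched(self):
        n = 120
        a = np.full((n, n), 2.0)
        regions = [("chr1", 20, 40), ("chr1", 60, 80)]
        for lo, hi in [(20, 40), (60, 80)]:
            a[lo:hi, lo:hi] *= 4
        bins = BinTable(ChromSizes([("chr1", n * 10_000)]), 10_000)
        m = ct.ContactMap(bins, sp.csr_matrix(a))
        e = ct.expected_by_distance(m, use_weights=False)
        z = ct.distance_normalize(m, e)
        ada = lp.aggregate_domains(z, regions, out_size=40)
        interior = ada[10:30, 10:30].mean()
        exterior = (ada.sum() - ada[10:30, 10:30].sum()) / (ada.size - 400)
        assert interior > exterior
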