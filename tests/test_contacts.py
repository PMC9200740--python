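"""Contact-map model: loading, balancing, expected profiles, the
pseudocounted z signal, downsampling and replicate distances."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import stats

from cyclehic import contacts as ct
from cyclehic.genome import BinTable, ChromSizes
from cyclehic.simulate import SyntheticSpec, generate


def dense_map(bins: BinTable, arr: np.ndarray) -> ct.ContactMap:
    return ct.ContactMap(bins, sp.csr_matrix(arr))


@pytest.fixture()
def small_bins():
    return BinTable(ChromSizes([("chr1", 500_000)]), 10_000)  # 50 bins


class TestLoading:
    def test_symmetrisation_sums_both_orientations(self, tmp_path, tiny_bins):
        p = tmp_path / "c.txt"
        p.write_text("chr1\t0\tchr1\t10000\t3\nchr1\t10000\tchr1\t0\t4\n")
        m = ct.load_contacts(p, tiny_bins)
        assert m.counts[0, 1] == 7 and m.counts[1, 0] == 7
        assert m.total_contacts == 7

    def test_empty_file_and_downstream_refusal(self, tmp_path, tiny_bins):
        p = tmp_path / "c.txt"
        p.write_text("")
        m = ct.load_contacts(p, tiny_bins)
        assert m.total_contacts == 0
        with pytest.raises(ValueError, match="empty matrix"):
            ct.balance(m)
        with pytest.raises(ValueError, match="empty matrix"):
            ct.trans_fraction(m)

    def test_total_equals_count_column_sum(self, rng, tiny_bins):
        n = tiny_bins.n_bins
        i = rng.integers(0, n, 10_000)
        j = rng.integers(0, n, 10_000)
        keep = i <= j  # upper triangle only, so no double counting
        c = rng.integers(1, 10, keep.sum())
        m = ct.ContactMap.from_triplets(tiny_bins, i[keep], j[keep], c)
        assert m.total_contacts == c.sum()

    def test_out_of_range_bin_rejected(self, tiny_bins):
        with pytest.raises(ValueError, match="record"):
            ct.ContactMap.from_triplets(
                tiny_bins, np.array([0]), np.array([tiny_bins.n_bins]), np.array([1.0])
            )

    def test_write_read_roundtrip(self, tmp_path, tiny_bins, rng):
        n = tiny_bins.n_bins
        i = rng.integers(0, n, 500)
        j = rng.integers(0, n, 500)
        c = rng.integers(1, 20, 500).astype(float)
        m = ct.ContactMap.from_triplets(tiny_bins, i, j, c)
        p = tmp_path / "out.txt"
        ct.write_contacts(m, p)
        back = ct.load_contacts(p, tiny_bins)
        assert (back.counts != m.counts).nnz == 0


class TestBalance:
    def test_equal_margin_fixed_point(self, small_bins):
        n = small_bins.n_bins
        m = dense_map(small_bins, np.full((n, n), 4.0))
        b = ct.balance(m)
        w = b.weights
        assert np.allclose(w, w[0])

    def test_zero_bin_filtered_others_converge(self, small_bins, rng):
        n = small_bins.n_bins
        a = rng.integers(1, 20, (n, n)).astype(float)
        a = a + a.T
        a[7, :] = 0
        a[:, 7] = 0
        b = ct.balance(dense_map(small_bins, a))
        assert not np.isfinite(b.weights[7])
        assert b.balance_converged

    def test_margin_cv_below_tolerance(self, rng):
        bins = BinTable(ChromSizes([("chr1", 2_000_000)]), 10_000)  # 200 bins
        n = bins.n_bins
        a = rng.integers(0, 30, (n, n)).astype(float)
        a = a + a.T
        b = ct.balance(dense_map(bins, a))
        bal = b.cis_dense("chr1", balanced=True)
        keep = np.isfinite(b.weights)
        margins = bal[np.ix_(keep, keep)].sum(axis=1)
        assert margins.std() / margins.mean() < 1e-3

    def test_invariant_to_bin_permutation(self, small_bins, rng):
        n = small_bins.n_bins
        a = rng.integers(1, 30, (n, n)).astype(float)
        a = a + a.T
        perm = rng.permutation(n)
        b1 = ct.balance(dense_map(small_bins, a))
        b2 = ct.balance(dense_map(small_bins, a[np.ix_(perm, perm)]))
        assert np.allclose(b2.weights, b1.weights[perm], rtol=1e-6)


class TestExpected:
    def test_constant_diagonals(self, small_bins):
        n = small_bins.n_bins
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        a = (d + 1.0) * 2  # value depends only on separation
        e = ct.expected_by_distance(dense_map(small_bins, a), use_weights=False)
        v = e.values["chr1"]
        assert np.allclose(v, (np.arange(n) + 1.0) * 2)

    def test_matches_bruteforce_mean(self, small_bins, rng):
        n = small_bins.n_bins
        a = rng.integers(0, 50, (n, n)).astype(float)
        a = a + a.T
        e = ct.expected_by_distance(dense_map(small_bins, a), use_weights=False)
        for d in (0, 1, 7, n - 1):
            brute = np.diagonal(a, offset=d).mean()
            assert e.at("chr1", d) == pytest.approx(brute)

    def test_out_of_range_distance_errors(self, small_bins):
        n = small_bins.n_bins
        e = ct.expected_by_distance(
            dense_map(small_bins, np.ones((n, n))), use_weights=False
        )
        with pytest.raises(ValueError, match="undefined"):
            e.at("chr1", n)


class TestDistanceNormalize:
    def test_formula(self, small_bins):
        n = small_bins.n_bins
        a = np.ones((n, n))
        a[3, 9] = a[9, 3] = 3.0
        e = ct.ExpectedProfile(small_bins, {"chr1": np.ones(n)}, balanced=False)
        z = ct.distance_normalize(dense_map(small_bins, a), e)
        assert z.z["chr1"][3, 9] == pytest.approx((3 + 1) / (1 + 1))

    def test_identity_when_observed_equals_expected(self, small_bins):
        n = small_bins.n_bins
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        a = (d + 1.0) * 3
        m = dense_map(small_bins, a)
        z = ct.distance_normalize(m, ct.expected_by_distance(m, use_weights=False))
        assert np.allclose(z.z["chr1"], 1.0)

    def test_matches_bruteforce(self, rng):
        bins = BinTable(ChromSizes([("chr1", 1_000_000)]), 10_000)  # 100 bins
        n = bins.n_bins
        a = rng.integers(0, 40, (n, n)).astype(float)
        a = a + a.T
        m = dense_map(bins, a)
        e = ct.expected_by_distance(m, use_weights=False)
        z = ct.distance_normalize(m, e)
        brute = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                brute[i, j] = (a[i, j] + 1) / (e.values["chr1"][abs(i - j)] + 1)
        assert np.allclose(z.z["chr1"], brute)

    def test_mismatched_bins_rejected(self, small_bins, tiny_bins):
        n = small_bins.n_bins
        m = dense_map(small_bins, np.ones((n, n)))
        e_other = ct.ExpectedProfile(
            tiny_bins, {c: np.ones(tiny_bins.n_bins_of(c)) for c in tiny_bins.sizes.names},
            balanced=False,
        )
        with pytest.raises(ValueError, match="mismatch"):
            ct.distance_normalize(m, e_other)

    def test_self_consistency_expected_of_z_near_one(self, loop_analysis):
        """Re-deriving the expected profile of z must give ~1 at every distance."""
        z = loop_analysis["z"]
        for chrom, zc in z.z.items():
            n = zc.shape[0]
            for d in (1, 10, 100):
                diag = np.diagonal(zc, offset=d)
                diag = diag[np.isfinite(diag)]
                assert diag.mean() == pytest.approx(1.0, abs=0.08)


class TestDownsample:
    def test_identity_and_empty(self, small_bins, rng):
        n = small_bins.n_bins
        a = rng.integers(0, 10, (n, n)).astype(float)
        a = a + a.T
        m = dense_map(small_bins, a)
        same = ct.downsample(m, int(m.total_contacts), seed=0)
        assert (same.counts != m.counts).nnz == 0
        empty = ct.downsample(m, 0, seed=0)
        assert empty.total_contacts == 0
        with pytest.raises(ValueError, match="exceeds"):
            ct.downsample(m, int(m.total_contacts) + 1)

    def test_hypergeometric_cell_means(self, rng):
        """Halving depth halves each cell in expectation (within 3 SE)."""
        bins = BinTable(ChromSizes([("chr1", 500_000)]), 10_000)
        n = bins.n_bins
        a = np.zeros((n, n))
        iu, ju = np.triu_indices(n)
        cells = rng.choice(iu.size, 500, replace=False)
        vals = rng.integers(50, 400, 500).astype(float)
        a[iu[cells], ju[cells]] = vals
        a = np.triu(a) + np.triu(a, 1).T
        m = dense_map(bins, a)
        total = int(m.total_contacts)
        target = total // 2
        acc = np.zeros(500)
        n_seeds = 200
        for s in range(n_seeds):
            d = ct.downsample(m, target, seed=s)
            acc += np.asarray(d.counts[iu[cells], ju[cells]]).ravel()
        mean = acc / n_seeds
        expect = vals * target / total
        se = np.sqrt(vals * (target / total) * (1 - target / total) / n_seeds)
        assert (np.abs(mean - expect) <= 3 * se + 1e-9).mean() > 0.98

    def test_chromosome_totals_match_hypergeometric_margin(self):
        """Exchangeability: per-chromosome totals follow the multivariate
        hypergeometric margin (chi-square GOF across 200 seeds)."""
        bins = BinTable(ChromSizes([("chr1", 300_000), ("chr2", 300_000)]), 10_000)
        rng = np.random.default_rng(7)
        n = bins.n_bins
        a = rng.integers(0, 6, (n, n)).astype(float)
        a = a + a.T
        m = dense_map(bins, a)
        total = int(m.total_contacts)
        sl = bins.chrom_slice("chr1")
        coo = sp.triu(m.counts).tocoo()
        on_chr1 = (coo.row < sl.stop) & (coo.col < sl.stop)
        K = int(coo.data[on_chr1].sum())  # chr1-internal contacts
        target = total // 3
        obs = []
        for s in range(200):
            d = ct.downsample(m, target, seed=1000 + s)
            dcoo = sp.triu(d.counts).tocoo()
            sel = (dcoo.row < sl.stop) & (dcoo.col < sl.stop)
            obs.append(dcoo.data[sel].sum())
        obs = np.asarray(obs)
        hg = stats.hypergeom(total, K, target)
        edges = hg.ppf([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        edges[0], edges[-1] = -np.inf, np.inf
        counts, _ = np.histogram(obs, bins=edges)
        probs = np.diff(hg.cdf(np.where(np.isinf(edges), [0 - 1, *edges[1:-1], total], edges)))
        probs = probs / probs.sum()
        res = stats.chisquare(counts, 200 * probs)
        assert res.pvalue > 0.01


class TestReplicateDistances:
    def test_duplicate_map_distance_zero(self, loop_analysis):
        z = loop_analysis["z"]
        D, emb = ct.replicate_distances([z, z])
        assert D[0, 1] == pytest.approx(0.0)

    def test_single_map_rejected(self, loop_analysis):
        with pytest.raises(ValueError, match=">=2"):
            ct.replicate_distances([loop_analysis["z"]])

    def test_two_condition_replicates_separate(self):
        """3+3 replicates of two conditions differing in planted loops
        cluster perfectly by condition once low-coverage pairs are dropped."""
        anchors = [(10 + 14 * k, 18 + 14 * k + 6 * (k % 3)) for k in range(20)]
        loops = [("chr1", a, b, 8.0) for a, b in anchors]
        from cyclehic.simulate import ConditionEffect

        spec = SyntheticSpec(
            chrom_sizes={"chr1": 3_000_000},
            loops=loops,
            conditions=["A", "B"],
            condition_effects={
                "B": ConditionEffect(loop_folds={k: 1.0 for k in range(20)})
            },
            seed=11,
        )
        ds = generate(spec)
        zs, labels = [], []
        cap = None
        for cond in ("A", "B"):
            for m in ds.maps[cond]:
                _, e, z = ct.prepare(m)
                cap = ct.informative_max_dist(e) if cap is None else cap
                zs.append(z)
                labels.append(cond)
        D, emb = ct.replicate_distances(zs, max_dist_bins=cap)
        within = [D[i, j] for i in range(6) for j in range(i + 1, 6) if labels[i] == labels[j]]
        between = [D[i, j] for i in range(6) for j in range(i + 1, 6) if labels[i] != labels[j]]
        assert max(within) < min(between)
        # the first principal coordinate alone separates the conditions
        side = emb[:, 0] > np.median(emb[:, 0])
        assert len({tuple(side[:3])}) == 1 and len({tuple(side[3:])}) == 1
        assert side[0] != side[3]


class TestTransFraction:
    def test_cis_only_map(self, loop_analysis):
        assert ct.trans_fraction(loop_analysis["raw"]) == 0.0

    def test_equal_cis_trans_per_chromosome(self):
        bins = BinTable(ChromSizes([("chr1", 20_000), ("chr2", 20_000)]), 10_000)
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 5  # chr1 cis
        a[2, 3] = a[3, 2] = 5  # chr2 cis
        a[0, 2] = a[2, 0] = 5  # trans: each chromosome sees 5 cis + 5 trans
        m = ct.ContactMap(bins, sp.csr_matrix(a))
        g, per = ct.trans_fraction(m, by_chromosome=True)
        assert per["chr1"] == pytest.approx(0.5)
        assert per["chr2"] == pytest.approx(0.5)

    def test_planted_trans_rate_recovered(self):
        ds = generate(SyntheticSpec(trans_rate=0.3, seed=9, n_replicates=1, depth=1_000_000))
        got = ct.trans_fraction(ds.maps["A"][0])
        assert got == pytest.approx(0.3, abs=0.01)
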