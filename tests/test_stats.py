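"""Distance statistics against enumeration oracles, closed forms, calibration
simulations, and independent library implementations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from volatilome import DistanceMatrix
from volatilome import stats as st


def frame(rng, n, p, ids=None):
    return pd.DataFrame(rng.normal(size=(n, p)),
                        index=ids or [f"s{i}" for i in range(n)])


class TestEuclidean:
    def test_three_four_five(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        d = st.euclidean_distances(df)
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert st.euclidean_distances(df).values[0, 1] == 0.0

    def test_matches_elementwise_sum_of_squares(self):
        rng = np.random.default_rng(0)
        df = frame(rng, 10, 5)
        d = st.euclidean_distances(df)
        x = df.to_numpy()
        for i in range(10):
            for j in range(10):
                expected = np.sqrt(sum((x[i, k] - x[j, k]) ** 2 for k in range(5)))
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        d = st.euclidean_distances(frame(rng, 8, 4)).values
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_rejects_missing_values(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["a"])
        with pytest.raises(ValueError, match="missing"):
            st.euclidean_distances(df)


def permanova_oracle(d2: np.ndarray, labels: list) -> tuple[float, float]:
    """Loop-based pseudo-F and exhaustive p over all distinct relabelings."""
    labels = list(labels)
    n = len(labels)

    def f_stat(lab):
        ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ss_within = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
        k = len(set(lab))
        return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))

    f_obs = f_stat(labels)
    arrangements = set(itertools.permutations(labels))
    count = sum(1 for a in arrangements if f_stat(a) >= f_obs - 1e-12)
    return f_obs, count / len(arrangements)


class TestPermanova:
    def test_label_symmetry(self):
        rng = np.random.default_rng(2)
        d = st.euclidean_distances(frame(rng, 8, 3))
        cfg = st.StatsConfig(n_permutations=99, seed=5)
        a = st.permanova(d, ["x"] * 4 + ["y"] * 4, cfg)
        b = st.permanova(d, ["y"] * 4 + ["x"] * 4, cfg)
        assert a.pseudo_f == pytest.approx(b.pseudo_f)
        assert a.r2 == pytest.approx(b.r2)
        assert a.p == b.p

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = st.euclidean_distances(frame(rng, 6, 4))
            labels = ["a", "a", "a", "b", "b", "b"]
            res = st.permanova(d, labels, exhaustive=True)
            f_oracle, p_oracle = permanova_oracle(d.values ** 2, labels)
            assert res.n_permutations == 20
            assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-10)
            assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_monte_carlo_approaches_exhaustive(self):
        rng = np.random.default_rng(4)
        d = st.euclidean_distances(frame(rng, 7, 3))
        labels = ["a"] * 3 + ["b"] * 4
        exact = st.permanova(d, labels, exhaustive=True).p
        mc = st.permanova(d, labels, st.StatsConfig(n_permutations=9999, seed=0)).p
        assert mc == pytest.approx(exact, abs=0.02)

    def test_agrees_with_skbio_pseudo_f(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        df = frame(rng, 12, 4)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mine = st.permanova(st.euclidean_distances(df), labels,
                            st.StatsConfig(n_permutations=99, seed=0))
        dm = skbio_distance.DistanceMatrix(
            st.euclidean_distances(df).values, ids=list(df.index))
        theirs = skbio_distance.permanova(dm, grouping=labels, permutations=99)
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_degenerate_inputs_raise(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            st.permanova(d, ["x", "x", "y"])
        d2 = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="2 groups"):
            st.permanova(d2, ["x", "x"])

    def test_species_signal_hits_permutation_floor(self, small_dataset):
        _, table, meta, _ = small_dataset
        cultures = meta.index[meta["role"] == "sample"]
        d = st.euclidean_distances(table.subset_samples(list(cultures)))
        res = st.permanova(d, meta.loc[cultures, "species"],
                           st.StatsConfig(n_permutations=999, seed=1))
        assert res.p == pytest.approx(1 / 1000)
        assert res.r2 > 0.05


class TestWithinBetween:
    @staticmethod
    def _meta(labels, ids):
        return pd.DataFrame({"species": labels,
                             "strain": labels}, index=ids)

    def test_perfect_separation_attains_minimal_p(self):
        """All within-distances 0, all between 1: p equals the exact rank-sum
        minimum for those pair counts."""
        ids = ["a1", "a2", "b1", "b2"]
        v = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float)
        d = DistanceMatrix(ids, v)
        meta = self._meta(["A", "A", "B", "B"], ids)
        _, p = st.within_between_test(d, meta, level="species")
        # exact one-sided p for 2 within-pairs all below 4 between-pairs
        within, between = [0.0, 0.0], [1.0, 1.0, 1.0, 1.0]
        expected = sps.mannwhitneyu(within, between, alternative="less",
                                    method="exact").pvalue
        assert p == pytest.approx(expected)
        assert p == min(p, 0.07)  # minimal attainable with 2x4 pairs: 1/C(6,2)

    def test_null_calibration_under_shuffled_labels(self):
        """Rejection rate at alpha = 0.05 stays within [0.01, 0.10] when labels
        carry no structure."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            df = frame(rng, 18, 6)
            d = st.euclidean_distances(df)
            labels = rng.permutation(np.repeat(["a", "b", "c"], 6))
            meta = self._meta(labels, list(df.index))
            _, p = st.within_between_test(d, meta, level="species")
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_sims <= 0.10

    def test_zero_technical_noise_degenerate(self):
        import volatilome.synthdata as sd

        spec = sd.SyntheticSpec(n_species=3, strains_per_species=2,
                                n_signal_peaks=30, n_noise_peaks=0, n_blanks=2,
                                n_general_peaks=2, technical_cv=0.0, seed=9)
        table, meta, _ = sd.generate_dataset(spec)
        cultures = meta.index[meta["role"] == "sample"]
        d = st.euclidean_distances(table.subset_samples(list(cultures)))
        _, p = st.within_between_test(d, meta.loc[cultures],
                                      level="strain-within-species")
        # all within-strain distances are exactly 0 -> smallest attainable p
        iu = np.triu_indices(len(d), k=1)
        strains = meta.loc[cultures, "strain"].to_numpy()
        within = d.values[iu][strains[iu[0]] == strains[iu[1]]]
        assert np.all(within == 0.0)
        assert p < 1e-6

    def test_empty_partition_raises(self):
        ids = ["a1", "b1"]
        d = DistanceMatrix(ids, np.array([[0.0, 1.0], [1.0, 0.0]]))
        meta = self._meta(["A", "B"], ids)
        with pytest.raises(ValueError, match="partition"):
            st.within_between_test(d, meta, level="species")


class TestMantel:
    def test_linear_transform_gives_r_one(self):
        rng = np.random.default_rng(7)
        d1 = st.euclidean_distances(frame(rng, 6, 3))
        d2 = DistanceMatrix(d1.ids, 2.0 * d1.values)
        r, _ = st.mantel(d1, d2, st.StatsConfig(n_permutations=99, seed=0))
        assert r == pytest.approx(1.0)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        d1 = st.euclidean_distances(frame(rng, 4, 3))
        d2 = st.euclidean_distances(frame(rng, 4, 3, ids=list(d1.ids)))
        r_obs, p = st.mantel(d1, d2, exhaustive=True)
        iu = np.triu_indices(4, k=1)
        x = d1.values[iu]
        count = total = 0
        for perm in itertools.permutations(range(4)):
            pm = np.array(perm)
            y = d2.values[np.ix_(pm, pm)][iu]
            r = np.corrcoef(x, y)[0, 1]
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_independent_matrices_rarely_reject(self):
        rng = np.random.default_rng(9)
        rejections, small_r = 0, 0
        for _ in range(100):
            d1 = st.euclidean_distances(frame(rng, 10, 5))
            d2 = st.euclidean_distances(frame(rng, 10, 5, ids=list(d1.ids)))
            r, p = st.mantel(d1, d2, st.StatsConfig(n_permutations=199,
                                                    seed=int(rng.integers(2 ** 31))))
            rejections += p <= 0.05
            small_r += abs(r) < 0.5
        assert rejections <= 10
        assert small_r >= 90

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(10)
        d1 = st.euclidean_distances(frame(rng, 8, 4))
        d2 = st.euclidean_distances(frame(rng, 8, 4, ids=list(d1.ids)))
        r, _ = st.mantel(d1, d2, st.StatsConfig(n_permutations=99, seed=0))
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.values, ids=d1.ids),
            skbio_distance.DistanceMatrix(d2.values, ids=d2.ids),
            method="pearson", permutations=0)
        assert r == pytest.approx(r_skbio, rel=1e-10)


class TestUnivariate:
    def test_kruskal_hand_ranked_example(self):
        h, p = st.kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9],
                                 ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert h == pytest.approx(7.2, abs=1e-9)

    def test_kruskal_all_equal_is_zero(self):
        assert st.kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"]) == (0.0, 1.0)

    def test_kruskal_invariant_to_sample_order(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=12)
        g = np.repeat(["a", "b", "c"], 4)
        h1, _ = st.kruskal_wallis(v, g)
        perm = rng.permutation(12)
        h2, _ = st.kruskal_wallis(v[perm], g[perm])
        assert h1 == pytest.approx(h2)

    def test_anova_f_near_one_under_null(self):
        rng = np.random.default_rng(12)
        fs = []
        for _ in range(500):
            v = rng.normal(size=30)
            f, _ = st.anova_oneway(v, np.repeat(["a", "b"], 15))
            fs.append(f)
        assert 0.8 <= np.mean(fs) <= 1.2

    def test_anova_detects_large_shift(self):
        rng = np.random.default_rng(13)
        v = np.concatenate([rng.normal(0, 1, 15), rng.normal(10, 1, 15)])
        _, p = st.anova_oneway(v, np.repeat(["a", "b"], 15))
        assert p < 1e-4

    def test_levene_p_uniform_under_equal_spread(self):
        rng = np.random.default_rng(14)
        ps = [st.levene(rng.normal(size=40), np.repeat(["a", "b"], 20))
              for _ in range(400)]
        ks_p = sps.kstest(ps, "uniform").pvalue
        assert ks_p > 0.01

    def test_shapiro_per_group_handles_small_groups(self):
        ps = st.shapiro_per_group([1.0, 2.0, 3.0, 4.0, 1.0, 1.5],
                                  ["a", "a", "a", "a", "b", "b"])
        assert not np.isnan(ps[0]) and np.isnan(ps[1])

    def test_kruskal_and_anova_agree_in_evidence_ranking(self):
        """On normal, equal-variance peaks the two omnibus tests order the
        evidence consistently (Spearman rho of -log p >= 0.8)."""
        rng = np.random.default_rng(15)
        kp, ap = [], []
        groups = np.repeat(["a", "b", "c"], 10)
        for shift in np.linspace(0, 2.0, 40):
            v = rng.normal(0, 1, 30)
            v[groups == "b"] += shift
            _, p1 = st.kruskal_wallis(v, groups)
            _, p2 = st.anova_oneway(v, groups)
            kp.append(p1)
            ap.append(p2)
        rho = sps.spearmanr(-np.log(kp), -np.log(ap)).statistic
        assert rho >= 0.8


class TestPosthocAndHolm:
    def test_holm_step_down_by_hand(self):
        np.testing.assert_allclose(st.holm_adjust([0.01, 0.04]), [0.02, 0.04])
        np.testing.assert_allclose(st.holm_adjust([0.04, 0.01]), [0.04, 0.02])
        np.testing.assert_allclose(st.holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(st.holm_adjust([0.3]), [0.3])

    def test_holm_matches_statsmodels_and_is_monotone(self):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(16)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 12))
            mine = st.holm_adjust(p)
            theirs = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(mine, theirs, rtol=1e-12)
            assert (mine >= p - 1e-15).all()
            # monotone with respect to the raw ordering
            order = np.argsort(p)
            assert (np.diff(mine[order]) >= -1e-15).all()

    def test_dunn_two_groups_reduces_to_rank_z_test(self):
        rng = np.random.default_rng(17)
        v = rng.normal(size=14)
        g = ["a"] * 6 + ["b"] * 8
        p_dunn = st.dunn_posthoc(v, g, holm=False).loc["a", "b"]
        # independent z computation from pooled ranks
        ranks = sps.rankdata(v)
        ra = ranks[:6].mean()
        rb = ranks[6:].mean()
        n = 14
        se = np.sqrt((n * (n + 1) / 12) * (1 / 6 + 1 / 8))
        z = (ra - rb) / se
        assert p_dunn == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-10)

    def test_dunn_holm_adjusts_over_all_pairs(self):
        rng = np.random.default_rng(18)
        v = np.concatenate([rng.normal(0, 1, 8), rng.normal(3, 1, 8),
                            rng.normal(0, 1, 8)])
        g = np.repeat(["a", "b", "c"], 8)
        raw = st.dunn_posthoc(v, g, holm=False)
        adj = st.dunn_posthoc(v, g, holm=True)
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        raw_ps = [raw.loc[x, y] for x, y in pairs]
        adj_ps = [adj.loc[x, y] for x, y in pairs]
        np.testing.assert_allclose(adj_ps, st.holm_adjust(raw_ps), rtol=1e-12)
        # symmetry
        assert adj.loc["a", "b"] == adj.loc["b", "a"]

    def test_tukey_matrix_is_symmetric_and_detects_shift(self):
        rng = np.random.default_rng(19)
        v = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                            rng.normal(0, 1, 10)])
        g = np.repeat(["a", "b", "c"], 10)
        out = st.tukey_hsd(v, g)
        assert out.loc["a", "b"] == out.loc["b", "a"]
        assert out.loc["a", "b"] < 1e-4
        assert out.loc["a", "c"] > 0.05


def test_univariate_screen_reports_all_peaks(small_dataset):
    _, table, meta, truth = small_dataset
    from volatilome import preprocess as pp

    filtered, _ = pp.preprocess(table, meta)
    screen = st.univariate_screen(filtered, meta)
    assert len(screen) == len(filtered.peaks)
    assert screen["kruskal_p"].between(0, 1).all()
    # injected species-specific peaks are overwhelmingly significant
    specific = [p for p in truth.specific if p in screen.index]
    assert (screen.loc[specific, "kruskal_p"] < 0.05).mean() > 0.9
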