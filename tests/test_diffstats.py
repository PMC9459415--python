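"""Count quantification, NB testing, classical tests and DIANA clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pausepipe.diffstats import (
    CountMatrix,
    bh_adjust,
    count_reads_in_regions,
    diana_clustering,
    kendall_distance_matrix,
    median_of_ratios,
    nb_lrt_test,
    nb_wald_test,
    two_proportion_z_test,
    wilcoxon_rank_sum,
    zscore_profiles,
)
from pausepipe.regions import GenomicInterval
from pausepipe.simulate import aging_demo_config, simulate_count_matrix


def _iv(start, end, strand=".", chrom="chr1"):
    return GenomicInterval(chrom, start, end, strand)


class TestCounting:
    def test_sense_filter(self):
        region = _iv(1000, 2000, strand="+")
        positions = [("chr1", 1100 + i, "+") for i in range(5)]
        positions += [("chr1", 1200 + i, "-") for i in range(3)]
        m = count_reads_in_regions(
            {"s1": positions}, [region], ["r0"], {"s1": "c"}, mode="five_prime_sense"
        )
        assert m.counts.loc["r0", "s1"] == 5

    def test_fragment_spanning_two_regions_counts_twice(self):
        regions = [_iv(0, 100), _iv(100, 200)]
        frags = [_iv(50, 150)]
        m = count_reads_in_regions(
            {"s1": frags}, regions, ["a", "b"], {"s1": "c"}, mode="fragment_overlap"
        )
        assert m.counts["s1"].tolist() == [1, 1]

    def test_matches_per_read_loop(self, rng):
        regions = [_iv(int(s), int(s) + 500, strand="+") for s in range(0, 5000, 1000)]
        ids = [f"r{i}" for i in range(len(regions))]
        positions = [
            ("chr1", int(p), s)
            for p, s in zip(rng.integers(0, 6000, 2000),
                            np.where(rng.random(2000) < 0.5, "+", "-"))
        ]
        m = count_reads_in_regions(
            {"s1": positions}, regions, ids, {"s1": "c"}, mode="five_prime_sense"
        )
        for region, rid in zip(regions, ids):
            expected = sum(
                1 for c, p, s in positions
                if region.start <= p < region.end and s == "+"
            )
            assert m.counts.loc[rid, "s1"] == expected


class TestSizeFactors:
    def test_closed_form_doubling(self):
        counts = pd.DataFrame({"A": [2, 4, 8], "B": [4, 8, 16]})
        sf = median_of_ratios(CountMatrix(counts, {"A": "x", "B": "y"}))
        assert sf["A"] == pytest.approx(1 / np.sqrt(2))
        assert sf["B"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [5, 9, 2], "B": [5, 9, 2]})
        sf = median_of_ratios(counts)
        assert np.allclose(sf, 1.0)

    def test_row_permutation_invariant(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(100, 4)),
                              columns=list("ABCD")) + 1
        sf1 = median_of_ratios(counts)
        sf2 = median_of_ratios(counts.sample(frac=1, random_state=1))
        pd.testing.assert_series_equal(sf1, sf2)

    def test_no_positive_row_raises(self):
        counts = pd.DataFrame({"A": [0, 1], "B": [1, 0]})
        with pytest.raises(ValueError):
            median_of_ratios(counts)

    def test_recovers_programmed_multipliers(self):
        cfg = aging_demo_config(
            seed=11, nb_effect_fraction=0.0,
            nb_size_multipliers=(1.0, 2.0, 1.0, 2.0, 1.0, 2.0),
        )
        matrix, _ = simulate_count_matrix(cfg, n_conditions=2)
        sf = median_of_ratios(matrix)
        ratios = sf.values[1::2] / sf.values[0::2]
        assert np.allclose(ratios, 2.0, rtol=0.02)


class TestNBWald:
    def test_null_poisson_type_i_error(self):
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.poisson(50, size=(2000, 6)), columns=[f"s{i}" for i in range(6)]
        )
        m = CountMatrix(counts, {f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
        res = nb_wald_test(m, ("A", "B"))
        assert 0.03 <= (res["pvalue"] < 0.05).mean() <= 0.07

    def test_null_nb_type_i_error(self):
        cfg = aging_demo_config(seed=7, nb_effect_fraction=0.0)
        matrix, _ = simulate_count_matrix(cfg, n_conditions=2)
        res = nb_wald_test(matrix, ("c1", "c2"))
        frac = (res["pvalue"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_all_zero_region_flagged(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]}
        )
        m = CountMatrix(counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        res = nb_wald_test(m, ("A", "B"))
        assert res["pvalue"].iloc[0] == 1.0
        assert res["log2FC"].iloc[0] == 0.0
        assert bool(res["all_zero"].iloc[0])

    def test_recovers_programmed_log2fc(self):
        cfg = aging_demo_config(seed=9, nb_n_regions=500, nb_effect_fraction=1.0,
                                nb_effect_log2fc=1.0)
        matrix, truth = simulate_count_matrix(cfg, n_conditions=2)
        res = nb_wald_test(matrix, ("c1", "c2"))
        signed = res["log2FC"].values * np.sign(truth["true_log2fc"].values)
        assert abs(signed.mean() - 1.0) < 0.1

    def test_single_replicate_raises(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "b2": [3]})
        m = CountMatrix(counts, {"a": "A", "b": "B", "b2": "B"})
        with pytest.raises(ValueError):
            nb_wald_test(m, ("A", "B"))


class TestNBLrt:
    def test_null_type_i_error(self):
        cfg = aging_demo_config(seed=8, nb_effect_fraction=0.0)
        matrix, _ = simulate_count_matrix(cfg, n_conditions=3)
        res = nb_lrt_test(matrix)
        assert 0.03 <= (res["pvalue"] < 0.05).mean() <= 0.07

    def test_power_for_doubled_condition(self):
        cfg = aging_demo_config(seed=10, nb_n_regions=500, nb_effect_fraction=1.0,
                                nb_effect_log2fc=1.0)
        matrix, _ = simulate_count_matrix(cfg, n_conditions=3)
        res = nb_lrt_test(matrix)
        assert (res["pvalue"] < 0.05).mean() > 0.8

    def test_constant_region_p_one(self):
        counts = pd.DataFrame(
            {f"{c}{r}": [0, 50] for c in "abc" for r in (1, 2)},
        )
        m = CountMatrix(counts, {f"{c}{r}": c for c in "abc" for r in (1, 2)})
        res = nb_lrt_test(m)
        assert res["pvalue"].iloc[0] == 1.0

    def test_two_conditions_raise(self):
        counts = pd.DataFrame({"a1": [1], "a2": [2], "b1": [1], "b2": [2]})
        m = CountMatrix(counts, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError):
            nb_lrt_test(m)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == 0.2

    def test_all_ones(self):
        assert (bh_adjust([1.0] * 5) == 1.0).all()

    def test_monotone_and_permutation_invariant(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(200)
        assert np.allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=97)
        _rej, q_sm, _a, _b = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, p = two_proportion_z_test(50, 100, 50, 100)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        z, p = two_proportion_z_test(30, 100, 70, 100)
        pooled = 0.5
        expected_z = (0.3 - 0.7) / np.sqrt(pooled * 0.5 * (0.02))
        assert z == pytest.approx(expected_z)
        assert p == pytest.approx(2 * stats.norm.sf(abs(expected_z)))

    def test_swapping_groups_flips_sign(self):
        z1, p1 = two_proportion_z_test(30, 100, 70, 100)
        z2, p2 = two_proportion_z_test(70, 100, 30, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_pooled_raises(self):
        with pytest.raises(ValueError):
            two_proportion_z_test(0, 10, 0, 10)


class TestWilcoxon:
    def test_identical_samples(self):
        _u, p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_separated_samples(self):
        _u, p = wilcoxon_rank_sum(np.arange(20) + 100.0, np.arange(20))
        assert p < 1e-6

    def test_small_samples_match_exact_enumeration(self, rng):
        """For n <= 8 without ties, compare the normal approximation to an
        exhaustive enumeration of all rank assignments."""
        for trial in range(10):
            n1, n2 = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            pooled = rng.permutation(n1 + n2).astype(float)  # distinct ranks
            x, y = pooled[:n1], pooled[n1:]
            u_obs, p_approx = wilcoxon_rank_sum(x, y)
            # exact null distribution of U over all C(n1+n2, n1) splits
            all_vals = np.sort(np.concatenate([x, y]))
            us = []
            for combo in itertools.combinations(range(n1 + n2), n1):
                xs = all_vals[list(combo)]
                u = sum(np.sum(xs_i > all_vals[~np.isin(range(n1 + n2), combo)])
                        for xs_i in xs)
                us.append(u)
            us = np.asarray(us, dtype=float)
            mean_u = n1 * n2 / 2
            p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u))
            assert abs(p_approx - p_exact) < 0.06


class TestKendall:
    def test_identical_profiles_zero_distance(self):
        profiles = pd.DataFrame([[1, 2, 3], [10, 20, 30]], index=["a", "b"])
        d = kendall_distance_matrix(profiles)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_reversed_profiles_distance_two(self):
        profiles = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["a", "b"])
        d = kendall_distance_matrix(profiles)
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_constant_profile_excluded(self):
        profiles = pd.DataFrame([[1, 2, 3], [5, 5, 5]], index=["a", "b"])
        d = kendall_distance_matrix(profiles)
        assert list(d.index) == ["a"]

    def test_matches_pair_enumeration_oracle(self, rng):
        """tau_b re-derived by explicit concordance counting."""
        profiles = pd.DataFrame(
            rng.integers(0, 5, size=(6, 7)).astype(float),
            index=[f"g{i}" for i in range(6)],
        )
        profiles = profiles.loc[profiles.std(axis=1) > 0]
        d = kendall_distance_matrix(profiles)
        values = profiles.values
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                x, y = values[i], values[j]
                nc = nd = tx = ty = 0
                for a, b in itertools.combinations(range(len(x)), 2):
                    dx, dy = x[a] - x[b], y[a] - y[b]
                    if dx == 0 and dy == 0:
                        continue
                    if dx == 0:
                        tx += 1
                    elif dy == 0:
                        ty += 1
                    elif dx * dy > 0:
                        nc += 1
                    else:
                        nd += 1
                denom = np.sqrt((nc + nd + tx) * (nc + nd + ty))
                tau = (nc - nd) / denom
                assert d.iloc[i, j] == pytest.approx(1 - tau)


class TestDiana:
    def _blob_distances(self, rng):
        a = rng.normal(0, 0.3, size=(5, 3))
        b = rng.normal(5, 0.3, size=(5, 3)) * np.array([1, -1, 1])
        points = np.vstack([a, b])
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        return pd.DataFrame(d, index=[f"p{i}" for i in range(10)],
                            columns=[f"p{i}" for i in range(10)])

    def test_two_blobs_split_perfectly(self, rng):
        d = self._blob_distances(rng)
        labels = diana_clustering(d, k=2)
        assert len(set(labels.iloc[:5])) == 1
        assert len(set(labels.iloc[5:])) == 1
        assert labels.iloc[0] != labels.iloc[9]

    def test_k_equals_n_gives_singletons(self, rng):
        d = self._blob_distances(rng)
        labels = diana_clustering(d, k=10)
        assert labels.nunique() == 10

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            diana_clustering(self._blob_distances(rng), k=11)

    def test_first_split_matches_naive_splinter_oracle(self, rng):
        """Independent plain-loop implementation of the splinter procedure
        reproduces the first division on small instances."""
        for trial in range(5):
            n = 8
            pts = rng.normal(size=(n, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = pd.DataFrame(d, index=range(n), columns=range(n))
            labels = diana_clustering(dm, k=2)
            got = frozenset(np.where(labels.values == labels.values[0])[0])

            # oracle: textbook splinter procedure, written independently
            avg = [sum(d[i][j] for j in range(n) if j != i) / (n - 1) for i in range(n)]
            seed = avg.index(max(avg))
            splinter, rest = {seed}, set(range(n)) - {seed}
            while len(rest) > 1:
                best, who = 0.0, None
                for i in sorted(rest):
                    a = sum(d[i][j] for j in rest if j != i) / (len(rest) - 1)
                    b = sum(d[i][j] for j in splinter) / len(splinter)
                    if a - b > best:
                        best, who = a - b, i
                if who is None:
                    break
                splinter.add(who)
                rest.remove(who)
            oracle = {frozenset(splinter), frozenset(rest)}
            assert got in oracle

    def test_deterministic(self, rng):
        d = self._blob_distances(rng)
        l1 = diana_clustering(d, k=3)
        l2 = diana_clustering(d.copy(), k=3)
        pd.testing.assert_series_equal(l1, l2)


class TestZscore:
    def test_basic_example(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        z = zscore_profiles(profiles)
        np.testing.assert_allclose(z.values[0], [-1, 0, 1])

    def test_constant_row_excluded(self):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]], index=["a", "b"])
        assert list(zscore_profiles(profiles).index) == ["a"]

    def test_rows_standardized(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(20, 5)))
        z = zscore_profiles(profiles)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)
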