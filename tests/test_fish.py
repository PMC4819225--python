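"""FISH distance scoring, association calls and the screen's statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gfap4c.config import SyntheticConfig
from gfap4c.fish import (
    allele_activity_association,
    anova_oneway,
    association_frequencies,
    call_association,
    chisq_residual_test,
    fisher_exact_2x2,
    ks_two_sample,
    min_pair_distance,
    pair_distances,
    triple_colocalization,
)
from gfap4c.synthetic import simulate_fish
from conftest import small_config


def signals_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "condition", "gene", "allele",
                 "x_um", "y_um", "z_um"],
    )


class TestDistances:
    def test_euclidean(self):
        assert min_pair_distance([[0, 0, 0]], [[0.3, 0, 0]]) == pytest.approx(0.3)

    def test_min_over_alleles(self):
        a = [[0, 0, 0], [1.0, 0, 0]]
        b = [[1.2, 0, 0]]
        assert min_pair_distance(a, b) == pytest.approx(0.2)

    def test_symmetry_and_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            a = rng.normal(size=(2, 3))
            b = rng.normal(size=(2, 3))
            d = min_pair_distance(a, b)
            assert d == pytest.approx(min_pair_distance(b, a))
            brute = min(
                np.sqrt(((p - q) ** 2).sum()) for p in a for q in b
            )
            assert d == pytest.approx(brute)

    def test_missing_gene_skipped(self, caplog):
        rows = [
            ("n1", "LIF+", "A", 1, 0, 0, 0),
            ("n1", "LIF+", "B", 1, 0.1, 0, 0),
            ("n2", "LIF+", "A", 1, 0, 0, 0),  # no B signal
        ]
        d = pair_distances(signals_frame(rows), "A", "B")
        assert list(d["nucleus_id"]) == ["n1"]


class TestAssociationCall:
    @pytest.mark.parametrize(
        "distance,expected", [(0.499, True), (0.5, True), (0.501, False)]
    )
    def test_threshold_inclusive(self, distance, expected):
        assert call_association(distance) is expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            call_association(-0.1)


class TestFrequencies:
    def test_all_associated(self):
        rows = []
        for i in range(5):
            rows += [
                (f"n{i}", "LIF+", "A", 1, 0, 0, 0),
                (f"n{i}", "LIF+", "B", 1, 0.2, 0, 0),
            ]
        freq, table = association_frequencies(signals_frame(rows), "A", "B")
        assert freq["fraction"].iloc[0] == 1.0
        assert table.loc["not_associated", "LIF+"] == 0

    def test_column_sums_equal_nucleus_counts(self):
        cfg = small_config(n_nuclei=30)
        ds = simulate_fish(cfg, [("A", "B")])
        freq, table = association_frequencies(ds.signals, "A", "B")
        for _, row in freq.iterrows():
            assert table[row["condition"]].sum() == row["n_total"]

    def test_planted_fraction_recovered_within_binomial_error(self):
        cfg = small_config(n_nuclei=400, seed=5)
        ds = simulate_fish(
            cfg, [("A", "B")], assoc_fraction={"LIF+": 0.5}, conditions=("LIF+",)
        )
        freq, _ = association_frequencies(ds.signals, "A", "B")
        se = np.sqrt(0.5 * 0.5 / 400)
        # chance proximity only adds to the planted fraction
        assert freq["fraction"].iloc[0] == pytest.approx(0.5, abs=3 * se + 0.01)


class TestChiSquaredResiduals:
    def test_independence_gives_zero(self):
        res = chisq_residual_test([[10, 20], [10, 20]])
        assert res.chi2 == pytest.approx(0.0)
        assert np.allclose(res.adjusted_residuals, 0.0)

    def test_hand_computed_2x2(self):
        # margins 30/30 and 30/30 -> E = 15 everywhere
        res = chisq_residual_test([[10, 20], [20, 10]])
        assert res.chi2 == pytest.approx(4 * 25 / 15)
        assert res.df == 1

    def test_residual_signs(self):
        res = chisq_residual_test([[10, 20], [20, 10]])
        assert res.adjusted_residuals[0, 0] < 0
        assert res.adjusted_residuals[0, 1] > 0

    def test_matches_direct_arithmetic_oracle_on_random_tables(self):
        rng = np.random.default_rng(61)
        for _ in range(100):
            r, c = rng.integers(2, 4, size=2)
            obs = rng.integers(1, 40, size=(r, c)).astype(float)
            res = chisq_residual_test(obs)
            row, col, n = obs.sum(1), obs.sum(0), obs.sum()
            chi2 = 0.0
            for i in range(r):
                for j in range(c):
                    e = row[i] * col[j] / n
                    chi2 += (obs[i, j] - e) ** 2 / e
                    adj = (obs[i, j] - e) / np.sqrt(
                        e * (1 - row[i] / n) * (1 - col[j] / n)
                    )
                    assert res.adjusted_residuals[i, j] == pytest.approx(adj)
            assert res.chi2 == pytest.approx(chi2)
            assert res.p == pytest.approx(
                float(stats.chi2.sf(chi2, (r - 1) * (c - 1)))
            )

    def test_permutation_invariance(self):
        obs = np.array([[5, 9, 2], [7, 3, 11]], dtype=float)
        base = chisq_residual_test(obs).chi2
        assert chisq_residual_test(obs[:, ::-1]).chi2 == pytest.approx(base)
        assert chisq_residual_test(obs[::-1, :]).chi2 == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_residual_test([[0, 0], [5, 5]])


def hypergeom_enumeration_p(table) -> float:
    """Independent oracle: two-sided Fisher p by exhaustive enumeration of
    tables with the observed margins, via log-factorials."""
    a, b, c, d = np.asarray(table, dtype=int).ravel()
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    # lf[k] = log k!
    lf = np.cumsum(np.concatenate([[0.0], np.log(np.arange(1, n + 1))]))

    def logp(k):
        return (
            lf[r1] + lf[r2] + lf[c1] + lf[n - c1] - lf[n]
            - lf[k] - lf[r1 - k] - lf[c1 - k] - lf[r2 - c1 + k]
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    probs = np.exp([logp(k) for k in ks])
    p_obs = np.exp(logp(a))
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


class TestFisher:
    def test_symmetric_table_p_one(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_extreme_table_minimal_p(self):
        n = 8
        _, p_extreme = fisher_exact_2x2([[0, n], [n, 0]])
        assert p_extreme == pytest.approx(
            hypergeom_enumeration_p([[0, n], [n, 0]])
        )
        _, p_mild = fisher_exact_2x2([[3, 5], [5, 3]])
        assert p_extreme < p_mild

    def test_haldane_corrected_odds_ratio(self):
        orat, _ = fisher_exact_2x2([[0, 5], [5, 5]])
        assert orat == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_shape_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(88)
        for _ in range(60):
            table = rng.integers(0, 15, size=(2, 2))
            if table.sum() == 0:
                continue
            _, p = fisher_exact_2x2(table)
            assert p == pytest.approx(hypergeom_enumeration_p(table), rel=1e-8)


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            a = rng.normal(size=12)
            b = rng.normal(0.5, 1.2, size=15)
            f, df1, df2, p_f = anova_oneway(a, b)
            t, p_t = stats.ttest_ind(a, b)
            assert f == pytest.approx(t**2)
            assert p_f == pytest.approx(p_t)
            assert (df1, df2) == (1, 25)

    def test_mirrored_groups_not_significant(self):
        a = np.array([9.0, 10.0, 11.0, 10.5, 9.5])
        b = a.copy()
        f, _, _, p = anova_oneway(a, b)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_published_diameter_spread_usually_not_significant(self):
        """Groups drawn at the published per-condition nuclear diameters
        (10.4/10.1/10.2 um, sd ~1.2) rarely differ significantly."""
        rng = np.random.default_rng(30)
        rejections = 0
        for _ in range(50):
            groups = [
                rng.normal(m, 1.2, size=30) for m in (10.4, 10.1, 10.2)
            ]
            _, _, _, p = anova_oneway(*groups)
            rejections += p < 0.05
        assert rejections <= 15

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([2.0, 2.0], [2.0, 2.0])


class TestAlleleActivity:
    def test_active_alleles_preferentially_associated(self):
        cfg = small_config(n_nuclei=200, seed=8)
        ds = simulate_fish(
            cfg, [("Gfap", "Ogn")],
            conditions=("LIF+",),
            activity=True,
            active_assoc_fraction={"LIF+": 0.6},
        )
        table, (orat, p) = allele_activity_association(ds.signals, "Gfap", "Ogn")
        assert table.to_numpy().sum() == 2 * 200
        assert orat > 1.0
        assert p < 0.01

    def test_shuffled_labels_null_odds_ratio(self):
        cfg = small_config(n_nuclei=150, seed=9)
        ds = simulate_fish(
            cfg, [("Gfap", "Ogn")], conditions=("LIF+",), activity=True,
            active_assoc_fraction={"LIF+": 0.7},
        )
        rng = np.random.default_rng(2)
        signals = ds.signals.copy()
        bait_mask = signals["gene"] == "Gfap"
        log_ors = []
        for _ in range(200):
            shuffled = signals.copy()
            labels = shuffled.loc[bait_mask, "active"].to_numpy().copy()
            rng.shuffle(labels)
            shuffled.loc[bait_mask, "active"] = labels
            _, (orat, _) = allele_activity_association(shuffled, "Gfap", "Ogn")
            log_ors.append(np.log(orat))
        assert abs(np.mean(log_ors)) < 0.25

    def test_missing_labels_rejected(self):
        rows = [("n1", "LIF+", "Gfap", 1, 0, 0, 0)]
        with pytest.raises(ValueError):
            allele_activity_association(signals_frame(rows), "Gfap", "Ogn")


class TestTriple:
    def test_mutually_close_positive(self):
        rows = [
            ("n1", "LIF+", "A", 1, 0, 0, 0),
            ("n1", "LIF+", "B", 1, 0.1, 0, 0),
            ("n1", "LIF+", "C", 1, 0, 0.1, 0),
        ]
        frac, n = triple_colocalization(signals_frame(rows), ("A", "B", "C"))
        assert (frac, n) == (1.0, 1)

    def test_one_far_negative(self):
        rows = [
            ("n1", "LIF+", "A", 1, 0, 0, 0),
            ("n1", "LIF+", "B", 1, 0.1, 0, 0),
            ("n1", "LIF+", "C", 1, 3.0, 0, 0),
        ]
        frac, _ = triple_colocalization(signals_frame(rows), ("A", "B", "C"))
        assert frac == 0.0

    def test_triple_bounded_by_pairwise(self):
        cfg = small_config(n_nuclei=100, seed=4)
        ds = simulate_fish(cfg, [("A", "B"), ("A", "C")], conditions=("LIF+",))
        frac, _ = triple_colocalization(ds.signals, ("A", "B", "C"))
        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            freq, _ = association_frequencies(ds.signals, *pair)
            assert frac <= freq["fraction"].iloc[0] + 1e-12
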