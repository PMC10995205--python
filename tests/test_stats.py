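import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import magniche.stats as st
from magniche.io import FeatureMatrix, SchemaError


def bh_brute_force(p):
    """Independent step-up definition: sort ascending, adj_(i) = min over the
    tail of m * p_(j) / j, capped at 1, returned in input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def fisher_two_sided_enumeration(a, b, c, d):
    """Sum of hypergeometric point probabilities <= the observed table's."""
    n1, n2, k = a + b, c + d, a + c

    def point(x):
        return (
            math.comb(n1, x) * math.comb(n2, k - x) / math.comb(n1 + n2, k)
        )

    p_obs = point(a)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = point(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            st.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert st.benjamini_hochberg([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(st.benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.benjamini_hochberg([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            p = rng.uniform(0, 1, n)
            np.testing.assert_allclose(
                st.benjamini_hochberg(p), bh_brute_force(p), atol=1e-12
            )

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 100)
        adj = st.benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()


class TestKruskalWallis:
    def test_closed_form_two_groups(self):
        res = st.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(3.857, abs=5e-4)

    def test_identical_groups(self):
        res = st.kruskal_wallis([1.0, 2.0], [1.0, 2.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.raw_p == pytest.approx(1.0)

    def test_tie_correction_matches_rank_formula(self, rng):
        """Brute-force tie-corrected H from the rank definition."""
        for _ in range(20):
            g1 = rng.integers(0, 5, size=int(rng.integers(3, 10))).astype(float)
            g2 = rng.integers(0, 5, size=int(rng.integers(3, 10))).astype(float)
            pooled = np.concatenate([g1, g2])
            ranks = scipy.stats.rankdata(pooled)
            n = len(pooled)
            r1, r2 = ranks[: len(g1)], ranks[len(g1):]
            h = (12 / (n * (n + 1))) * (
                r1.sum() ** 2 / len(g1) + r2.sum() ** 2 / len(g2)
            ) - 3 * (n + 1)
            _, counts = np.unique(pooled, return_counts=True)
            tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
            if tie == 0:
                continue
            h /= tie
            res = st.kruskal_wallis(g1, g2)
            assert res.statistic == pytest.approx(h, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            st.kruskal_wallis([1.0, 2.0], [])


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 0, 0, 10), 2 / 184756),  # complete separation, 10 vs 10
            ((3, 1, 1, 3), 34 / 70),  # tables with point prob <= observed
        ],
    )
    def test_enumeration_values(self, table, expected):
        a, b, c, d = table
        p, _ = st.fisher_exact_two_sided(np.array([[a, b], [c, d]]))
        assert p == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d), rel=1e-9
        )
        assert p == pytest.approx(expected, rel=1e-9)

    def test_equal_proportions_p_one(self):
        p, _ = st.fisher_exact_two_sided(np.array([[5, 5], [5, 5]]))
        assert p == pytest.approx(1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            st.fisher_exact_two_sided(np.array([[1, -1], [0, 2]]))


class TestFisherEnrichment:
    def _features(self, presence, mag_ids):
        return FeatureMatrix(
            counts=pd.DataFrame(presence, index=mag_ids,
                                columns=[f"K{i:05d}" for i in range(presence.shape[1])]),
            namespace="KO",
        )

    def test_planted_feature_significant(self):
        mags = [f"h{i}" for i in range(20)] + [f"s{i}" for i in range(20)]
        labels = pd.Series(
            ["host_specific"] * 20 + ["seawater_specific"] * 20, index=mags
        )
        presence = np.zeros((40, 3), dtype=int)
        presence[:20, 0] = 1  # perfectly separating feature
        presence[:, 1] = 1  # uninformative
        enr = st.fisher_enrichment(self._features(presence, mags), labels)
        row = enr.set_index("feature_id").loc["K00000"]
        assert row["raw_p"] < 1e-8
        assert row["direction"] == "host_specific"
        # feature absent everywhere is skipped
        assert "K00002" not in set(enr["feature_id"])

    def test_too_few_mags_rejected(self):
        labels = pd.Series(["host_specific", "seawater_specific"], index=["a", "b"])
        fm = self._features(np.ones((2, 2), dtype=int), ["a", "b"])
        with pytest.raises(SchemaError):
            st.fisher_enrichment(fm, labels)

    def test_null_generator_controls_fdr(self):
        """With no planted enrichment, BH at 0.05 yields few discoveries."""
        import magniche as mg

        discoveries, n_features = 0, 0
        for seed in range(8):
            design = mg.SimulationDesign(
                seed=seed,
                n_enriched={"KO": 0, "Pfam": 0, "CAZy": 0},
                n_features={"KO": 120, "Pfam": 0, "CAZy": 0},
            )
            study = mg.generate_study(design)
            labels = pd.Series(study.truth.labels)
            enr = st.fisher_enrichment(study.annotations["KO"], labels)
            discoveries += int((enr["adjusted_p"] <= 0.05).sum())
            n_features += len(enr)
        assert discoveries / n_features <= 0.02  # BH on a global null is conservative


class TestMannWhitney:
    def test_exact_separated_3v3(self):
        u, p = st.mann_whitney_u([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])
        assert u == 9.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme

    def test_identical_distributions_p_one(self):
        _, p = st.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 7)))
            y = rng.normal(size=int(rng.integers(3, 7)))
            _, p = st.mann_whitney_u(x, y)
            _, p_ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_enumeration_with_ties_matches_permutation_null(self, rng):
        """With ties the exact p equals the fraction of label assignments with
        |U - n1 n2 / 2| at least as large as observed."""
        for _ in range(10):
            x = rng.integers(0, 4, 5).astype(float)
            y = rng.integers(0, 4, 5).astype(float)
            u, p = st.mann_whitney_u(x, y)
            pooled = np.concatenate([x, y])
            ranks = scipy.stats.rankdata(pooled)
            mu = len(x) * len(y) / 2
            obs = abs(u - mu)
            hits = sum(
                abs(ranks[list(idx)].sum() - len(x) * (len(x) + 1) / 2 - mu) >= obs - 1e-9
                for idx in itertools.combinations(range(10), 5)
            )
            assert p == pytest.approx(hits / math.comb(10, 5), abs=1e-12)


class TestWeightedClusterEnrichment:
    def test_weights_and_separation(self, default_study, default_abundance):
        study = default_study
        res = st.weighted_cluster_enrichment(
            study.clusters, default_abundance, study.samples, factor="wq_category"
        )
        assert len(res) > 0
        assert ((res["raw_p"] >= 0) & (res["raw_p"] <= 1)).all()
        assert (res["adjusted_p"] >= res["raw_p"] - 1e-12).all()
        pairs = set(zip(res["category_1"], res["category_2"]))
        assert all(c1 < c2 for c1, c2 in pairs)

    def test_all_zero_cluster_skipped(self, default_study, default_abundance):
        counts = default_study.clusters.counts.copy()
        counts["CL_zero"] = 0
        fm = FeatureMatrix(counts=counts, namespace="cluster")
        res = st.weighted_cluster_enrichment(
            fm, default_abundance, default_study.samples, factor="wq_category"
        )
        assert "CL_zero" not in set(res["cluster_id"])
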