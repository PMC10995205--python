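import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance as ssd

import magniche.ordination as ord_
from conftest import make_distance
from magniche.io import SchemaError


def frame(arr, prefix="s"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"m{j}" for j in range(arr.shape[1])],
    )


class TestHellinger:
    def test_hand_values(self):
        out = ord_.hellinger(frame([[1, 1, 2]]))
        np.testing.assert_allclose(out.iloc[0], [0.5, 0.5, np.sqrt(0.5)])

    def test_single_taxon_sample(self):
        out = ord_.hellinger(frame([[7.0]]))
        assert out.iloc[0, 0] == 1.0

    def test_unit_squared_row_sums_random(self, rng):
        x = frame(rng.uniform(0, 10, (15, 40)))
        out = ord_.hellinger(x)
        np.testing.assert_allclose((out**2).sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_sample_names_offender(self):
        with pytest.raises(SchemaError, match="s1"):
            ord_.hellinger(frame([[1, 2], [0, 0]]))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        d = ord_.bray_curtis(frame([[1, 2, 0], [1, 2, 0], [0, 0, 5]]))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_hand_value(self):
        d = ord_.bray_curtis(frame([[1, 2], [2, 1]]))
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_binary_equals_sorensen(self, rng):
        x = (rng.uniform(0, 1, (8, 30)) > 0.5) * rng.uniform(0.1, 5, (8, 30))
        d = ord_.bray_curtis(frame(x), binary=True)
        b = (x > 0).astype(float)
        for i, j in itertools.combinations(range(8), 2):
            a = np.logical_and(b[i], b[j]).sum()
            expected = 1 - 2 * a / (b[i].sum() + b[j].sum())
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_zero_one(self, rng):
        d = ord_.bray_curtis(frame(rng.uniform(0, 5, (10, 20))))
        assert (d.values >= 0).all() and (d.values <= 1 + 1e-12).all()


class TestPcoa:
    def test_reconstructs_euclidean_distances(self, rng):
        pts = rng.normal(size=(6, 3))
        d = make_distance(pts)
        res = ord_.pcoa(d)
        rec = ssd.squareform(ssd.pdist(res.scores.to_numpy()))
        np.testing.assert_allclose(rec, d.values, atol=1e-9)

    def test_eigenvalue_sum_gower_identity(self, rng):
        pts = rng.normal(size=(7, 4))
        d = make_distance(pts)
        res = ord_.pcoa(d)
        n = 7
        g_trace = (-0.5 * d.values**2).trace() - (-0.5 * d.values**2).sum() / n
        # trace of centered G equals sum of all eigenvalues (negatives included)
        assert res.eigenvalues.sum() + res.negative_eigenvalues.sum() == pytest.approx(
            g_trace, abs=1e-8
        )

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        x = rng.uniform(0, 5, (9, 25))
        d = ord_.bray_curtis(frame(x))
        res = ord_.pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.ids), method="eigh"
        )
        ref_pos = np.array([e for e in ref.eigvals if e > 1e-9])
        np.testing.assert_allclose(res.eigenvalues, ref_pos[: len(res.eigenvalues)],
                                   atol=1e-8)

    def test_too_few_samples_rejected(self):
        d = make_distance(np.zeros((2, 2)))
        with pytest.raises(SchemaError):
            ord_.pcoa(d)


class TestDbrda:
    def test_inertia_conservation_random(self, rng):
        for _ in range(10):
            x = rng.uniform(0, 5, (12, 30))
            d = ord_.bray_curtis(frame(x))
            factor = pd.Series(
                rng.choice(["a", "b", "c"], 12), index=d.ids
            )
            res = ord_.dbrda(d, factor)
            total = ord_.pcoa(d).eigenvalues.sum()
            assert res.constrained_inertia + res.unconstrained_inertia == pytest.approx(
                total, abs=1e-8
            )
            assert res.n_constrained_axes <= factor.nunique() - 1

    def test_separated_clusters_capture_inertia(self, rng):
        a = rng.normal(0, 0.05, (6, 10)) + 1
        b = rng.normal(0, 0.05, (6, 10)) + 10
        x = np.vstack([a, b])
        d = make_distance(x)
        factor = pd.Series(["g1"] * 6 + ["g2"] * 6, index=d.ids)
        res = ord_.dbrda(d, factor)
        frac = res.constrained_inertia / (res.constrained_inertia + res.unconstrained_inertia)
        assert frac > 0.95

    def test_constant_factor_rejected(self, rng):
        d = make_distance(rng.normal(size=(5, 2)))
        with pytest.raises(SchemaError):
            ord_.dbrda(d, pd.Series(["x"] * 5, index=d.ids))

    def test_numeric_constraint_matrix(self, rng):
        pts = rng.normal(size=(10, 3))
        d = make_distance(pts)
        env = pd.DataFrame(
            rng.normal(size=(10, 2)), index=d.ids, columns=["v1", "v2"]
        )
        res = ord_.dbrda(d, env)
        assert res.n_constrained_axes <= 2
        total = ord_.pcoa(d).eigenvalues.sum()
        assert res.constrained_inertia + res.unconstrained_inertia == pytest.approx(
            total, abs=1e-8
        )


def _independent_pseudo_f(d, labels):
    """Text-book PERMANOVA partition, written independently of the package."""
    labels = np.asarray(labels)
    n = len(labels)
    ss_t = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        if len(idx) < 2:
            continue
        ss_w += sum(
            d[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    a = len(set(labels))
    return ((ss_t - ss_w) / (a - 1)) / (ss_w / (n - a))


class TestPermanova:
    def test_statistic_matches_independent_formula(self, rng):
        pts = rng.normal(size=(12, 3))
        d = make_distance(pts)
        labels = pd.Series(rng.choice(["x", "y", "z"], 12), index=d.ids)
        res = ord_.permanova_test(d, labels, n_perm=99, seed=1)
        assert res.pseudo_F == pytest.approx(
            _independent_pseudo_f(d.values, labels.to_numpy()), abs=1e-10
        )

    def test_statistic_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.normal(size=(14, 4))
        d = make_distance(pts)
        labels = pd.Series(rng.choice(["x", "y"], 14), index=d.ids)
        res = ord_.permanova_test(d, labels, n_perm=9, seed=1)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, ids=d.ids), labels.to_numpy(), permutations=9
        )
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_exhaustive_enumeration_3v3(self, rng):
        """Exact p over all 20 distinct 3+3 partitions equals independent
        brute force."""
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(3, 1, (3, 2))])
        d = make_distance(pts)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=d.ids)
        res = ord_.permanova_exhaustive(d, labels)
        f_obs = _independent_pseudo_f(d.values, labels.to_numpy())
        hits, total = 0, 0
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            if _independent_pseudo_f(d.values, lab) >= f_obs - 1e-12:
                hits += 1
            total += 1
        assert total == 20
        assert res.p_value == pytest.approx(hits / 20)

    def test_minimum_p_floor(self, rng):
        # unbalanced well-separated groups: permutation p hits 1/(n_perm+1);
        # balanced groups would hit 2/(n_perm+1) via the mirror labelling
        pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(50, 0.1, (8, 2))])
        d = make_distance(pts)
        labels = pd.Series(["a"] * 4 + ["b"] * 8, index=d.ids)
        res = ord_.permanova_test(d, labels, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seeded_reproducibility(self, rng):
        pts = rng.normal(size=(10, 2))
        d = make_distance(pts)
        labels = pd.Series(rng.choice(["a", "b"], 10), index=d.ids)
        r1 = ord_.permanova_test(d, labels, n_perm=199, seed=42)
        r2 = ord_.permanova_test(d, labels, n_perm=199, seed=42)
        assert r1 == r2


class TestEnvfit:
    def _ord(self, rng, n=20):
        pts = rng.normal(size=(n, 4))
        return ord_.pcoa(make_distance(pts))

    def test_axis_variable_r2_one(self, rng):
        res = self._ord(rng)
        v = pd.DataFrame({"ax1": res.scores.iloc[:, 0]}, index=res.scores.index)
        fit = ord_.envfit(res, v, n_perm=99, seed=0)
        assert fit.iloc[0]["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_diagonal_variable_direction(self, rng):
        res = self._ord(rng)
        v = pd.DataFrame(
            {"diag": res.scores.iloc[:, 0] + res.scores.iloc[:, 1]},
            index=res.scores.index,
        )
        fit = ord_.envfit(res, v, n_perm=9, seed=0)
        # direction cosines proportional to the axis standard deviations,
        # here recovered by least squares; equal-weight composite aligns with
        # (1,1)/sqrt(2) after correcting for axis scale
        s = res.scores.iloc[:, :2].to_numpy()
        b, *_ = np.linalg.lstsq(s - s.mean(0), v["diag"] - v["diag"].mean(), rcond=None)
        expect = b / np.linalg.norm(b)
        got = fit.iloc[0][["axis1", "axis2"]].to_numpy(float)
        np.testing.assert_allclose(np.abs(got), np.abs(expect), atol=1e-10)

    def test_constant_variable_skipped(self, rng):
        res = self._ord(rng)
        v = pd.DataFrame({"const": np.ones(20)}, index=res.scores.index)
        fit = ord_.envfit(res, v, n_perm=9, seed=0)
        assert len(fit) == 0

    def test_missing_values_excluded_pairwise(self, rng):
        res = self._ord(rng)
        vals = res.scores.iloc[:, 0].to_numpy().copy()
        vals[:3] = np.nan
        v = pd.DataFrame({"partial": vals}, index=res.scores.index)
        fit = ord_.envfit(res, v, n_perm=9, seed=0)
        assert fit.iloc[0]["r_squared"] == pytest.approx(1.0, abs=1e-10)


class TestPairwisePosthoc:
    def test_identical_distributions_large_p(self, rng):
        scores = pd.DataFrame(
            np.tile(rng.normal(size=(5, 2)), (2, 1)),
            index=[f"s{i}" for i in range(10)], columns=["A1", "A2"],
        )
        factor = pd.Series(["a"] * 5 + ["b"] * 5, index=scores.index)
        res = ord_.pairwise_posthoc(scores, factor, n_perm=199, seed=0)
        assert res.iloc[0]["raw_p"] > 0.5

    def test_separated_pair_has_smallest_p(self, rng):
        blocks = [rng.normal(loc, 0.3, (5, 2)) for loc in (0, 0.5, 1.0, 12.0)]
        scores = pd.DataFrame(
            np.vstack(blocks), index=[f"s{i}" for i in range(20)], columns=["A1", "A2"]
        )
        factor = pd.Series(
            ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5, index=scores.index
        )
        res = ord_.pairwise_posthoc(scores, factor, n_perm=199, seed=0)
        res = res.set_index(["level_1", "level_2"])
        d_pairs = [p for p in res.index if "d" in p]
        assert min(res.loc[d_pairs, "adjusted_p"]) <= res["adjusted_p"].min() + 1e-12

    def test_p_floor_with_999_permutations(self, rng):
        scores = pd.DataFrame(
            np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(30, 0.1, (8, 2))]),
            index=[f"s{i}" for i in range(12)], columns=["A1", "A2"],
        )
        factor = pd.Series(["a"] * 4 + ["b"] * 8, index=scores.index)
        res = ord_.pairwise_posthoc(scores, factor, n_perm=999, seed=0)
        assert res.iloc[0]["raw_p"] == pytest.approx(1 / 1000)


class TestPreprocessEnv:
    def test_duplicate_column_removed(self, rng):
        v = rng.normal(size=15)
        env = pd.DataFrame({"a": v, "b": v * 1.0, "c": rng.normal(size=15)})
        out, removed = ord_.preprocess_env(env)
        assert list(out.columns) == ["a", "c"]
        assert removed[0]["variable"] == "b" and removed[0]["partner"] == "a"

    def test_boundary_correlation_retained(self, rng):
        # construct a pair with |r| = 0.69 exactly: strict > keeps both
        n = 200
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        r_target = 0.69
        y = r_target * (x - x.mean()) / x.std() + math.sqrt(1 - r_target**2) * (
            (e - e.mean()) / e.std()
        )
        # orthogonalize the residual part exactly
        xs = (x - x.mean()) / x.std()
        es = e - np.dot(e, xs) / np.dot(xs, xs) * xs
        es = (es - es.mean()) / es.std()
        y = r_target * xs + math.sqrt(1 - r_target**2) * es
        env = pd.DataFrame({"x": xs, "y": y})
        assert abs(np.corrcoef(xs, y)[0, 1]) == pytest.approx(0.69, abs=1e-12)
        out, removed = ord_.preprocess_env(env)
        assert list(out.columns) == ["x", "y"] and removed == []

    def test_standardization_identities(self, rng):
        env = pd.DataFrame(rng.normal(5, 3, size=(30, 4)), columns=list("abcd"))
        out, _ = ord_.preprocess_env(env)
        assert np.abs(out.mean()).max() < 1e-12
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-12)

    def test_zero_variance_removed_with_log(self):
        env = pd.DataFrame({"flat": [1.0] * 5, "ok": [1, 2, 3, 4, 5.0]})
        out, removed = ord_.preprocess_env(env)
        assert list(out.columns) == ["ok"]
        assert removed[0]["reason"] == "zero_variance"


def test_hellinger_bray_pipeline_scale_invariant(rng):
    """Rescaling any sample's raw abundances leaves Hellinger + Bray-Curtis
    distances unchanged."""
    x = rng.uniform(0, 10, (8, 20))
    d1 = ord_.bray_curtis(ord_.hellinger(frame(x)))
    x2 = x.copy()
    x2[3] *= 17.0
    d2 = ord_.bray_curtis(ord_.hellinger(frame(x2)))
    np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)
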