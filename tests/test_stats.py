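import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import conngrad as cg
from conngrad.stats import EffectMap, _random_rotation, build_design, hotelling_t2

from conftest import covariates_frame


def brute_force_bh(p, alpha=0.05):
    """Step-up procedure written straight from its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = ranked * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest p downward
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def make_effect_map(t2, p, alpha=0.05):
    q, sig = cg.fdr_bh(p, alpha)
    return EffectMap(
        t2=np.asarray(t2, float),
        f=np.asarray(t2, float),
        p=np.asarray(p, float),
        q=q,
        significant=sig,
        df=(3, 50),
        alpha=alpha,
    )


class TestHotelling:
    @pytest.mark.parametrize("seed", range(50))
    def test_univariate_reduces_to_pooled_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 20, size=2)
        y1, y2 = rng.normal(size=n1), rng.normal(1.0, 2.0, size=n2)
        y = np.concatenate([y1, y2])[:, None]
        x = np.column_stack(
            [np.ones(n1 + n2), np.r_[np.ones(n1), np.zeros(n2)]]
        )
        t2, f, p, df = hotelling_t2(y, x, np.array([0.0, 1.0]))
        t_stat, t_p = sps.ttest_ind(y1, y2)
        assert t2 == pytest.approx(t_stat**2, abs=1e-10)
        assert p == pytest.approx(t_p, abs=1e-10)

    def test_monotone_t2_to_p(self):
        rng = np.random.default_rng(0)
        aligned = rng.normal(size=(40, 30, 3))
        cov = pd.DataFrame(
            {
                "group": ["case"] * 20 + ["control"] * 20,
                "age": rng.uniform(8, 30, 40),
                "sex": rng.choice(["M", "F"], 40),
                "site": rng.choice(["a", "b"], 40),
            }
        )
        eff = cg.fit_mglm(aligned, cov)
        order = np.argsort(eff.t2)
        assert np.all(np.diff(eff.p[order]) <= 1e-12)
        assert np.all(eff.t2 >= 0)

    def test_subject_order_and_site_reference_invariance(self):
        rng = np.random.default_rng(1)
        n = 36
        aligned = rng.normal(size=(n, 10, 3))
        cov = pd.DataFrame(
            {
                "group": rng.permutation(["case"] * 18 + ["control"] * 18),
                "age": rng.uniform(8, 30, n),
                "sex": rng.choice(["M", "F"], n),
                "site": rng.choice(["s0", "s1", "s2"], n),
            }
        )
        base = cg.fit_mglm(aligned, cov)
        perm = rng.permutation(n)
        shuffled = cg.fit_mglm(aligned[perm], cov.iloc[perm].reset_index(drop=True))
        assert np.allclose(base.p, shuffled.p, atol=1e-10)
        other_ref = cg.fit_mglm(aligned, cov, drop_site="s2")
        assert np.allclose(base.p, other_ref.p, atol=1e-10)

    def test_constant_response_rejected(self):
        aligned = np.zeros((20, 4, 3))
        cov = pd.DataFrame(
            {
                "group": ["case"] * 10 + ["control"] * 10,
                "age": np.linspace(8, 30, 20),
                "sex": ["M", "F"] * 10,
                "site": ["a"] * 20,
            }
        )
        with pytest.raises(ValueError, match="singular|degenerate"):
            cg.fit_mglm(aligned, cov)

    def test_aliased_design_named(self):
        rng = np.random.default_rng(2)
        aligned = rng.normal(size=(20, 4, 3))
        cov = pd.DataFrame(
            {
                "group": ["case"] * 10 + ["control"] * 10,
                "age": np.linspace(8, 30, 20),
                "sex": ["M"] * 20,  # constant: aliased with the intercept
                "site": ["a"] * 20,
            }
        )
        with pytest.raises(ValueError, match="sex"):
            cg.fit_mglm(aligned, cov)

    def test_design_encoding(self):
        cov = pd.DataFrame(
            {
                "group": ["case", "control", "case"],
                "age": [10.0, 20.0, 30.0],
                "sex": ["M", "F", "F"],
                "site": ["b", "a", "c"],
            }
        )
        x, names = build_design(cov)
        assert names == ["intercept", "group", "age", "sex", "site[b]", "site[c]"]
        assert np.array_equal(x[:, 1], [1, 0, 1])
        assert np.array_equal(x[:, 3], [1, 0, 0])


class TestFdrBh:
    def test_single_p_and_all_significant_block(self):
        q, sig = cg.fdr_bh(np.array([0.03]))
        assert q[0] == pytest.approx(0.03)
        q, sig = cg.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert sig.all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 50)
        p = rng.uniform(1e-6, 1.0, size=m)
        q, sig = cg.fdr_bh(p, alpha=0.05)
        expect = brute_force_bh(p)
        assert np.allclose(q, expect, atol=1e-12)
        assert np.array_equal(sig, expect < 0.05)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            cg.fdr_bh(np.array([0.1, 0.0]))
        with pytest.raises(ValueError):
            cg.fdr_bh(np.array([0.1, 1.2]))


class TestSpin:
    def test_identity_rotation_gives_identity_permutation(self, scheme60):
        eye = [np.eye(3)]
        perm = cg.spin_permutations(scheme60, 1, rotations=eye)[0]
        assert np.array_equal(perm, np.arange(scheme60.n_parcels))

    def test_null_is_a_permutation_per_hemisphere(self, scheme60):
        perms = cg.spin_permutations(scheme60, 25, seed=3)
        for h in ("L", "R"):
            idx = scheme60.hemisphere_indices(h)
            for k in range(25):
                assert sorted(perms[k, idx]) == sorted(idx)

    def test_identical_smooth_maps_give_minimal_p(self, scheme100):
        smooth = scheme100.centroids[:, 2] + 0.5 * scheme100.centroids[:, 1]
        null = cg.spin_test(smooth, smooth, scheme100, n_perm=99, seed=0)
        assert null.observed_r == pytest.approx(1.0)
        assert null.p == pytest.approx(1.0 / 100.0)

    def test_determinism_and_p_bounds(self, scheme60):
        rng = np.random.default_rng(7)
        a = scheme60.centroids[:, 0] + 0.1 * rng.standard_normal(60)
        b = rng.standard_normal(60)
        s1 = cg.spin_test(a, b, scheme60, n_perm=50, seed=5)
        s2 = cg.spin_test(a, b, scheme60, n_perm=50, seed=5)
        assert np.array_equal(s1.null_r, s2.null_r)
        assert s1.p == s2.p
        assert 1 / 51 <= s1.p <= 1.0

    def test_constant_map_rejected(self, scheme60):
        with pytest.raises(ValueError, match="constant"):
            cg.spin_test(np.ones(60), np.arange(60.0), scheme60)

    def test_zero_permutations_rejected(self, scheme60):
        with pytest.raises(ValueError):
            cg.spin_permutations(scheme60, 0)

    def test_random_rotation_is_proper(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            r = _random_rotation(rng)
            assert np.allclose(r.T @ r, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0)


class TestStratify:
    def test_single_label_equals_global_mean(self, scheme60):
        rng = np.random.default_rng(0)
        t2 = rng.random(60)
        eff = make_effect_map(t2, rng.uniform(0.01, 1.0, 60))
        scheme = cg.make_parcellation(60, 1, 1, seed=2)
        table = cg.stratify_effects(eff, scheme, by="community")
        assert len(table) == 1
        assert table["mean_T2"].iloc[0] == pytest.approx(t2.mean())

    def test_hand_built_two_label_means(self):
        scheme = cg.make_parcellation(8, 2, 2, seed=0)
        t2 = np.arange(8, dtype=float)
        eff = make_effect_map(t2, np.full(8, 0.5))
        table = cg.stratify_effects(eff, scheme, by="community")
        for _, row in table.iterrows():
            members = t2[scheme.community == row["label"]]
            assert row["mean_T2"] == pytest.approx(members.mean())
            assert row["sd_T2"] == pytest.approx(members.std(ddof=0))
            assert row["n_parcels"] == len(members)
        # weighted overall mean reproduces the global mean
        total = (table["mean_T2"] * table["n_parcels"]).sum() / 8
        assert total == pytest.approx(t2.mean())

    def test_invalid_grouping(self, scheme60):
        eff = make_effect_map(np.ones(60), np.full(60, 0.5))
        with pytest.raises(ValueError):
            cg.stratify_effects(eff, scheme60, by="lobe")


class TestSummarize:
    def test_degenerate_and_hand_built(self):
        eff = make_effect_map(np.full(5, 2.0), np.full(5, 0.9))
        s = cg.summarize_template(eff)
        assert s == {"mean_T2": 2.0, "sd_T2": 0.0, "n_significant": 0}
        t2 = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        eff = make_effect_map(t2, np.array([0.5, 0.5, 0.5, 0.5, 1e-5]))
        s = cg.summarize_template(eff)
        assert s["mean_T2"] == pytest.approx(t2.mean())
        assert s["sd_T2"] == pytest.approx(t2.std(ddof=0))
        assert s["n_significant"] == 1


class TestTemplateUtility:
    def _features(self, rng, n, p, separation=0.0):
        labels = np.array(["case"] * (n // 2) + ["control"] * (n // 2))
        x = rng.normal(size=(n, p))
        x[: n // 2, 0] += separation
        cov = pd.DataFrame(
            {
                "group": labels,
                "age": rng.uniform(8, 30, n),
                "sex": rng.choice(["M", "F"], n),
                "site": rng.choice(["a", "b"], n),
            }
        )
        return x, cov, labels

    def test_separable_classes_reach_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        x, cov, labels = self._features(rng, 40, 10, separation=50.0)
        table = cg.evaluate_template_utility(
            x, cov, labels, task="classify", n_repeats=3, seed=1
        )
        assert table["accuracy"].iloc[:-1].min() == 1.0

    def test_null_features_stay_near_chance(self):
        rng = np.random.default_rng(1)
        x, cov, labels = self._features(rng, 60, 20, separation=0.0)
        table = cg.evaluate_template_utility(
            x, cov, labels, task="classify", n_repeats=10, seed=2
        )
        mean_acc = table["accuracy"].iloc[-1]
        # 95% band for chance-level accuracy at n=60
        assert 0.5 - 2 * np.sqrt(0.25 / 60) - 0.05 < mean_acc
        assert mean_acc < 0.5 + 2 * np.sqrt(0.25 / 60) + 0.05

    def test_prediction_recovers_linear_score(self):
        rng = np.random.default_rng(3)
        x, cov, _ = self._features(rng, 50, 8)
        score = x[:, 0] * 2.0 + 0.1 * rng.standard_normal(50)
        table = cg.evaluate_template_utility(
            x, cov, score, task="predict", n_repeats=5, seed=4
        )
        assert table["r"].iloc[-1] > 0.9

    def test_determinism(self):
        rng = np.random.default_rng(5)
        x, cov, labels = self._features(rng, 30, 6, separation=1.0)
        t1 = cg.evaluate_template_utility(
            x, cov, labels, task="classify", n_repeats=4, seed=9
        )
        t2 = cg.evaluate_template_utility(
            x, cov, labels, task="classify", n_repeats=4, seed=9
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(6)
        x, cov, _ = self._features(rng, 20, 4)
        with pytest.raises(ValueError):
            cg.evaluate_template_utility(
                x, cov, np.array(["case"] * 20), task="classify"
            )
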