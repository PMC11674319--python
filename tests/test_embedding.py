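import numpy as np
import pytest
from scipy.linalg import eig

import conngrad as cg
import conngrad.synthetic as syn
from conngrad.connectome import ConnectivityMatrix
from conngrad.embedding import GradientParams, _fix_signs

from conftest import random_spd_affinity


def reference_diffusion_map(w: np.ndarray, k: int, alpha: float):
    """Brute-force dense oracle via the symmetric conjugate operator.

    Builds the density-normalized operator with explicit diagonal-matrix
    products, eigendecomposes its symmetric conjugate S = D^-1/2 W' D^-1/2
    densely, and maps the eigenvectors back to Markov-operator
    eigenvectors normalized so the trivial one is the constant vector.
    Additionally checks the eigenvalues against a general (non-symmetric)
    eigensolver applied to the Markov operator itself.
    """
    d = w.sum(axis=1)
    da = np.diag(d**-alpha)
    w_alpha = da @ w @ da
    d2 = w_alpha.sum(axis=1)
    dm = np.diag(d2**-0.5)
    s = dm @ w_alpha @ dm
    evals, evecs = np.linalg.eigh((s + s.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    psi = (dm @ evecs)
    psi = psi / psi[:, [0]]
    lam = evals[1 : k + 1]

    markov = np.diag(1.0 / d2) @ w_alpha
    mu = np.sort(np.real(eig(markov, right=False)))[::-1]
    assert np.allclose(mu[: k + 1], evals[: k + 1], atol=1e-8)
    return psi[:, 1 : k + 1] * (lam / (1 - lam)), lam


class TestRowThreshold:
    def test_density_one_is_identity_off_diagonal(self):
        m = np.random.default_rng(0).random((6, 6))
        out = cg.row_threshold(m, density=1.0)
        off = ~np.eye(6, dtype=bool)
        assert np.array_equal(out[off], m[off])
        assert np.all(np.diag(out) == 0)

    def test_top_ten_percent_of_200_parcels_keeps_20(self):
        m = np.random.default_rng(1).normal(size=(200, 200))
        out = cg.row_threshold(m, density=0.10)
        assert np.all(np.count_nonzero(out, axis=1) == 20)

    def test_against_sort_oracle(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(5, 5))
        out = cg.row_threshold(m, density=0.5)
        for i in range(5):
            off = [j for j in range(5) if j != i]
            expect = sorted(off, key=lambda j: (-m[i, j], j))[:2]
            kept = set(np.flatnonzero(out[i]))
            assert kept == set(expect)
            for j in expect:
                assert out[i, j] == m[i, j]

    def test_tie_break_prefers_lower_column(self):
        m = np.zeros((4, 4))
        m[0] = [0.0, 5.0, 5.0, 5.0]
        out = cg.row_threshold(m, density=0.34)  # keeps ceil(0.34*3) = 2
        assert set(np.flatnonzero(out[0])) == {1, 2}

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            cg.row_threshold(np.eye(3), density=0.0)
        with pytest.raises(ValueError):
            cg.row_threshold(np.eye(3), density=1.5)


class TestAffinities:
    def test_normalized_angle_landmarks(self):
        rows = np.array([[1.0, 2.0, 0.5], [1.0, 2.0, 0.5], [-1.0, -2.0, -0.5]])
        a = cg.normalized_angle_affinity(rows).values
        assert a[0, 1] == pytest.approx(1.0)  # equal angles
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # opposite angles
        b = cg.normalized_angle_affinity(np.eye(3)).values
        assert b[0, 1] == pytest.approx(0.5)  # orthogonal rows

    def test_normalized_angle_bounds_and_symmetry(self):
        m = np.random.default_rng(3).normal(size=(20, 20))
        a = cg.normalized_angle_affinity(m).values
        assert a.min() >= 0.0 and a.max() <= 1.0
        assert np.allclose(a, a.T, atol=1e-12)
        assert np.all(np.diag(a) == 1.0)

    def test_cosine_against_dot_product_oracle(self):
        m = np.array(
            [[1.0, 0.0, 2.0, -1.0], [0.5, 1.0, 0.0, 3.0], [2.0, -1.0, 1.0, 0.0]]
        )
        a = cg.cosine_affinity(m).values
        for i in range(3):
            for j in range(i + 1, 3):
                c = m[i] @ m[j] / (np.linalg.norm(m[i]) * np.linalg.norm(m[j]))
                assert a[i, j] == pytest.approx(max(c, 0.0), abs=1e-12)

    def test_all_zero_row_rejected(self):
        m = np.eye(4)
        m[2] = 0.0
        with pytest.raises(ValueError, match="2"):
            cg.normalized_angle_affinity(m)


class TestDiffusionMap:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("p", [10, 40, 100])
    def test_oracle_equivalence(self, seed, p):
        rng = np.random.default_rng(seed)
        w = random_spd_affinity(rng, p)
        g = cg.diffusion_map(cg.normalized_angle_affinity(w), k=3, alpha=0.5)
        oracle, lam = reference_diffusion_map(
            cg.normalized_angle_affinity(w).values, k=3, alpha=0.5
        )
        assert np.allclose(g.eigenvalues, lam, atol=1e-8)
        for j in range(3):
            dev = min(
                np.abs(g.components[:, j] - oracle[:, j]).max(),
                np.abs(g.components[:, j] + oracle[:, j]).max(),
            )
            assert dev < 1e-8

    def test_two_block_affinity_separated_by_g1(self):
        w = np.full((10, 10), 0.01)
        w[:5, :5] = 0.9
        w[5:, 5:] = 0.9
        np.fill_diagonal(w, 1.0)
        g = cg.diffusion_map(cg.AffinityMatrix(w, "cosine"), k=2)
        signs = np.sign(g.components[:, 0])
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]

    def test_ring_graph_gives_sine_cosine_pair(self):
        p = 40
        w = np.zeros((p, p))
        idx = np.arange(p)
        w[idx, (idx + 1) % p] = 1.0
        w[idx, (idx - 1) % p] = 1.0
        w += np.eye(p)
        g = cg.diffusion_map(cg.AffinityMatrix(w, "cosine"), k=2)
        assert g.eigenvalues[0] == pytest.approx(g.eigenvalues[1], abs=1e-10)
        radius = g.components[:, 0] ** 2 + g.components[:, 1] ** 2
        assert radius.std() / radius.mean() < 1e-8
        # one full period around the ring
        angle = np.unwrap(np.arctan2(g.components[:, 1], g.components[:, 0]))
        assert abs(abs(angle[-1] - angle[0]) - 2 * np.pi * (p - 1) / p) < 1e-6

    def test_spectral_properties(self):
        w = random_spd_affinity(np.random.default_rng(9), 30)
        g = cg.diffusion_map(cg.AffinityMatrix(w, "cosine"), k=5)
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)
        assert np.all(np.abs(g.eigenvalues) < 1.0)
        assert g.variance_explained.sum() <= 1.0 + 1e-12
        all_ev = g.meta["all_eigenvalues"][1:]
        k_all = np.sum(all_ev > 0)
        g_full = cg.diffusion_map(cg.AffinityMatrix(w, "cosine"), k=int(k_all))
        pos = g_full.variance_explained[g_full.eigenvalues > 0]
        assert pos.sum() == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_idempotent(self):
        comps = np.random.default_rng(4).normal(size=(20, 3))
        once = _fix_signs(comps)
        assert np.array_equal(_fix_signs(once), once)
        for j in range(3):
            assert once[np.argmax(np.abs(once[:, j])), j] > 0

    def test_disconnected_affinity_reports_components(self):
        w = np.eye(6)
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="2 components"):
            cg.diffusion_map(cg.AffinityMatrix(w, "cosine"), k=2)

    def test_k_too_large(self):
        w = random_spd_affinity(np.random.default_rng(0), 5)
        with pytest.raises(ValueError):
            cg.diffusion_map(cg.AffinityMatrix(w, "cosine"), k=5)


class TestEmbedFunctional:
    def test_three_factor_subspace_recovery(self, scheme100):
        """A noise-free 3-factor correlation matrix embeds onto the factor span.

        Row thresholding at the default 10% density discards some third-axis
        information, so full recovery is asserted for the untruncated kernel
        and slightly relaxed recovery for the default pipeline.
        """
        latent = syn.latent_from_scheme(scheme100)
        latent = latent / latent.std(axis=0)
        corr = syn.implied_correlation(latent, 0.05)
        fc = ConnectivityMatrix(corr, "functional", "raw_r")

        def cancorrs(components):
            qx, _ = np.linalg.qr(latent - latent.mean(0))
            qy, _ = np.linalg.qr(components - components.mean(0))
            return np.linalg.svd(qx.T @ qy, compute_uv=False)

        full = cg.embed_functional(cg.fisher_z(fc), GradientParams(density=1.0))
        assert cancorrs(full.components).min() > 0.95
        default = cg.embed_functional(cg.fisher_z(fc))
        cc = cancorrs(default.components)
        assert cc[0] > 0.95
        assert cc[:2].min() > 0.9
        assert cc.min() > 0.85

    def test_determinism_and_shape(self, fc_cohort):
        fc = cg.fisher_z(fc_cohort[0].fc)
        a = cg.embed_functional(fc)
        b = cg.embed_functional(fc)
        assert np.array_equal(a.components, b.components)
        assert a.components.shape == (100, 3)
        assert np.array_equal(a.eigenvalues, b.eigenvalues)

    def test_state_contract(self, fc_cohort):
        with pytest.raises(ValueError):
            cg.embed_functional(fc_cohort[0].fc)  # raw_r, not fisher_z


class TestEmbedStructural:
    def test_hemisphere_symmetric_sc_gives_mirror_gradients(self, scheme60):
        truth = cg.make_ground_truth(scheme60, n_affected=0, seed=5)
        sc = cg.simulate_sc_cohort(scheme60, 2, 2, truth)[0].sc
        h = scheme60.homologue
        sym = sc.values + sc.values[np.ix_(h, h)]
        logm = cg.log_transform_sc(
            ConnectivityMatrix(sym, "structural", "raw_count")
        )
        g = cg.embed_structural(logm, scheme60)
        left = scheme60.hemisphere_indices("L")
        assert np.allclose(
            g.components[left], g.components[h[left]], atol=1e-8
        )

    def test_flip_commutes_up_to_anchor_rotation(self, scheme60):
        """Flipping hemispheres before embedding equals flipping gradient rows
        afterwards, modulo the rotation that re-anchors the right hemisphere
        onto the left (the anchoring direction swaps under the flip)."""
        truth = cg.make_ground_truth(scheme60, n_affected=6, seed=8)
        group = cg.distance_consensus_group_sc(
            [r.sc for r in cg.simulate_sc_cohort(scheme60, 3, 3, truth)], scheme60
        )
        g = cg.embed_structural(cg.log_transform_sc(group), scheme60)
        g_flip = cg.embed_structural(
            cg.log_transform_sc(cg.flip_hemispheres(group, scheme60)), scheme60
        )
        from conngrad.connectome import flip_gradient_rows

        expected = flip_gradient_rows(g.components, scheme60)
        aligned, _ = cg.procrustes_rotate(g_flip.components, expected)
        assert np.abs(aligned - expected).max() < 1e-8

    def test_planted_subspace_recovery(self, scheme100):
        truth = cg.make_ground_truth(scheme100, n_affected=0, seed=2)
        group = cg.distance_consensus_group_sc(
            [r.sc for r in cg.simulate_sc_cohort(scheme100, 5, 5, truth)],
            scheme100,
        )
        g = cg.embed_structural(cg.log_transform_sc(group), scheme100)
        # G1 tracks the dominant latent axis within each hemisphere
        r = np.corrcoef(g.components[:, 0], truth.latent_coords[:, 0])[0, 1]
        assert abs(r) > 0.7
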