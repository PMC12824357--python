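import numpy as np
import pytest
from scipy.linalg import circulant
from scipy.stats import spearmanr

from hiergrad import gradients as gr
from hiergrad.errors import ConfigError, ConnectivityError, DegenerateDataError
from hiergrad.synthetic import SynthConfig, latent_kernel, synth_cohort

from conftest import oracle_diffusion_embed


def random_affinity(n: int, seed: int, density: float = 0.3) -> np.ndarray:
    """Random but in-domain affinity: correlation-like matrix ->
    sparsified cosine similarity.  Density scales up for tiny n so the
    graph stays connected."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4 * n))
    conn = np.corrcoef(X)
    # shift positive mass so every row keeps edges
    conn = np.clip(conn + 0.3, -1, 1)
    np.fill_diagonal(conn, 1.0)
    density = max(density, min(4.0 / (n - 1), 1.0))
    return gr.affinity_from_connectome(conn, density=density).matrix


class TestConnectome:
    def test_identical_and_opposite_rows(self):
        t = np.linspace(0, 1, 50)
        x = np.sin(7 * t) + t
        data = np.vstack([x, x, -x])
        c = gr.build_connectome(data).matrix
        assert np.isclose(c[0, 1], 1.0)
        assert np.isclose(c[0, 2], -1.0)

    def test_matches_sum_formula_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((5, 200))
        c = gr.build_connectome(data).matrix
        # direct textbook formula
        for i in range(5):
            for j in range(5):
                xi, xj = data[i] - data[i].mean(), data[j] - data[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(c[i, j] - r) < 1e-12

    def test_constant_row_rejected(self):
        data = np.ones((3, 10))
        data[0] = np.random.default_rng(0).standard_normal(10)
        with pytest.raises(DegenerateDataError):
            gr.build_connectome(data)


class TestSparsify:
    def test_row_example_density_half(self):
        # row of interest keeps its 2 = round(0.5 * 4) largest positives
        m = np.full((5, 5), 0.2)
        m[0, 1:] = [0.9, 0.5, 0.1, -0.3]
        m[1:, 0] = m[0, 1:]
        np.fill_diagonal(m, 1.0)
        out = gr.sparsify_rows(m, density=0.5)
        np.testing.assert_allclose(out[0], [0.0, 0.9, 0.5, 0.0, 0.0])

    def test_at_most_k_per_row_and_only_positive(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 100))
        conn = np.corrcoef(X)
        out = gr.sparsify_rows(conn, density=0.1)
        k = round(0.1 * 29)
        assert ((out > 0).sum(axis=1) <= k).all()
        assert (out >= 0).all()
        assert np.all(np.diag(out) == 0)

    def test_tie_break_drops_larger_column_first(self):
        m = np.eye(4)
        m[0, 1:] = [0.5, 0.5, 0.5]
        m = np.clip(m + m.T, -1, 1)
        np.fill_diagonal(m, 1.0)
        out = gr.sparsify_rows(m, density=1 / 3)  # k = 1
        np.testing.assert_allclose(out[0], [0.0, 0.5, 0.0, 0.0])

    def test_row_without_positive_entries(self):
        m = np.eye(3)
        m[0, 1:] = [-0.2, -0.5]
        m[1:, 0] = [-0.2, -0.5]
        m[1, 2] = m[2, 1] = 0.5
        with pytest.raises(DegenerateDataError, match="row 0"):
            gr.sparsify_rows(m, density=0.5)


class TestAffinity:
    def test_identical_sparsified_profiles_give_one(self):
        # rows 0 and 1 share their retained profile (their mutual edge is
        # too weak to survive sparsification) -> cosine affinity exactly 1
        n = 6
        m = np.full((n, n), 0.3)
        m[0, 1] = m[1, 0] = 0.05
        for j, v in zip(range(2, 6), [0.9, 0.8, 0.7, -0.1]):
            m[0, j] = m[j, 0] = v
            m[1, j] = m[j, 1] = v
        np.fill_diagonal(m, 1.0)
        aff = gr.affinity_from_connectome(m, density=0.4).matrix  # k = 2
        assert np.isclose(aff[0, 1], 1.0, atol=1e-12)

    def test_disjoint_support_gives_zero(self):
        sparse = np.zeros((4, 4))
        sparse[0, 1] = 0.9
        sparse[2, 3] = 0.8
        # cosine of disjoint rows is 0 by construction; exercise via the
        # internal step on a crafted connectome
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.9
        m[2, 3] = m[3, 2] = 0.8
        m[0, 2] = m[2, 0] = -0.1
        m[1, 3] = m[3, 1] = -0.1
        m[0, 3] = m[3, 0] = -0.1
        m[1, 2] = m[2, 1] = -0.1
        aff = gr.affinity_from_connectome(m, density=1 / 3).matrix
        assert aff[0, 2] == 0.0


class TestDiffusionEmbed:
    def test_two_block_step_component(self):
        eps = 1e-3
        W = np.full((6, 6), eps)
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        g = gr.diffusion_embed(W, n_components=2)
        c = g.components[:, 0]
        assert np.ptp(np.sign(c[:3])) == 0 and np.ptp(np.sign(c[3:])) == 0
        assert np.sign(c[0]) != np.sign(c[3])
        assert np.std(c[:3]) < 1e-6 * np.abs(c).max()

    def test_ring_lattice_sine_cosine_pair(self):
        n = 24
        dist = np.minimum(np.arange(n), n - np.arange(n))
        W = circulant(np.exp(-dist / 3.0))
        g = gr.diffusion_embed(W, n_components=4)
        assert np.isclose(g.eigenvalues[0], g.eigenvalues[1], atol=1e-10)
        assert g.degenerate[0] and g.degenerate[1]
        # first pair spans the fundamental Fourier mode
        theta = 2 * np.pi * np.arange(n) / n
        basis = np.column_stack([np.cos(theta), np.sin(theta)])
        pair = g.components[:, :2]
        proj = basis @ np.linalg.lstsq(basis, pair, rcond=None)[0]
        assert np.linalg.norm(pair - proj) < 1e-8 * np.linalg.norm(pair)

    def test_matches_dense_oracle(self):
        for seed, n in [(0, 6), (1, 17), (2, 33), (3, 50)]:
            W = random_affinity(n, seed)
            k = min(5, n - 2)
            g = gr.diffusion_embed(W, alpha=0.5, n_components=k)
            evals, comps = oracle_diffusion_embed(W, 0.5, k)
            np.testing.assert_allclose(g.eigenvalues, evals, atol=1e-8)
            mine = g.components / np.linalg.norm(g.components, axis=0)
            for j in range(k):
                if g.degenerate[j]:
                    continue
                assert min(np.linalg.norm(mine[:, j] - comps[:, j]),
                           np.linalg.norm(mine[:, j] + comps[:, j])) < 1e-6

    def test_markov_property(self):
        W = random_affinity(20, 5)
        P = gr.markov_matrix(W, alpha=0.5)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        lam = np.max(np.abs(np.linalg.eigvals(P)))
        assert abs(lam - 1.0) < 1e-10

    def test_permutation_equivariance(self):
        W = random_affinity(15, 8)
        rng = np.random.default_rng(1)
        p = rng.permutation(15)
        g1 = gr.diffusion_embed(W, n_components=3)
        g2 = gr.diffusion_embed(W[np.ix_(p, p)], n_components=3)
        for j in range(3):
            a, b = g1.components[p, j], g2.components[:, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_scale_invariance_of_pipeline(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((20, 200))
        g1 = gr.embed_scan(data, density=0.3, n_components=3)
        g2 = gr.embed_scan(4.0 * data, density=0.3, n_components=3)
        np.testing.assert_array_equal(g1.components, g2.components)

    def test_disconnected_graph_refused(self):
        W = np.eye(6)
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        with pytest.raises(ConnectivityError, match="2 components"):
            gr.diffusion_embed(W, n_components=2)

    def test_too_many_components_refused(self):
        with pytest.raises(ConfigError):
            gr.diffusion_embed(random_affinity(6, 0), n_components=6)


class TestTemplates:
    def test_identical_connectomes_equal_single_scan(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((30, 300))
        conn = gr.build_connectome(data)
        tem = gr.build_templates([conn, conn, conn], density=0.3)
        g = gr.diffusion_embed(gr.affinity_from_connectome(conn, 0.3),
                               n_components=10)
        for tvec, comp in ((tem.principal, g.components[:, 0]),
                           (tem.secondary, g.components[:, 1])):
            assert min(np.abs(tvec - comp).max(),
                       np.abs(tvec + comp).max()) < 1e-10

    def test_mean_connectome_is_elementwise_average(self):
        rng = np.random.default_rng(5)
        c1 = gr.build_connectome(rng.standard_normal((10, 100)))
        c2 = gr.build_connectome(rng.standard_normal((10, 100)))
        mean = np.mean([c1.matrix, c2.matrix], axis=0)
        np.testing.assert_allclose(
            mean, (c1.matrix + c2.matrix) / 2, atol=1e-15
        )

    def test_planted_hierarchy_template_tracks_latent(self):
        cfg = SynthConfig(seed=9, n_parcels=100, n_subjects=3,
                          n_scans_per_condition=1, noise_sigma=0.05)
        coh = synth_cohort(cfg)
        conns = [gr.build_connectome(ts.data) for ts in coh.timeseries]
        tem = gr.build_templates(conns)
        rho = spearmanr(tem.principal, coh.ground_truth.latent_base).statistic
        assert abs(rho) > 0.95

    def test_mixed_parcel_counts_rejected(self):
        rng = np.random.default_rng(6)
        c1 = gr.build_connectome(rng.standard_normal((10, 100)))
        c2 = gr.build_connectome(rng.standard_normal((12, 100)))
        with pytest.raises(Exception, match="parcel"):
            gr.build_templates([c1, c2])


class TestAlign:
    def _gset(self, comps):
        return gr.GradientSet(components=comps,
                              eigenvalues=np.linspace(0.9, 0.5, comps.shape[1]),
                              alpha=0.5, density=0.1)

    def test_identity_alignment(self):
        rng = np.random.default_rng(7)
        comps = rng.standard_normal((40, 4))
        tem = gr.GradientTemplate(comps[:, 0], comps[:, 1])
        al = gr.align_gradients(self._gset(comps), tem)
        assert al.source_component_index == (0, 1)
        assert al.sign_flipped == (False, False)
        assert al.match_r[0] > 0.999 and al.match_r[1] > 0.999

    def test_negated_component_found_and_flipped(self):
        rng = np.random.default_rng(8)
        comps = rng.standard_normal((40, 5))
        tem = gr.GradientTemplate(-comps[:, 3], comps[:, 1])
        al = gr.align_gradients(self._gset(comps), tem)
        assert al.source_component_index[0] == 3
        assert al.sign_flipped[0] is True or al.sign_flipped[0] == True  # noqa: E712
        np.testing.assert_allclose(al.principal, -comps[:, 3])

    def test_greedy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        comps = rng.standard_normal((60, 10))
        noisy = comps[:, 7] + 0.3 * rng.standard_normal(60)
        tem = gr.GradientTemplate(noisy, comps[:, 2] + 0.3 * rng.standard_normal(60))
        al = gr.align_gradients(self._gset(comps), tem)
        # exhaustive: best |r| for principal, then best remaining
        r_p = [abs(np.corrcoef(tem.principal, comps[:, j])[0, 1]) for j in range(10)]
        jp = int(np.argmax(r_p))
        r_s = [abs(np.corrcoef(tem.secondary, comps[:, j])[0, 1]) if j != jp else -1
               for j in range(10)]
        assert al.source_component_index == (jp, int(np.argmax(r_s)))

    def test_low_match_warning_flag(self):
        rng = np.random.default_rng(10)
        comps = rng.standard_normal((200, 3))
        tem = gr.GradientTemplate(rng.standard_normal(200),
                                  rng.standard_normal(200))
        al = gr.align_gradients(self._gset(comps), tem, floor=0.9)
        assert al.low_match_warning
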