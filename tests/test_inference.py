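import numpy as np
import pytest
from scipy.stats import nbinom, poisson, spearmanr

from hic3d.contacts import ContactMatrix
from hic3d.genome_layout import ChromosomeRecord, GenomeLayout
from hic3d.inference import (
    InferenceConfig,
    NBParams,
    counts_to_wish_distances,
    estimate_nb_params,
    fit_structure,
    mds_init,
    nb_loglik,
)
from hic3d import synthetic


def line_layout(n, res=100):
    return GenomeLayout((ChromosomeRecord("c", n * res),), resolution=res)


@pytest.fixture(scope="module")
def helix_60():
    layout, truth = synthetic.make_helix_structure(
        60, radius=3.0, rise_per_bead=0.12, beads_per_turn=12
    )
    return layout, truth


class TestWishDistances:
    def test_closed_form_before_rescaling(self):
        # single adjacent pair => rescaling divides by its own distance
        lay = line_layout(3)
        m = ContactMatrix.from_pairs(lay, [1, 1], [2, 3], [8.0, 8.0])
        wish = counts_to_wish_distances(m, alpha=-3.0)
        # both distances are 8**(-1/3) = 0.5 pre-scaling; adjacent median = 0.5
        assert wish[(1, 2)] == pytest.approx(1.0)
        assert wish[(1, 3)] == pytest.approx(1.0)

    def test_count_one_gives_unit_distance(self):
        lay = line_layout(2)
        m = ContactMatrix.from_pairs(lay, [1], [2], [1.0])
        wish = counts_to_wish_distances(m, alpha=-7.0)
        assert wish[(1, 2)] == pytest.approx(1.0)

    def test_zero_pairs_absent(self):
        lay = line_layout(3)
        m = ContactMatrix.from_pairs(lay, [1], [2], [8.0])
        wish = counts_to_wish_distances(m, alpha=-3.0)
        assert (1, 3) not in wish and (2, 3) not in wish

    def test_nonnegative_alpha_rejected(self):
        lay = line_layout(2)
        m = ContactMatrix.from_pairs(lay, [1], [2], [1.0])
        with pytest.raises(ValueError):
            counts_to_wish_distances(m, alpha=0.0)


class TestMDSInit:
    def test_exact_line_distances_embed_collinearly(self):
        wish = {(1, 2): 1.0, (1, 3): 2.0, (1, 4): 3.0,
                (2, 3): 1.0, (2, 4): 2.0, (3, 4): 1.0}
        X = mds_init(wish, 4, seed=0)
        s = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
        assert s[1] < 1e-6 and s[2] < 1e-6  # collinear
        stress = sum(
            (np.linalg.norm(X[a - 1] - X[b - 1]) - d) ** 2
            for (a, b), d in wish.items()
        )
        assert stress < 1e-8

    def test_deterministic_given_seed(self):
        wish = {(1, 2): 1.0, (2, 3): 1.5, (1, 3): 2.2}
        assert np.array_equal(mds_init(wish, 3, seed=7), mds_init(wish, 3, seed=7))

    def test_single_pair_placed_at_wish_distance(self):
        X = mds_init({(1, 2): 2.0}, 2, seed=0)
        assert np.linalg.norm(X[0] - X[1]) == pytest.approx(2.0, abs=1e-6)

    def test_fewer_than_two_beads_rejected(self):
        with pytest.raises(ValueError):
            mds_init({(1, 2): 1.0}, 1, seed=0)


class TestNBLoglik:
    def setup_method(self):
        self.lay = line_layout(3)
        self.mat = ContactMatrix.from_pairs(
            self.lay, [1, 1, 2], [2, 3, 3], [5.0, 2.0, 7.0]
        )
        self.coords = np.array([[0, 0, 0], [1.1, 0, 0], [1.9, 0.4, 0.2]])
        self.mu = [
            6.0 * np.linalg.norm(self.coords[a] - self.coords[b]) ** -3
            for a, b in [(0, 1), (0, 2), (1, 2)]
        ]

    def test_matches_poisson_in_large_r_limit(self):
        ll = nb_loglik(self.mat, self.coords, NBParams(alpha=-3, beta=6.0, r=1e12))
        ll_poisson = sum(
            poisson.logpmf(c, mu) for c, mu in zip([5, 2, 7], self.mu)
        )
        assert ll == pytest.approx(ll_poisson, abs=1e-4)

    def test_matches_direct_pmf_summation(self):
        r = 4.0
        ll = nb_loglik(self.mat, self.coords, NBParams(alpha=-3, beta=6.0, r=r))
        # scipy's NB(n, p) equals NB(mean mu, dispersion r) with n=r, p=r/(r+mu)
        ll_oracle = sum(
            nbinom.logpmf(c, r, r / (r + mu)) for c, mu in zip([5, 2, 7], self.mu)
        )
        assert ll == pytest.approx(ll_oracle, abs=1e-9)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(0)
        Q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        moved = self.coords @ Q.T + np.array([5.0, -2.0, 1.0])
        p = NBParams(alpha=-3, beta=6.0, r=8.0)
        assert nb_loglik(self.mat, self.coords, p) == pytest.approx(
            nb_loglik(self.mat, moved, p), abs=1e-9
        )

    def test_coincident_beads_guarded_by_floor(self):
        coords = np.array([[0.0, 0, 0], [0.0, 0, 0], [1, 0, 0]])
        ll = nb_loglik(self.mat, coords, NBParams(alpha=-3, beta=6.0, r=8.0),
                       dist_floor=1e-6)
        assert np.isfinite(ll)


class TestEstimateNBParams:
    def test_beta_closed_form_exact(self):
        lay, truth = synthetic.make_helix_structure(30)
        mat = synthetic.counts_from_structure(
            truth, NBParams(alpha=-3, beta=1.0, r=1e12), noise="exact"
        )
        est = estimate_nb_params(mat, truth.coords, alpha=-3)
        assert est.beta == pytest.approx(1.0, abs=1e-9)

    def test_beta_homogeneous_in_counts(self):
        lay, truth = synthetic.make_helix_structure(30)
        m1 = synthetic.counts_from_structure(
            truth, NBParams(alpha=-3, beta=1.0, r=1e12), noise="exact"
        )
        i, j, c = m1.pairs()
        m100 = ContactMatrix.from_pairs(truth.layout, i, j, 100.0 * c)
        e1 = estimate_nb_params(m1, truth.coords, alpha=-3)
        e100 = estimate_nb_params(m100, truth.coords, alpha=-3)
        assert e100.beta == pytest.approx(100.0 * e1.beta, rel=1e-9)

    def test_dispersion_recovered_within_factor_two(self):
        lay, truth = synthetic.make_helix_structure(200)
        mat = synthetic.counts_from_structure(
            truth, NBParams(alpha=-3, beta=100.0, r=10.0), noise="nb", seed=5
        )
        est = estimate_nb_params(mat, truth.coords, alpha=-3)
        assert 5.0 < est.r < 20.0

    def test_all_zero_counts_rejected(self):
        lay = line_layout(3)
        m = ContactMatrix.from_pairs(lay, [1, 1], [2, 3], [0.0, 0.0])
        with pytest.raises(ValueError):
            estimate_nb_params(m, np.zeros((3, 3)) + np.arange(3)[:, None], alpha=-3)


class TestFitStructure:
    def test_two_bead_closed_form_distance(self):
        lay = line_layout(2)
        m = ContactMatrix.from_pairs(lay, [1], [2], [8.0])
        cfg = InferenceConfig(
            beta_mode="fixed", beta=8.0, dispersion_mode="fixed", dispersion=1e12
        )
        model = fit_structure(m, cfg)
        d = np.linalg.norm(model.coords[0] - model.coords[1])
        assert d == pytest.approx(1.0, abs=1e-6)  # mu = beta d^-3 = c at d=1

    def test_loglik_trace_monotone_and_above_init(self, helix_60):
        layout, truth = helix_60
        mat = synthetic.counts_from_structure(
            truth, NBParams(alpha=-3, beta=100.0, r=1e12), noise="none"
        )
        model = fit_structure(mat, InferenceConfig())
        trace = np.array(model.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert trace[-1] >= trace[0]

    def test_distances_anticorrelate_with_counts(self, helix_60):
        layout, truth = helix_60
        mat = synthetic.counts_from_structure(
            truth, NBParams(alpha=-3, beta=100.0, r=1e12), noise="exact"
        )
        model = fit_structure(mat, InferenceConfig())
        i, j, c = mat.pairs()
        off = i != j
        i, j, c = i[off] - 1, j[off] - 1, c[off]
        d = np.linalg.norm(model.coords[i] - model.coords[j], axis=1)
        assert spearmanr(d, c).statistic <= -0.95

    def test_poisson_special_case_matches_nb_on_poisson_data(self, helix_60):
        layout, truth = helix_60
        mat = synthetic.counts_from_structure(
            truth, NBParams(alpha=-3, beta=100.0, r=1e12), noise="poisson", seed=0
        )
        nb_fit = fit_structure(mat, InferenceConfig())
        po_fit = fit_structure(
            mat, InferenceConfig(dispersion_mode="fixed", dispersion=1e12)
        )
        from hic3d.stability import superpose_rmsd

        rmsd, _ = superpose_rmsd(nb_fit, po_fit)
        scale = np.sqrt(np.mean(np.sum(
            (nb_fit.coords - nb_fit.coords.mean(0)) ** 2, axis=1)))
        assert rmsd < 0.1 * scale

    def test_zero_marginal_beads_stay_unplaced(self):
        lay = line_layout(4)
        m = ContactMatrix.from_pairs(lay, [1, 2], [2, 3], [5.0, 5.0])
        model = fit_structure(m, InferenceConfig())
        assert model.placed[:3].all()
        assert not model.placed[3]
        assert model.status[3] == "missing"

    def test_empty_matrix_rejected(self):
        import scipy.sparse as sp

        lay = line_layout(3)
        m = ContactMatrix(lay, sp.csr_matrix((3, 3)))
        with pytest.raises(ValueError):
            fit_structure(m, InferenceConfig())
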