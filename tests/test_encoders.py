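"""Autoencoder building blocks: layers, losses, gradients, sampling."""

import numpy as np
import pytest

from vgaedti.autodiff import Tensor
from vgaedti.encoders import (
    GAE,
    VGAE,
    gae_forward,
    gae_loss,
    gcn_layer,
    kl_loss,
    recon_loss,
    reparameterize,
)
from vgaedti.hetnet import normalize_adjacency


def numeric_grad(f, x, h=1e-6):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        g[idx] = (f(xp) - f(xm)) / (2 * h)
    return g


def assert_grad_close(f_tensor, x0, rtol=1e-4):
    """Compare autodiff gradient of f at x0 with central differences."""
    leaf = Tensor(x0.copy(), requires_grad=True)
    out = f_tensor(leaf)
    out.backward()
    num = numeric_grad(lambda x: float(f_tensor(Tensor(x))), x0)
    denom = np.maximum(np.abs(num), 1e-3)
    assert np.max(np.abs(leaf.grad - num) / denom) < rtol


class TestGCNLayer:
    def test_identity_propagation(self):
        X = np.arange(6.0).reshape(3, 2)
        out = gcn_layer(X, np.eye(3), np.eye(2), "linear")
        assert np.array_equal(out.value, X)

    def test_zero_input_relu(self):
        out = gcn_layer(np.zeros((3, 2)), np.eye(3), np.ones((2, 2)), "relu")
        assert not out.value.any()

    def test_two_node_hand_product(self):
        A = np.full((2, 2), 0.5)
        out = gcn_layer(np.array([[1.0], [3.0]]), A, np.array([[1.0]]), "linear")
        assert np.allclose(out.value, [[2.0], [2.0]])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(np.zeros((3, 2)), np.eye(2), np.eye(2))


class TestReparameterize:
    def test_direct_substitution(self):
        assert float(reparameterize(np.array(2.0), np.array(3.0), np.array(1.0))) == 5.0

    def test_zero_eps_returns_mu(self, rng):
        mu = rng.standard_normal((4, 3))
        Z = reparameterize(mu, np.ones_like(mu), np.zeros_like(mu))
        assert np.array_equal(Z.value, mu)

    def test_linearity_in_mu(self, rng):
        mu = rng.standard_normal((2, 2))
        sig = np.abs(rng.standard_normal((2, 2)))
        eps = rng.standard_normal((2, 2))
        d = reparameterize(2 * mu, sig, eps).value - reparameterize(mu, sig, eps).value
        assert np.allclose(d, mu)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            reparameterize(np.zeros(2), np.array([1.0, -1.0]), np.zeros(2))


class TestLossValues:
    def test_gaussian_zero_at_equality(self, rng):
        X = rng.standard_normal((3, 3))
        assert float(recon_loss(X, X)) == 0.0

    def test_gaussian_frobenius_arithmetic(self):
        assert float(recon_loss(np.array([[1.0, 0]]), np.array([[3.0, 0]]))) == 2.0

    def test_bernoulli_positive_term(self):
        val = float(
            recon_loss(np.array([[1.0]]), np.array([[0.5]]), dist="bernoulli")
        )
        assert val == pytest.approx(-np.log(0.5))

    def test_bernoulli_rejects_out_of_range_predictions(self):
        with pytest.raises(ValueError, match="\\(0, 1\\)"):
            recon_loss(np.array([[1.0]]), np.array([[1.5]]), dist="bernoulli")

    def test_kl_zero_at_standard_normal(self):
        assert float(kl_loss(np.zeros((2, 3)), np.zeros((2, 3)))) == 0.0

    def test_kl_single_element_closed_form(self):
        assert float(kl_loss(np.array([[1.0]]), np.array([[0.0]]))) == 0.5

    def test_kl_increases_in_mean_magnitude(self):
        vals = [float(kl_loss(np.array([[m]]), np.zeros((1, 1)))) for m in (0.5, 1, 2)]
        assert vals[0] < vals[1] < vals[2]

    def test_kl_matches_monte_carlo_1d(self):
        """KL equals a brute-force E_q[log q - log p] estimate (1-D)."""
        mu, sigma = 0.7, 1.6
        rng = np.random.default_rng(99)
        z = rng.normal(mu, sigma, size=100_000)
        log_q = -0.5 * np.log(2 * np.pi * sigma**2) - (z - mu) ** 2 / (2 * sigma**2)
        log_p = -0.5 * np.log(2 * np.pi) - z**2 / 2
        est = log_q - log_p
        closed = float(kl_loss(np.array([[mu]]), np.array([[np.log(sigma)]])))
        assert abs(closed - est.mean()) < 3 * est.std() / np.sqrt(est.size)

    def test_gae_loss_positive_edge_contribution(self):
        A = np.array([[1.0]])
        assert float(
            gae_loss(A, np.array([[0.5]]), positive_only_ce=True)
        ) == pytest.approx(-np.log(0.5))

    def test_gae_loss_vanishes_at_perfect_reconstruction(self):
        A = np.array([[1.0, 0.0]])
        val = float(gae_loss(A, np.array([[1 - 1e-9, 1e-9]])))
        assert val < 1e-5

    def test_gae_loss_monotone_in_edge_confidence(self):
        A = np.array([[1.0]])
        losses = [float(gae_loss(A, np.array([[p]]))) for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]


class TestVGAEForward:
    def _setup(self, rng, n=5, hidden=4, latent=3):
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        A_norm = Tensor(normalize_adjacency(A).A_norm)
        X = Tensor(rng.random((n, n)))
        model = VGAE(n, hidden, latent, rng)
        return model, X, A_norm

    def test_no_sampling_gives_mu(self, rng):
        model, X, A_norm = self._setup(rng)
        mu, _, Z = model.encode(X, A_norm, eps=None)
        assert np.array_equal(mu.value, Z.value)

    def test_forward_deterministic_without_eps(self, rng):
        model, X, A_norm = self._setup(rng)
        out1 = model.decode(model.encode(X, A_norm, eps=None)[2]).value
        out2 = model.decode(model.encode(X, A_norm, eps=None)[2]).value
        assert np.array_equal(out1, out2)

    def test_decoder_affine_evaluation(self, rng):
        model = VGAE(1, 2, 1, rng)
        model.params["W_dec"].value = np.array([[2.0]])
        model.params["b_dec"].value = np.array([1.0])
        assert float(model.decode(Tensor(np.array([[3.0]]))).value[0, 0]) == 7.0

    def test_decode_output_shape_matches_input_space(self, rng):
        model, X, A_norm = self._setup(rng)
        _, _, Z = model.encode(X, A_norm, eps=np.zeros((5, 3)))
        assert model.decode(Z).shape == X.shape


class TestGAEForward:
    def test_inner_product_decoder_values(self, rng):
        model = GAE(4, 3, 1, rng)
        Zp = Tensor(np.array([[2.0]]))
        Zr = Tensor(np.array([[1.0]]))
        A_hat = (Zp @ Zr.T).sigmoid()
        assert A_hat.value[0, 0] == pytest.approx(1 / (1 + np.exp(-2.0)))

    def test_orthogonal_embeddings_score_half(self, rng):
        n = 6
        A = np.zeros((3, 3))
        model = GAE(n, 4, 2, rng)
        for p in model.params.values():
            p.value = np.zeros_like(p.value)  # forces Z = 0, logits 0
        A_norm = Tensor(np.eye(n))
        X = Tensor(np.ones((n, n)))
        _, _, A_hat = gae_forward(A, A_norm, X, model, [0, 1, 2], [3, 4, 5])
        assert np.allclose(A_hat.value, 0.5)


class TestGradients:
    """Every loss term matches central finite differences on tiny networks."""

    n, hidden, latent = 6, 4, 3

    @pytest.fixture()
    def graph(self, rng):
        A = (rng.random((self.n, self.n)) < 0.5).astype(float)
        A = np.maximum(A, A.T)
        np.fill_diagonal(A, 0)
        return normalize_adjacency(A).A_norm, rng.random((self.n, self.n))

    def test_gaussian_recon_grad(self, rng, graph):
        X = rng.standard_normal((4, 5))
        assert_grad_close(lambda t: recon_loss(X, t), rng.standard_normal((4, 5)))

    def test_bernoulli_recon_grad(self, rng):
        X = (rng.random((3, 4)) < 0.5).astype(float)
        X_hat0 = rng.uniform(0.2, 0.8, size=(3, 4))
        assert_grad_close(lambda t: recon_loss(X, t, dist="bernoulli"), X_hat0)

    def test_kl_grad(self, rng):
        mu0 = rng.standard_normal((3, 3))
        ls0 = rng.uniform(-1, 1, size=(3, 3))
        assert_grad_close(lambda t: kl_loss(t, ls0), mu0)
        assert_grad_close(lambda t: kl_loss(mu0, t), ls0)

    def test_gae_loss_grad_through_decoder(self, rng):
        A = (rng.random((3, 2)) < 0.5).astype(float)
        Zr = rng.standard_normal((2, self.latent))

        def f(t):
            A_hat = (t @ Tensor(Zr).T).sigmoid().clip(1e-7, 1 - 1e-7)
            return gae_loss(A, A_hat)

        assert_grad_close(f, rng.standard_normal((3, self.latent)))

    @pytest.mark.parametrize("wname", ["W_hidden", "W_mu", "W_logsig", "W_dec"])
    def test_full_vgae_objective_grad(self, rng, graph, wname):
        """End-to-end gradient through encoder, sampling, decoder and KL."""
        A_norm, X = graph
        model = VGAE(self.n, self.hidden, self.latent, rng)
        eps = rng.standard_normal((self.n, self.latent))
        w0 = model.params[wname].value.copy()

        def f(t):
            model.params[wname] = t
            mu, ls, Z = model.encode(X, A_norm, eps)
            return recon_loss(X, model.decode(Z)) + kl_loss(mu, ls)

        try:
            assert_grad_close(f, w0)
        finally:
            model.params[wname] = Tensor(w0, requires_grad=True)

    @pytest.mark.parametrize("wname", ["W1", "W2"])
    def test_full_gae_objective_grad(self, rng, graph, wname):
        A_norm, X = graph
        A = (rng.random((3, 3)) < 0.5).astype(float)
        model = GAE(self.n, self.hidden, self.latent, rng)
        w0 = model.params[wname].value.copy()

        def f(t):
            model.params[wname] = t
            _, _, A_hat = gae_forward(A, A_norm, X, model, [0, 1, 2], [3, 4, 5])
            return gae_loss(A, A_hat)

        try:
            assert_grad_close(f, w0)
        finally:
            model.params[wname] = Tensor(w0, requires_grad=True)
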