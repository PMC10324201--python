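"""Graph-convolutional autoencoders: the variational feature-inference
encoder (VGAE) and the deterministic label-propagation encoder (GAE).

Both operate on the full heterogeneous network: each layer computes
sigma(A_norm @ X @ W) with A_norm the symmetrically normalized adjacency.
The VGAE has a shared leaky-ReLU hidden layer feeding linear mu / log-sigma GCN
heads, a reparameterized sample Z = mu + sigma * eps, and a dense decoder
mapping latents back to the node feature space. The GAE stacks two GCN
layers (leaky ReLU then linear) and reconstructs the drug-target association
block through a logistic inner-product decoder between target-row and
drug-row embeddings.

All losses are differentiable through :mod:`vgaedti.autodiff`; they accept
plain arrays or Tensors and return a Tensor (use ``float()`` for the value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor

EPS_CLIP = 1e-7  # probability clamp inside all log terms


@dataclass
class LossBreakdown:
    recon: float
    kl: float
    total: float


def glorot(shape, rng) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def gcn_layer(X, A_norm, W, activation="relu"):
    """One graph convolution: activation(A_norm @ X @ W)."""
    X, A_norm, W = as_tensor(X), as_tensor(A_norm), as_tensor(W)
    if A_norm.shape[1] != X.shape[0] or X.shape[1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: A_norm {A_norm.shape}, X {X.shape}, W {W.shape}"
        )
    out = A_norm @ X @ W
    if activation == "relu":
        return out.relu()
    if activation == "leaky_relu":
        return out.leaky_relu()
    if activation == "linear":
        return out
    if activation == "sigmoid":
        return out.sigmoid()
    raise ValueError(f"unknown activation {activation!r}")


def reparameterize(mu, sigma, eps):
    """Z = mu + sigma * eps (elementwise); sigma must be positive."""
    mu, sigma, eps = as_tensor(mu), as_tensor(sigma), as_tensor(eps)
    if (sigma.value < 0).any():
        raise ValueError("sigma must be nonnegative (it is exp(log_sigma))")
    return mu + sigma * eps


def recon_loss(X, X_hat, dist: str = "gaussian", positive_only_ce: bool = False):
    """Reconstruction error.

    gaussian: (1/2) ||X - X_hat||_F^2. bernoulli: full binary cross-entropy
    -sum[X log X_hat + (1-X) log(1-X_hat)] by default; ``positive_only_ce``
    keeps only the positive term.
    """
    X, X_hat = as_tensor(X), as_tensor(X_hat)
    if X.shape != X_hat.shape:
        raise ValueError("X and X_hat shapes differ")
    if dist == "gaussian":
        return 0.5 * (X - X_hat).square().sum()
    if dist == "bernoulli":
        v = X.value
        if v.min() < 0 or v.max() > 1:
            raise ValueError("bernoulli targets must lie in [0, 1]")
        if (X_hat.value <= 0).any() or (X_hat.value >= 1).any():
            raise ValueError("bernoulli predictions must lie in (0, 1)")
        P = X_hat.clip(EPS_CLIP, 1 - EPS_CLIP)
        loss = -(X * P.log()).sum()
        if not positive_only_ce:
            loss = loss - ((1.0 - X) * (1.0 - P).log()).sum()
        return loss
    raise ValueError("dist must be 'gaussian' or 'bernoulli'")


def kl_loss(mu, log_sigma):
    """KL(q || N(0, I)) summed over all latent entries.

    sum_ij (1/2) (mu^2 + sigma^2 - 1 - 2 log sigma); zero exactly when
    mu = 0 and sigma = 1.
    """
    mu, log_sigma = as_tensor(mu), as_tensor(log_sigma)
    sigma2 = (2.0 * log_sigma).exp()
    return 0.5 * (mu.square() + sigma2 - 1.0 - 2.0 * log_sigma).sum()


def gae_loss(A_pr, A_pr_hat, positive_only_ce: bool = False):
    """Association reconstruction error (binary cross-entropy by default)."""
    return recon_loss(A_pr, A_pr_hat, dist="bernoulli", positive_only_ce=positive_only_ce)


class VGAE:
    """Variational graph autoencoder over the heterogeneous network.

    Encoder: shared leaky-ReLU GCN hidden layer, then parallel linear GCN heads
    for mu and log sigma. Decoder: dense affine layer (latent -> feature
    width), linear for Gaussian feature reconstruction.
    """

    def __init__(self, n_features, hidden, latent, rng, recon_dist="gaussian",
                 hidden_activation="leaky_relu"):
        self.recon_dist = recon_dist
        self.hidden_activation = hidden_activation
        self.params = {
            "W_hidden": Tensor(glorot((n_features, hidden), rng), requires_grad=True),
            "W_mu": Tensor(glorot((hidden, latent), rng), requires_grad=True),
            "W_logsig": Tensor(glorot((hidden, latent), rng), requires_grad=True),
            "W_dec": Tensor(glorot((latent, n_features), rng), requires_grad=True),
            "b_dec": Tensor(np.zeros(n_features), requires_grad=True),
        }
        self.latent = latent

    def encode(self, X, A_norm, eps=None):
        """Returns (mu, log_sigma, Z). ``eps=None`` disables sampling (Z=mu)."""
        h = gcn_layer(X, A_norm, self.params["W_hidden"], self.hidden_activation)
        if not np.isfinite(h.value).all():
            raise FloatingPointError("non-finite activations in hidden layer 1")
        mu = gcn_layer(h, A_norm, self.params["W_mu"], "linear")
        log_sigma = gcn_layer(h, A_norm, self.params["W_logsig"], "linear")
        # clamp keeps exp() finite early in training
        log_sigma = log_sigma.clip(-10.0, 10.0)
        for name, t in (("mu", mu), ("log_sigma", log_sigma)):
            if not np.isfinite(t.value).all():
                raise FloatingPointError(f"non-finite activations in {name} head")
        if eps is None:
            Z = mu
        else:
            Z = reparameterize(mu, log_sigma.exp(), eps)
        return mu, log_sigma, Z

    def decode(self, Z):
        out = as_tensor(Z) @ self.params["W_dec"] + self.params["b_dec"]
        if self.recon_dist == "bernoulli":
            return out.sigmoid()
        return out


class GAE:
    """Deterministic graph autoencoder for label propagation.

    Two stacked GCN layers (leaky ReLU, then linear) produce node embeddings;
    the decoder scores a (target, drug) pair as
    logistic(<Z'_p[i], Z'_r[j]>), reconstructing the DTI block.
    """

    def __init__(self, n_features, hidden, latent, rng, hidden_activation="leaky_relu"):
        self.hidden_activation = hidden_activation
        self.params = {
            "W1": Tensor(glorot((n_features, hidden), rng), requires_grad=True),
            "W2": Tensor(glorot((hidden, latent), rng), requires_grad=True),
        }
        self.latent = latent

    def encode(self, X, A_norm):
        h = gcn_layer(X, A_norm, self.params["W1"], self.hidden_activation)
        return gcn_layer(h, A_norm, self.params["W2"], "linear")


def gae_forward(A_pr, A_norm, X, model: GAE, target_rows, drug_rows):
    """Full GAE pass: embeddings for target/drug rows plus the
    reconstructed association block.

    Returns (Z_p_prime, Z_r_prime, A_pr_hat) with
    A_pr_hat[i, j] = logistic(<Z'_p[i], Z'_r[j]>) in (0, 1).
    """
    Z = model.encode(X, A_norm)
    Zp = Z[np.asarray(target_rows)]
    Zr = Z[np.asarray(drug_rows)]
    A_hat = (Zp @ Zr.T).sigmoid().clip(EPS_CLIP, 1 - EPS_CLIP)
    A_pr = np.asarray(as_tensor(A_pr).value)
    if A_hat.shape != A_pr.shape:
        raise ValueError("A_pr shape does not match embedding blocks")
    return Zp, Zr, A_hat
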