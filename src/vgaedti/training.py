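"""Alternating variational-EM training of the two autoencoders.

The E-step updates the variational encoders (one view reading out target
rows, one reading out drug rows) to minimize the weighted reconstruction +
KL objective plus a latent-alignment term that pulls the variational
latents toward the label-propagation embeddings. The M-step updates the
GAE to minimize the association reconstruction loss plus the same
alignment term with the variational latents frozen. An optional
co-training term enforces that the fused embeddings still reconstruct the
input features. Optimization is Adam on the dense full-graph computation
graph; everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor
from .encoders import GAE, VGAE, gae_forward, gae_loss, kl_loss, recon_loss
from .hetnet import HeterogeneousNetwork, node_features, normalize_adjacency


@dataclass
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 0.1
    weight_decay: float = 1e-8
    hidden_size: int = 256
    latent_dim: int = 64
    alpha: float = 0.5
    beta: float = 0.5
    em_switch_every: int = 1
    seed: int = 0
    co_training: bool = True
    align_weight: float = 1.0
    embedding_source: str = "mean"  # vgae | gae | mean
    early_stop_tol: float = 1e-6
    early_stop_patience: int = 20

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.beta < 1.0):
            raise ValueError("beta must lie in (0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.embedding_source not in ("vgae", "gae", "mean"):
            raise ValueError("embedding_source must be vgae, gae or mean")


@dataclass
class TrainState:
    config: TrainConfig
    vgae_p: VGAE
    vgae_r: VGAE
    gae: GAE
    history: list
    Y_p: np.ndarray
    Y_r: np.ndarray
    target_ids: list[str]
    drug_ids: list[str]

    def weights(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, model in (
            ("vgae_p", self.vgae_p),
            ("vgae_r", self.vgae_r),
            ("gae", self.gae),
        ):
            for name, t in model.params.items():
                out[f"{prefix}.{name}"] = t.value
        return out


def em_alignment_loss(Z, Z_prime):
    """(1/2) ||Z - Z'||_F^2 between the two encoders' latents."""
    Z, Z_prime = as_tensor(Z), as_tensor(Z_prime)
    if Z.shape != Z_prime.shape:
        raise ValueError("latent shapes differ between encoders")
    return 0.5 * (Z - Z_prime).square().sum()


def cotraining_loss(Y_p, X_p, Y_r, X_r):
    """(1/2) ||Y_p - X_p||_F^2 + (1/2) ||Y_r - X_r||_F^2."""
    Y_p, X_p, Y_r, X_r = map(as_tensor, (Y_p, X_p, Y_r, X_r))
    if Y_p.shape != X_p.shape or Y_r.shape != X_r.shape:
        raise ValueError("co-training operand shapes differ")
    return 0.5 * (Y_p - X_p).square().sum() + 0.5 * (Y_r - X_r).square().sum()


def total_vgae_loss(L_pVGAE, L_rVGAE, L_KL, alpha, beta):
    """alpha * L_pVGAE + (1 - alpha) * L_rVGAE + beta * L_KL."""
    if not (0.0 < alpha < 1.0) or not (0.0 < beta < 1.0):
        raise ValueError("alpha and beta must lie in (0, 1)")
    return alpha * as_tensor(L_pVGAE) + (1.0 - alpha) * as_tensor(L_rVGAE) + beta * as_tensor(L_KL)


def total_gae_loss(L_pGAE, L_rGAE, alpha):
    """alpha * L_pGAE + (1 - alpha) * L_rGAE."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha * as_tensor(L_pGAE) + (1.0 - alpha) * as_tensor(L_rGAE)


class Adam:
    """Classic Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _epoch_losses(net, X, A_norm, vgae_p, vgae_r, gae, cfg, eps_p, eps_r, step):
    """Build the loss graph for one epoch.

    ``step`` is "E" (GAE latents frozen) or "M" (VGAE latents frozen).
    Returns (objective Tensor, record dict).
    """
    p_rows, r_rows = net.target_rows, net.drug_rows
    X_p, X_r = X.value[p_rows], X.value[r_rows]
    A_pr = net.A_pr

    mu_p, logsig_p, Z_p = vgae_p.encode(X, A_norm, eps_p)
    mu_r, logsig_r, Z_r = vgae_r.encode(X, A_norm, eps_r)
    Zp_v, Zr_v = Z_p[p_rows], Z_r[r_rows]
    Xhat_p = vgae_p.decode(Zp_v)
    Xhat_r = vgae_r.decode(Zr_v)
    L_p = recon_loss(X_p, Xhat_p, dist=vgae_p.recon_dist)
    L_r = recon_loss(X_r, Xhat_r, dist=vgae_r.recon_dist)
    L_KL = kl_loss(mu_p[p_rows], logsig_p[p_rows]) + kl_loss(
        mu_r[r_rows], logsig_r[r_rows]
    )
    L_vgae = total_vgae_loss(L_p, L_r, L_KL, cfg.alpha, cfg.beta)

    Zp_g, Zr_g, A_hat = gae_forward(A_pr, A_norm, X, gae, p_rows, r_rows)
    L_gae_recon = gae_loss(A_pr, A_hat)
    # the shared inner-product decoder makes the drug-space reconstruction
    # error identical to the target-space one
    L_gae = total_gae_loss(L_gae_recon, L_gae_recon, cfg.alpha)

    if step == "E":
        Zp_g_a, Zr_g_a = Zp_g.detach(), Zr_g.detach()
        Zp_v_a, Zr_v_a = Zp_v, Zr_v
        objective_core = L_vgae
    else:
        Zp_g_a, Zr_g_a = Zp_g, Zr_g
        Zp_v_a, Zr_v_a = Zp_v.detach(), Zr_v.detach()
        objective_core = L_gae
    L_align = em_alignment_loss(Zp_v_a, Zp_g_a) + em_alignment_loss(
        Zr_v_a, Zr_g_a
    )
    objective = objective_core + cfg.align_weight * L_align

    L_cot = None
    if cfg.co_training:
        if step == "E":
            Y_p = 0.5 * (mu_p[p_rows] + Zp_g.detach())
            Y_r = 0.5 * (mu_r[r_rows] + Zr_g.detach())
        else:
            Y_p = 0.5 * (mu_p[p_rows].detach() + Zp_g)
            Y_r = 0.5 * (mu_r[r_rows].detach() + Zr_g)
        L_cot = cotraining_loss(
            vgae_p.decode(Y_p), X_p, vgae_r.decode(Y_r), X_r
        )
        objective = objective + L_cot

    record = {
        "step": step,
        "L_pVGAE": float(L_p),
        "L_rVGAE": float(L_r),
        "L_KL": float(L_KL),
        "total_vgae": float(L_vgae),
        "L_pGAE": float(L_gae_recon),
        "L_rGAE": float(L_gae_recon),
        "total_gae": float(L_gae),
        "align": float(L_align),
        "cotrain": float(L_cot) if L_cot is not None else 0.0,
        "objective": float(objective),
    }
    return objective, record


def fit(net: HeterogeneousNetwork, config: TrainConfig | None = None) -> TrainState:
    """Train both autoencoders on a heterogeneous network.

    Alternates E-epochs (variational encoders updated, GAE frozen) and
    M-epochs (GAE updated, variational latents frozen) every
    ``em_switch_every`` epochs; stops early once the combined objective
    changes by less than ``early_stop_tol`` for ``early_stop_patience``
    consecutive epochs. Returns the trained weights, the per-epoch loss
    history, and the final drug/target embeddings.
    """
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    A_norm = Tensor(normalize_adjacency(net.H).A_norm)
    X = Tensor(node_features(net, "joint").X)
    n_feat = X.shape[1]

    vgae_p = VGAE(n_feat, cfg.hidden_size, cfg.latent_dim, rng)
    vgae_r = VGAE(n_feat, cfg.hidden_size, cfg.latent_dim, rng)
    gae = GAE(n_feat, cfg.hidden_size, cfg.latent_dim, rng)

    opt_vgae = Adam(
        list(vgae_p.params.values()) + list(vgae_r.params.values()),
        cfg.learning_rate,
        cfg.weight_decay,
    )
    opt_gae = Adam(list(gae.params.values()), cfg.learning_rate, cfg.weight_decay)

    history = []
    prev_total, stall = None, 0
    n_p, n_r = net.n_targets, net.n_drugs
    for epoch in range(cfg.epochs):
        step = "E" if (epoch // max(cfg.em_switch_every, 1)) % 2 == 0 else "M"
        eps_p = rng.standard_normal((X.shape[0], cfg.latent_dim))
        eps_r = rng.standard_normal((X.shape[0], cfg.latent_dim))
        objective, record = _epoch_losses(
            net, X, A_norm, vgae_p, vgae_r, gae, cfg, eps_p, eps_r, step
        )
        if not np.isfinite(record["objective"]):
            bad = [k for k, v in record.items() if k != "step" and not np.isfinite(v)]
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (non-finite: {bad})"
            )
        opt = opt_vgae if step == "E" else opt_gae
        opt.zero_grad()
        objective.backward()
        opt.step()
        record["epoch"] = epoch
        history.append(record)

        total = record["objective"]
        if prev_total is not None and abs(total - prev_total) < cfg.early_stop_tol:
            stall += 1
            if stall >= cfg.early_stop_patience:
                break
        else:
            stall = 0
        prev_total = total

    # final deterministic embeddings (mu, no sampling)
    mu_p, _, _ = vgae_p.encode(X, A_norm, eps=None)
    mu_r, _, _ = vgae_r.encode(X, A_norm, eps=None)
    Zg = gae.encode(X, A_norm)
    Yp_v, Yr_v = mu_p.value[net.target_rows], mu_r.value[net.drug_rows]
    Yp_g, Yr_g = Zg.value[net.target_rows], Zg.value[net.drug_rows]
    if cfg.embedding_source == "vgae":
        Y_p, Y_r = Yp_v, Yr_v
    elif cfg.embedding_source == "gae":
        Y_p, Y_r = Yp_g, Yr_g
    else:
        Y_p, Y_r = (Yp_v + Yp_g) / 2.0, (Yr_v + Yr_g) / 2.0
    return TrainState(
        cfg,
        vgae_p,
        vgae_r,
        gae,
        history,
        Y_p,
        Y_r,
        list(net.target_ids),
        list(net.drug_ids),
    )
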