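"""Synthetic drug-target-disease data with planted low-rank structure.

The generator draws latent factor vectors for targets (U), drugs (V) and
diseases (W) from a seeded Gaussian and samples every association block
from Bernoulli(sigmoid(factor product + bias)), with the bias calibrated
by bisection so the realized edge density matches the requested one.
Surface data carry the same latent signal the model is meant to exploit:

* fingerprints — each drug's bits are Bernoulli with probabilities given
  by a fixed random projection of its factor vector, so fingerprint cosine
  similarity tracks latent proximity;
* protein sequences — targets are clustered on their factors; each
  cluster gets an ancestor sequence and members are point-mutated at a
  rate growing with their distance from the cluster centre, so local
  alignment similarity also tracks latent proximity.

A fraction of true interactions can be masked out as a held-out test set
for recovery benchmarks; label noise flips observed association entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import AssociationMatrix, HeterogeneousNetwork, build_heterogeneous_adjacency
from .similarity import (
    FingerprintMatrix,
    SequenceSet,
    SimilarityMatrix,
    SWParams,
    cosine_similarity,
    normalize_sw,
    smith_waterman_matrix,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    n_drugs: int = 60
    n_targets: int = 80
    n_diseases: int = 30
    latent_rank: int = 8
    edge_density: float = 0.08
    noise_flip_rate: float = 0.02
    signal_strength: float = 8.0  # scale of the planted association logits
    fingerprint_bits: int = 256
    sequence_length_range: tuple[int, int] = (80, 120)
    n_seq_clusters: int = 8
    test_fraction: float = 0.0  # fraction of DTI positives masked as test
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_targets, self.n_diseases) < 2:
            raise ValueError("entity counts must be >= 2")
        if not 0.0 < self.edge_density < 1.0:
            raise ValueError("edge_density must lie in (0, 1)")
        if not 0.0 <= self.noise_flip_rate < 0.5:
            raise ValueError("noise_flip_rate must lie in [0, 0.5)")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in [0, 1)")


@dataclass
class SynthTruth:
    U: np.ndarray  # targets x r
    V: np.ndarray  # drugs x r
    W: np.ndarray  # diseases x r
    P: np.ndarray  # true DTI probability matrix, targets x drugs
    A_pr_full: np.ndarray  # clean sampled associations, before masking/noise
    test_mask: np.ndarray  # masked-out positives (targets x drugs bool)

    def eval_cells(self, A_pr_train) -> np.ndarray:
        """Cells a recovery benchmark scores: masked positives plus pairs
        unknown in both the clean truth and the observed training block."""
        A_pr_train = np.asarray(A_pr_train)
        return self.test_mask | ((self.A_pr_full == 0) & (A_pr_train == 0))


@dataclass
class SynthData:
    fingerprints: FingerprintMatrix
    sequences: SequenceSet
    S_r: SimilarityMatrix
    S_p: SimilarityMatrix
    A_pr: AssociationMatrix  # training block (test positives masked)
    A_dp: AssociationMatrix
    A_dr: AssociationMatrix
    truth: SynthTruth
    config: SynthConfig

    def network(self) -> HeterogeneousNetwork:
        return build_heterogeneous_adjacency(
            self.S_p, self.S_r, self.A_pr, self.A_dp, self.A_dr
        )


def _calibrated_probs(logits, density):
    """sigmoid(logits + b) with b bisected so the mean equals ``density``."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))) < density:
            lo = mid
        else:
            hi = mid
    p = 1.0 / (1.0 + np.exp(-(logits + (lo + hi) / 2.0)))
    return np.clip(p, 1e-9, 1 - 1e-9)


def _sample_block(F1, F2, density, rng, flip_rate, scale=3.0):
    logits = scale * F1 @ F2.T / np.sqrt(F1.shape[1])
    P = _calibrated_probs(logits, density)
    A = (rng.random(P.shape) < P).astype(int)
    if flip_rate > 0:
        flips = rng.random(P.shape) < flip_rate
        A = np.where(flips, 1 - A, A)
    return A, P


def _latent_fingerprints(V, bits, rng):
    proj = rng.standard_normal((V.shape[1], bits))
    probs = _calibrated_probs(V @ proj / np.sqrt(V.shape[1]), 0.25)
    F = (rng.random(probs.shape) < probs).astype(int)
    # guarantee no all-zero row (cosine similarity requires it)
    empty = F.sum(axis=1) == 0
    if empty.any():
        F[empty, rng.integers(bits, size=int(empty.sum()))] = 1
    return F


def _latent_sequences(U, cfg: SynthConfig, rng):
    """Cluster targets on factors; mutate each cluster ancestor per member."""
    n, r = U.shape
    k = min(cfg.n_seq_clusters, n)
    centers = U[rng.choice(n, size=k, replace=False)]
    assign = np.argmin(
        ((U[:, None, :] - centers[None, :, :]) ** 2).sum(-1), axis=1
    )
    lo, hi = cfg.sequence_length_range
    ancestors = [
        "".join(rng.choice(list(AA20), size=rng.integers(lo, hi + 1)))
        for _ in range(k)
    ]
    dist = np.sqrt(((U - centers[assign]) ** 2).sum(-1))
    rate = 0.05 + 0.4 * dist / (dist.max() + 1e-12)  # per-site mutation rate
    seqs = []
    for i in range(n):
        base = list(ancestors[assign[i]])
        mut = rng.random(len(base)) < rate[i]
        for j in np.flatnonzero(mut):
            base[j] = AA20[rng.integers(20)]
        seqs.append("".join(base))
    return seqs


def generate(config: SynthConfig) -> SynthData:
    """Draw a full synthetic input bundle; bit-reproducible from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    U = rng.standard_normal((cfg.n_targets, cfg.latent_rank))
    V = rng.standard_normal((cfg.n_drugs, cfg.latent_rank))
    W = rng.standard_normal((cfg.n_diseases, cfg.latent_rank))

    s = cfg.signal_strength
    # clean draws; observation noise is applied to the training copies below
    A_pr_full, P = _sample_block(U, V, cfg.edge_density, rng, 0.0, s)
    A_dp, _ = _sample_block(W, U, cfg.edge_density, rng, cfg.noise_flip_rate, s)
    A_dr, _ = _sample_block(W, V, cfg.edge_density, rng, cfg.noise_flip_rate, s)

    test_mask = np.zeros_like(A_pr_full, dtype=bool)
    if cfg.test_fraction > 0:
        pos = np.flatnonzero(A_pr_full.ravel() == 1)
        n_test = int(round(cfg.test_fraction * pos.size))
        chosen = rng.choice(pos, size=n_test, replace=False)
        test_mask.ravel()[chosen] = True
    A_pr_train = np.where(test_mask, 0, A_pr_full)
    if cfg.noise_flip_rate > 0:
        # flip observed entries only outside the held-out cells, so noise
        # can never re-introduce a masked positive
        flips = (rng.random(A_pr_train.shape) < cfg.noise_flip_rate) & ~test_mask
        A_pr_train = np.where(flips, 1 - A_pr_train, A_pr_train)

    target_ids = [f"P{i:04d}" for i in range(cfg.n_targets)]
    drug_ids = [f"D{i:04d}" for i in range(cfg.n_drugs)]
    disease_ids = [f"M{i:04d}" for i in range(cfg.n_diseases)]

    F = FingerprintMatrix(
        _latent_fingerprints(V, cfg.fingerprint_bits, rng), drug_ids
    )
    seqs = SequenceSet(_latent_sequences(U, cfg, rng), target_ids)
    S_r = cosine_similarity(F)
    S_p = normalize_sw(
        smith_waterman_matrix(seqs, SWParams(match=2.0, mismatch=-1.0, gap=-1.0))
    )

    return SynthData(
        fingerprints=F,
        sequences=seqs,
        S_r=S_r,
        S_p=S_p,
        A_pr=AssociationMatrix(A_pr_train, target_ids, drug_ids, "target-drug"),
        A_dp=AssociationMatrix(A_dp, disease_ids, target_ids, "disease-target"),
        A_dr=AssociationMatrix(A_dr, disease_ids, drug_ids, "disease-drug"),
        truth=SynthTruth(U, V, W, P, A_pr_full, test_mask),
        config=cfg,
    )


REFERENCE_SEED = 20240601


def reference_benchmark() -> SynthData:
    """The canonical recovery fixture.

    60 drugs x 80 targets x 30 diseases, latent rank 8, edge density 0.08,
    2% label flips, fixed seed, with 20% of the true interactions masked
    out as the held-out test set.
    """
    return generate(
        SynthConfig(
            n_drugs=60,
            n_targets=80,
            n_diseases=30,
            latent_rank=8,
            edge_density=0.08,
            noise_flip_rate=0.02,
            test_fraction=0.20,
            seed=REFERENCE_SEED,
        )
    )


def null_benchmark(seed: int = 0, n_drugs=25, n_targets=30, n_diseases=10) -> SynthData:
    """A structureless control: associations independent of every feature."""
    data = generate(
        SynthConfig(
            n_drugs=n_drugs,
            n_targets=n_targets,
            n_diseases=n_diseases,
            latent_rank=4,
            edge_density=0.15,
            noise_flip_rate=0.0,
            seed=seed,
        )
    )
    rng = np.random.default_rng(seed + 1)
    # overwrite every association block with pure coin flips
    for block in (data.A_pr, data.A_dp, data.A_dr):
        block.values = (rng.random(block.values.shape) < 0.15).astype(int)
    data.truth.A_pr_full = data.A_pr.values.copy()
    data.truth.P = np.full_like(data.truth.P, 0.15)
    return data
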