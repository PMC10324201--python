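"""Drug-drug and target-target similarity matrices.

Drug similarity is the cosine similarity between binary structure
fingerprints (ECFP-style bit vectors). Target similarity comes from
Smith-Waterman local-alignment scores, min-max normalized row-wise and then
symmetrized. Auxiliary similarity channels (side-effect profiles, protein
domains) are fused in by a weighted elementwise mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class FingerprintMatrix:
    """Binary fingerprint bits, one row per drug."""

    values: np.ndarray
    drug_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("fingerprint matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("fingerprint entries must be binary")
        if len(self.drug_ids) != self.values.shape[0]:
            raise ValueError("drug_ids length must match row count")


@dataclass
class SequenceSet:
    """Amino-acid sequences (20-letter alphabet plus X), one per target."""

    sequences: list[str]
    protein_ids: list[str]

    def __post_init__(self):
        if len(self.sequences) != len(self.protein_ids):
            raise ValueError("protein_ids length must match sequence count")
        for pid, seq in zip(self.protein_ids, self.sequences):
            if not seq:
                raise ValueError(f"empty sequence for protein {pid!r}")
            bad = set(seq.upper()) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {pid!r} contains non-amino-acid letters {sorted(bad)}"
                )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity class, entries in [0, 1]."""

    values: np.ndarray
    entity_ids: list[str]
    kind: str  # "drug" or "target"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.entity_ids)
        if self.values.shape != (k, k):
            raise ValueError("similarity matrix shape must match entity_ids")

    def validate(self, atol: float = 1e-8) -> None:
        if not np.allclose(self.values, self.values.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -atol or self.values.max() > 1 + atol:
            raise ValueError("similarity entries outside [0, 1]")


@dataclass
class RawScoreMatrix:
    """Unnormalized Smith-Waterman scores (nonnegative, symmetric)."""

    values: np.ndarray
    protein_ids: list[str]


@dataclass
class SWParams:
    """Smith-Waterman scoring scheme.

    Two modes: a substitution-matrix mode with affine gaps (default
    BLOSUM62, open 10 / extend 1 — the usual protein local-alignment
    setting) or, when ``match`` is set, a simple match/mismatch scheme
    with a linear gap penalty.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    match: float | None = None
    mismatch: float = -1.0
    gap: float = -1.0
    include_diagonal: bool = False  # whether self-scores enter row min/max


def cosine_similarity(F: FingerprintMatrix) -> SimilarityMatrix:
    """Pairwise cosine similarity between fingerprint rows.

    S[i, j] = (F_i . F_j) / (||F_i|| ||F_j||). With binary inputs all
    entries lie in [0, 1] and the diagonal is exactly 1.
    """
    norms = np.linalg.norm(F.values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            "all-zero fingerprint row(s) for drug id(s): "
            + ", ".join(F.drug_ids[i] for i in zero)
        )
    S = _sk_cosine(F.values)
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(S, list(F.drug_ids), kind="drug")


def _make_aligner(scoring: SWParams):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if scoring.match is not None:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
        aligner.open_gap_score = scoring.gap
        aligner.extend_gap_score = scoring.gap
    else:
        aligner.substitution_matrix = Align.substitution_matrices.load(
            scoring.matrix
        )
        aligner.open_gap_score = -abs(scoring.gap_open)
        aligner.extend_gap_score = -abs(scoring.gap_extend)
    return aligner


def smith_waterman_matrix(
    P: SequenceSet, scoring: SWParams | None = None
) -> RawScoreMatrix:
    """All-vs-all Smith-Waterman local alignment scores.

    Scores are the optimal local-alignment DP maxima, hence nonnegative
    and symmetric; the diagonal holds self-alignment scores.
    """
    scoring = scoring or SWParams()
    aligner = _make_aligner(scoring)
    m = len(P.sequences)
    sw = np.zeros((m, m))
    seqs = [s.upper() for s in P.sequences]
    if scoring.match is None:
        alphabet = set(str(aligner.substitution_matrix.alphabet))
        for pid, s in zip(P.protein_ids, seqs):
            bad = set(s) - alphabet
            if bad:
                raise ValueError(
                    f"no substitution score for residue(s) {sorted(bad)} in {pid!r}"
                )
    for i in range(m):
        for j in range(i, m):
            sw[i, j] = sw[j, i] = aligner.score(seqs[i], seqs[j])
    return RawScoreMatrix(sw, list(P.protein_ids))


def normalize_sw(
    sw: RawScoreMatrix, include_diagonal: bool = False, symmetrize: bool = True
) -> SimilarityMatrix:
    """Row-wise min-max normalization of raw alignment scores.

    S_p[i, j] = (sw[i, j] - min(sw_i)) / (max(sw_i) - min(sw_i)), where the
    row extrema are by default taken over off-diagonal entries only
    (self-alignment scores dominate and would compress the scale). The
    row-normalized matrix is asymmetric, so it is symmetrized by averaging
    with its transpose; pass ``symmetrize=False`` to inspect the
    intermediate.
    """
    V = np.asarray(sw.values, dtype=float)
    m = V.shape[0]
    if m < 2:
        raise ValueError("need at least two sequences to normalize")
    mask = np.ones_like(V, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    row_min = np.where(mask, V, np.inf).min(axis=1)
    row_max = np.where(mask, V, -np.inf).max(axis=1)
    span = row_max - row_min
    S = np.zeros_like(V)
    const = span == 0
    if const.any():
        ids = [sw.protein_ids[i] for i in np.flatnonzero(const)]
        logger.warning(
            "constant Smith-Waterman score row(s) for %s; set to 0", ids
        )
        warnings.warn(
            f"constant Smith-Waterman score row(s) for {ids}; set to 0",
            stacklevel=2,
        )
    ok = ~const
    S[ok] = (V[ok] - row_min[ok, None]) / span[ok, None]
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    if symmetrize:
        S = (S + S.T) / 2.0
    return SimilarityMatrix(S, list(sw.protein_ids), kind="target")


def fuse_similarities(
    mats: list[SimilarityMatrix], weights: list[float] | None = None
) -> SimilarityMatrix:
    """Elementwise weighted mean of similarity channels (default uniform)."""
    if not mats:
        raise ValueError("need at least one similarity matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.entity_ids != first.entity_ids:
            raise ValueError(
                "entity orderings differ between fused similarity matrices"
            )
        if m.kind != first.kind:
            raise ValueError("cannot fuse similarities of different kinds")
    if weights is None:
        weights = [1.0 / len(mats)] * len(mats)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(mats):
        raise ValueError("one weight per matrix required")
    if (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    fused = sum(wi * m.values for wi, m in zip(w, mats))
    return SimilarityMatrix(fused, list(first.entity_ids), kind=first.kind)


def fingerprints_from_smiles(
    smiles: list[str], drug_ids: list[str], radius: int = 2, n_bits: int = 1024
) -> FingerprintMatrix:
    """Morgan circular fingerprints from SMILES (requires rdkit)."""
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "rdkit is required to compute fingerprints from SMILES; "
            "supply a precomputed fingerprint matrix instead"
        ) from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits
    )
    rows = []
    for did, smi in zip(drug_ids, smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {did!r}: {smi!r}")
        rows.append(np.array(gen.GetFingerprint(mol), dtype=np.int8))
    return FingerprintMatrix(np.vstack(rows), list(drug_ids))
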