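"""Drug-target-disease heterogeneous network assembly.

The block adjacency stacks, in node order (targets, drugs, diseases):

    H = [ S_p     A_pr    A_dp^T ]
        [ A_pr^T  S_r     A_dr^T ]
        [ A_dp    A_dr    0      ]

with S_p / S_r the target / drug similarity blocks, A_pr the target-by-drug
association block, and A_dp / A_dr the disease-by-target and disease-by-drug
associations. No disease-disease similarity is available, so that block is
zero. Node features are simply the rows of H: each node is described by its
full similarity-plus-association profile. Graph-convolution layers consume
the symmetrically normalized adjacency D^{-1/2}(H + I)D^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import SimilarityMatrix

VALID_RELATIONS = {"target-drug", "disease-drug", "disease-target"}


@dataclass
class AssociationMatrix:
    """Binary association block between two entity classes."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    relation: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.relation not in VALID_RELATIONS:
            raise ValueError(
                f"relation must be one of {sorted(VALID_RELATIONS)}"
            )
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("association shape must match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association entries must be binary")
        if len(set(self.row_ids)) != len(self.row_ids) or len(
            set(self.col_ids)
        ) != len(self.col_ids):
            raise ValueError("duplicate entity ids in association matrix")


@dataclass
class HeterogeneousNetwork:
    H: np.ndarray
    target_ids: list[str]
    drug_ids: list[str]
    disease_ids: list[str]

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def node_types(self) -> list[str]:
        return (
            ["target"] * self.n_targets
            + ["drug"] * self.n_drugs
            + ["disease"] * self.n_diseases
        )

    @property
    def target_rows(self) -> np.ndarray:
        return np.arange(self.n_targets)

    @property
    def drug_rows(self) -> np.ndarray:
        return self.n_targets + np.arange(self.n_drugs)

    @property
    def disease_rows(self) -> np.ndarray:
        return self.n_targets + self.n_drugs + np.arange(self.n_diseases)

    @property
    def A_pr(self) -> np.ndarray:
        """Target-by-drug association block (the DTI labels)."""
        return self.H[np.ix_(self.target_rows, self.drug_rows)]

    def with_dti_block(self, A_pr: np.ndarray) -> "HeterogeneousNetwork":
        """Copy of the network with the DTI block replaced (e.g. masked)."""
        A_pr = np.asarray(A_pr, dtype=float)
        if A_pr.shape != (self.n_targets, self.n_drugs):
            raise ValueError("A_pr shape mismatch")
        H = self.H.copy()
        H[np.ix_(self.target_rows, self.drug_rows)] = A_pr
        H[np.ix_(self.drug_rows, self.target_rows)] = A_pr.T
        return HeterogeneousNetwork(
            H, list(self.target_ids), list(self.drug_ids), list(self.disease_ids)
        )


@dataclass
class NodeFeatureMatrix:
    X: np.ndarray
    space: str  # "drug", "target" or "joint"


@dataclass
class NormalizedAdjacency:
    A_norm: np.ndarray


def build_heterogeneous_adjacency(
    S_p: SimilarityMatrix,
    S_r: SimilarityMatrix,
    A_pr: AssociationMatrix,
    A_dp: AssociationMatrix,
    A_dr: AssociationMatrix,
) -> HeterogeneousNetwork:
    """Assemble the symmetric block adjacency from its five blocks.

    ``A_pr`` is targets-by-drugs; ``A_dp`` and ``A_dr`` are disease-rowed
    (diseases-by-targets, diseases-by-drugs) and enter the top/middle rows
    transposed so that H is symmetric by construction.
    """
    target_ids = list(S_p.entity_ids)
    drug_ids = list(S_r.entity_ids)
    disease_ids = list(A_dp.row_ids)

    def _check(name, got, want):
        missing = [g for g, w in zip(got, want) if g != w]
        if list(got) != list(want):
            raise ValueError(
                f"{name} entity ordering does not match network ordering "
                f"(first mismatches: {missing[:5]})"
            )

    _check("A_pr rows (targets)", A_pr.row_ids, target_ids)
    _check("A_pr columns (drugs)", A_pr.col_ids, drug_ids)
    _check("A_dp columns (targets)", A_dp.col_ids, target_ids)
    _check("A_dr columns (drugs)", A_dr.col_ids, drug_ids)
    _check("A_dr rows (diseases)", A_dr.row_ids, disease_ids)

    m, n, d = len(target_ids), len(drug_ids), len(disease_ids)
    H = np.zeros((m + n + d, m + n + d))
    H[:m, :m] = S_p.values
    H[m : m + n, m : m + n] = S_r.values
    H[:m, m : m + n] = A_pr.values
    H[m : m + n, :m] = A_pr.values.T
    H[:m, m + n :] = A_dp.values.T
    H[m + n :, :m] = A_dp.values
    H[m : m + n, m + n :] = A_dr.values.T
    H[m + n :, m : m + n] = A_dr.values
    return HeterogeneousNetwork(H, target_ids, drug_ids, disease_ids)


def node_features(
    net: HeterogeneousNetwork, space: str = "joint"
) -> NodeFeatureMatrix:
    """Node feature rows of H for the requested node type.

    Every node's feature vector is its full (m+n+d)-long profile of
    similarities and associations.
    """
    if space == "target":
        rows = net.target_rows
    elif space == "drug":
        rows = net.drug_rows
    elif space == "joint":
        rows = np.arange(net.H.shape[0])
    else:
        raise ValueError("space must be 'drug', 'target' or 'joint'")
    return NodeFeatureMatrix(net.H[rows].copy(), space)


def normalize_adjacency(A: np.ndarray) -> NormalizedAdjacency:
    """Symmetric GCN normalization with self-loops.

    A_tilde = A + I; D_tilde = diag(row sums); returns
    D_tilde^{-1/2} A_tilde D_tilde^{-1/2}. Self-loops guarantee strictly
    positive degrees.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.min() < 0:
        raise ValueError("adjacency must be nonnegative")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return NormalizedAdjacency(A_tilde * np.outer(d_inv_sqrt, d_inv_sqrt))
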