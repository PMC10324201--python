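"""Readers and writers for the package's on-disk formats.

Dense matrices travel as TSV with a header row and an id column, values at
6-decimal fixed point; association blocks additionally accept a sparse
(row_id, col_id, value) triplet dialect and plain edge lists. Protein
sequences are FASTA (via Biopython); SMILES come as id<TAB>smiles lines.
Every file written here starts with ``#`` comment lines recording the
package version, the seed and a hash of the run configuration; readers
skip them.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .hetnet import AssociationMatrix
from .similarity import FingerprintMatrix, SequenceSet, SimilarityMatrix

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    blob = "\n".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(seed=None, cfg_hash=None) -> str:
    parts = [f"# vgaedti {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return " ".join(parts) + "\n"


def write_matrix(path, values, row_ids, col_ids, seed=None, cfg_hash=None):
    """Dense TSV matrix: header comment, column-id header, id-led rows."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("id\t" + "\t".join(map(str, col_ids)) + "\n")
        for rid, row in zip(row_ids, np.asarray(values, dtype=float)):
            fh.write(str(rid) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix(path):
    """Read a dense TSV matrix; returns (values, row_ids, col_ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values")
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def read_similarity(path, kind) -> SimilarityMatrix:
    values, rows, cols = read_matrix(path)
    if rows != cols:
        raise ValueError(f"{path}: similarity matrix ids differ between axes")
    return SimilarityMatrix(values, rows, kind)


def read_association(path, relation, row_ids=None, col_ids=None) -> AssociationMatrix:
    """Dense or sparse-triplet association block.

    A file whose header is exactly ``source_id  target_id  value`` (or a
    two/three-column header-less edge list) is treated as sparse and needs
    ``row_ids``/``col_ids`` to fix the universe; anything else is dense.
    """
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    n_cols = len(first.rstrip("\n").split("\t"))
    if n_cols <= 3 and (row_ids is not None and col_ids is not None):
        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["source", "target", "value"][:n_cols], header=None,
            dtype={"source": str, "target": str},
        )
        if list(df.iloc[0, :2]) == ["source_id", "target_id"]:
            df = df.iloc[1:]
        if "value" not in df:
            df["value"] = 1
        ridx = {r: i for i, r in enumerate(row_ids)}
        cidx = {c: i for i, c in enumerate(col_ids)}
        values = np.zeros((len(row_ids), len(col_ids)), dtype=int)
        for line_no, (_, row) in enumerate(df.iterrows(), start=1):
            if row["source"] not in ridx:
                raise ValueError(
                    f"{path}:{line_no}: unknown row entity {row['source']!r}"
                )
            if row["target"] not in cidx:
                raise ValueError(
                    f"{path}:{line_no}: unknown column entity {row['target']!r}"
                )
            values[ridx[row["source"]], cidx[row["target"]]] = int(row["value"])
        return AssociationMatrix(values, list(row_ids), list(col_ids), relation)
    values, rows, cols = read_matrix(path)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError(f"{path}: association entries must be binary")
    return AssociationMatrix(values.astype(int), rows, cols, relation)


def load_inputs(config: dict):
    """Load and validate every network block named in a path config.

    ``config`` maps block names (S_p, S_r, A_pr, A_dp, A_dr) to file
    paths, e.g. as parsed by :func:`read_config`. Returns the assembled
    :class:`~vgaedti.hetnet.HeterogeneousNetwork`; entity counts and the
    number of known interactions are logged.
    """
    from .hetnet import build_heterogeneous_adjacency

    required = ("S_p", "S_r", "A_pr", "A_dp", "A_dr")
    missing = [k for k in required if k not in config]
    if missing:
        raise ValueError(f"config is missing input paths for {missing}")
    S_p = read_similarity(config["S_p"], "target")
    S_r = read_similarity(config["S_r"], "drug")
    A_pr = read_association(
        config["A_pr"], "target-drug", S_p.entity_ids, S_r.entity_ids
    )
    A_dp = read_association(config["A_dp"], "disease-target", col_ids=S_p.entity_ids)
    A_dr = read_association(
        config["A_dr"], "disease-drug",
        row_ids=A_dp.row_ids, col_ids=S_r.entity_ids,
    )
    net = build_heterogeneous_adjacency(S_p, S_r, A_pr, A_dp, A_dr)
    logger.info(
        "loaded %d targets, %d drugs, %d diseases, %d known DTIs",
        net.n_targets, net.n_drugs, net.n_diseases, int(net.A_pr.sum()),
    )
    return net


def read_fasta(path) -> SequenceSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceSet(
        [str(r.seq).upper() for r in records], [r.id for r in records]
    )


def write_fasta(path, sequences: SequenceSet):
    with open(path, "w") as fh:
        for pid, seq in zip(sequences.protein_ids, sequences.sequences):
            fh.write(f">{pid}\n{seq}\n")


def read_smiles(path):
    """One drug per line: id<TAB>smiles. Returns (ids, smiles)."""
    ids, smiles = [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected id<TAB>smiles")
            ids.append(parts[0])
            smiles.append(parts[1])
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate drug ids")
    return ids, smiles


def read_fingerprints(path) -> FingerprintMatrix:
    values, rows, _ = read_matrix(path)
    return FingerprintMatrix(values.astype(int), rows)


def read_config(path) -> dict:
    """Flat key: value (or key=value) text config; values kept as strings."""
    cfg = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = ":" if ":" in line else "="
            if sep not in line:
                raise ValueError(f"{path}:{line_no}: expected key{sep}value")
            key, value = line.split(sep, 1)
            cfg[key.strip()] = value.strip()
    return cfg


def write_scores_tsv(path, score_matrix, seed=None, cfg_hash=None):
    write_matrix(
        path,
        score_matrix.values,
        score_matrix.target_ids,
        score_matrix.drug_ids,
        seed=seed,
        cfg_hash=cfg_hash,
    )


def write_ranked_pairs(path, score_matrix, top: int | None = None,
                       seed=None, cfg_hash=None):
    """Ranked (target_id, drug_id, score) list, descending score."""
    values = score_matrix.values
    if score_matrix.known is not None:
        values = np.where(score_matrix.known, -np.inf, values)
    order = np.argsort(-values.ravel(), kind="stable")
    if top is not None:
        order = order[:top]
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        fh.write("rank\ttarget_id\tdrug_id\tscore\n")
        for rank, flat in enumerate(order, start=1):
            i, j = np.unravel_index(flat, values.shape)
            if not np.isfinite(values[i, j]):
                continue
            fh.write(
                f"{rank}\t{score_matrix.target_ids[i]}\t"
                f"{score_matrix.drug_ids[j]}\t{values[i, j]:.6f}\n"
            )


def write_embeddings(path, ids, Y, seed=None, cfg_hash=None):
    write_matrix(
        path, Y, ids, [f"z{i}" for i in range(np.asarray(Y).shape[1])],
        seed=seed, cfg_hash=cfg_hash,
    )


def write_history_csv(path, history, seed=None, cfg_hash=None):
    df = pd.DataFrame(history)
    with open(path, "w") as fh:
        fh.write(_header(seed, cfg_hash))
        df.to_csv(fh, index=False)
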