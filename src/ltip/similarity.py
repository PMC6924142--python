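"""Chemical-chemical and protein-protein similarity graphs.

The similarity matrices feed the two graph-Laplacian penalties of the
factorization objective: similar chemicals (Tanimoto over binary
fingerprints) and similar proteins (normalized pairwise alignment bit-scores)
are pulled toward nearby latent rows.  Similarities are stored with a zero
diagonal; self-loops cancel in ``D - S`` so this convention is loss-neutral.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

_SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1], zero diagonal."""

    values: sp.csr_matrix
    entity_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.values.setdiag(0.0)
        self.values.eliminate_zeros()
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {self.values.shape} != ({n}, {n})"
            )
        asym = abs(self.values - self.values.T)
        if asym.nnz and asym.max() > _SYMMETRY_TOL:
            raise ValidationError("similarity matrix is not symmetric")
        if self.values.nnz:
            lo, hi = self.values.data.min(), self.values.data.max()
            if lo < 0 or hi > 1 + _SYMMETRY_TOL:
                raise ValidationError(f"similarity entries outside [0, 1]: [{lo}, {hi}]")

    @property
    def size(self) -> int:
        return len(self.entity_ids)

    @property
    def degree(self) -> np.ndarray:
        """Row sums (the diagonal of the degree matrix D)."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian D - S."""
        return (sp.diags(self.degree) - self.values).tocsr()


@dataclass
class FingerprintSet:
    """Named fingerprint matrix (chemicals x bits), binary or counts."""

    name: str
    matrix: np.ndarray | sp.spmatrix
    chemical_ids: list[str]

    def __post_init__(self) -> None:
        rows = self.matrix.shape[0]
        if rows != len(self.chemical_ids):
            raise ValidationError(
                f"{rows} fingerprint rows for {len(self.chemical_ids)} chemical ids"
            )

    @property
    def is_binary(self) -> bool:
        data = self.matrix.data if sp.issparse(self.matrix) else np.asarray(self.matrix)
        return bool(np.isin(data, (0, 1)).all())


def tanimoto_matrix(fps: FingerprintSet) -> SimilarityMatrix:
    """All-pairs Tanimoto coefficient |A n B| / |A u B| over on-bits.

    Requires binary fingerprints; a pair of all-zero fingerprints scores 0 by
    convention.  The diagonal is stored as 0 (self-similarity is excluded
    from the graph).
    """
    if not fps.is_binary:
        raise TypeError(
            "tanimoto_matrix requires binary fingerprints; count-valued "
            "fingerprints would need a continuous Tanimoto variant, which "
            "this package does not provide"
        )
    X = sp.csr_matrix(fps.matrix, dtype=np.float64)
    inter = np.asarray((X @ X.T).todense())
    popcount = np.asarray(X.sum(axis=1)).ravel()
    union = popcount[:, None] + popcount[None, :] - inter
    S = np.divide(inter, union, out=np.zeros_like(inter), where=union > 0)
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(sp.csr_matrix(S), list(fps.chemical_ids))


def normalize_sequence_scores(
    raw_scores: Iterable[tuple[str, str, float]] | pd.DataFrame,
) -> SimilarityMatrix:
    """Turn pairwise alignment bit-scores into a [0, 1] similarity matrix.

    S(i, j) = score(i, j) / sqrt(score(i, i) * score(j, j)), clipped to
    [0, 1].  Asymmetric score tables are symmetrized by taking the larger of
    the two directions before normalization; absent pairs score 0.  Every
    protein appearing in any pair must have a positive self-score.
    """
    if isinstance(raw_scores, pd.DataFrame):
        triples = [
            (str(a), str(b), float(s))
            for a, b, s in raw_scores.itertuples(index=False)
        ]
    else:
        triples = [(str(a), str(b), float(s)) for a, b, s in raw_scores]

    ids = list(dict.fromkeys([a for a, _, _ in triples] + [b for _, b, _ in triples]))
    index = {p: i for i, p in enumerate(ids)}
    self_scores = np.zeros(len(ids))
    best: dict[tuple[int, int], float] = {}
    for a, b, s in triples:
        i, j = index[a], index[b]
        if i == j:
            self_scores[i] = max(self_scores[i], s)
        else:
            key = (min(i, j), max(i, j))
            best[key] = max(best.get(key, -np.inf), s)
    missing = [ids[i] for i in range(len(ids)) if not self_scores[i] > 0]
    if missing:
        raise ValidationError(f"missing positive self-score for: {missing}")

    n = len(ids)
    S = np.zeros((n, n))
    for (i, j), s in best.items():
        value = np.clip(s / np.sqrt(self_scores[i] * self_scores[j]), 0.0, 1.0)
        S[i, j] = S[j, i] = value
    return SimilarityMatrix(sp.csr_matrix(S), ids)


def sparsify_topk(S: SimilarityMatrix, k: int) -> SimilarityMatrix:
    """Keep each row's k largest off-diagonal entries, re-symmetrized by union.

    An edge survives if either endpoint retained it; surviving entries keep
    their original values.  Keeps Laplacian solves tractable on large graphs.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    csr = S.values
    n = S.size
    keep_rows, keep_cols = [], []
    for i in range(n):
        start, stop = csr.indptr[i], csr.indptr[i + 1]
        cols, data = csr.indices[start:stop], csr.data[start:stop]
        if data.size > k:
            top = np.argpartition(data, -k)[-k:]
            cols = cols[top]
        keep_rows.append(np.full(cols.size, i))
        keep_cols.append(cols)
    rows = np.concatenate(keep_rows) if keep_rows else np.array([], dtype=int)
    cols = np.concatenate(keep_cols) if keep_cols else np.array([], dtype=int)
    mask = sp.csr_matrix((np.ones(rows.size, bool), (rows, cols)), shape=(n, n))
    mask = (mask + mask.T).astype(bool)  # union of endpoint selections
    kept = csr.multiply(mask)
    return SimilarityMatrix(sp.csr_matrix(kept), list(S.entity_ids))


def laplacian_quadratic(S: SimilarityMatrix, U: np.ndarray) -> float:
    """tr(U^T (D - S) U), the graph-smoothness penalty.

    Equals 0.5 * sum_ij S(i,j) ||U_i - U_j||^2; non-negative for any
    symmetric non-negative S.
    """
    U = np.asarray(U, dtype=np.float64)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape[0] != S.size:
        raise ValidationError(
            f"U has {U.shape[0]} rows but similarity matrix has size {S.size}"
        )
    return float(np.sum(U * (S.laplacian() @ U)))


# -- fingerprint file readers and rdkit conveniences -------------------------


def read_fingerprint_tsv(
    path: str | os.PathLike,
    name: str,
    fmt: str = "bitstring",
    n_bits: int | None = None,
) -> FingerprintSet:
    """Read fingerprints from TSV: chemical id + bitstring, or id + on-bit indices."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            ids.append(parts[0])
            if fmt == "bitstring":
                rows.append(np.frombuffer(parts[1].encode(), np.uint8) - ord("0"))
            elif fmt == "indices":
                idx = np.array([int(p) for p in " ".join(parts[1:]).split()], dtype=int)
                rows.append(idx)
            else:
                raise ValidationError(f"unknown fingerprint format {fmt!r}")
    if fmt == "bitstring":
        matrix = np.vstack(rows).astype(np.float64) if rows else np.zeros((0, 0))
    else:
        width = n_bits or (max((r.max() + 1 for r in rows if r.size), default=0))
        matrix = np.zeros((len(rows), width))
        for i, idx in enumerate(rows):
            matrix[i, idx] = 1.0
    return FingerprintSet(name, matrix, ids)


def maccs_fingerprints(smiles: Sequence[tuple[str, str]]) -> FingerprintSet:
    """MACCS keys from (id, SMILES) pairs.  Convenience wrapper around rdkit."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    ids, rows = [], []
    for cid, smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"unparseable SMILES for {cid!r}: {smi!r}")
        ids.append(cid)
        rows.append(np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64))
    return FingerprintSet("MACCS", np.vstack(rows), ids)


def atom_pair_fingerprints(
    smiles: Sequence[tuple[str, str]], n_bits: int = 2048
) -> FingerprintSet:
    """Hashed binary atom-pair fingerprints from (id, SMILES) pairs."""
    from rdkit import Chem
    from rdkit.Chem.rdFingerprintGenerator import GetAtomPairGenerator

    gen = GetAtomPairGenerator(fpSize=n_bits)
    ids, rows = [], []
    for cid, smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"unparseable SMILES for {cid!r}: {smi!r}")
        ids.append(cid)
        rows.append(np.array(gen.GetFingerprint(mol), dtype=np.float64))
    return FingerprintSet("AP2D", np.vstack(rows), ids)
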