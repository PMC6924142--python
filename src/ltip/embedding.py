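"""Incorporating query chemicals into the network and extracting their profiles.

A chemical of interest — typically a "novel" chemical whose targets are
unknown — is appended to the interaction matrix as an all-zero row and to the
chemical similarity graph via its similarity to the existing chemicals.  The
Laplacian penalty then anchors its latent row through its neighbors
(cold-start embedding).  Two routes are offered:

joint
    Augment R and C, then fit the whole model (matches the incorporate-first
    schema of the method).
fold-in
    Solve only the new rows of U against frozen V and frozen existing rows,
    for cheap scoring against an existing model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data_io import InteractionMatrix
from .errors import ValidationError
from .similarity import SimilarityMatrix
from .winoccf import LatentModel, WinOCCFConfig, occf_loss, update_rows_U

_SYM_TOL = 1e-9


@dataclass
class LTIPFeatures:
    """Latent target interaction profiles for a set of query chemicals."""

    matrix: np.ndarray  # queries x rank
    chemical_ids: list[str]
    rank: int
    provenance: WinOCCFConfig | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.chemical_ids), self.rank):
            raise ValidationError(
                f"feature matrix shape {self.matrix.shape} != "
                f"({len(self.chemical_ids)}, {self.rank})"
            )
        if not np.isfinite(self.matrix).all():
            raise ValidationError("non-finite feature entries")


def incorporate_chemicals(
    R: InteractionMatrix,
    C: SimilarityMatrix,
    new_ids: list[str],
    new_similarities: np.ndarray,
    new_interactions: sp.spmatrix | np.ndarray | None = None,
) -> tuple[InteractionMatrix, SimilarityMatrix, list[int]]:
    """Append query chemicals to R and C; return their row indices.

    ``new_similarities`` has one row per query and ``n + q`` columns
    (similarity to every existing chemical, then to the other queries); the
    query-query block must be symmetric.  Without ``new_interactions`` the
    queries enter target-less (all-zero rows of R) — the novel-chemical
    assumption under which the benchmark operates.
    """
    n, q = R.n, len(new_ids)
    if len(set(new_ids)) != q:
        raise ValidationError("duplicate ids among new chemicals")
    clash = set(new_ids) & set(R.chemical_ids)
    if clash:
        raise ValidationError(f"new chemical ids already present: {sorted(clash)}")
    sims = np.asarray(new_similarities, dtype=np.float64)
    if sims.shape != (q, n + q):
        raise ValidationError(
            f"new_similarities shape {sims.shape} != ({q}, {n + q})"
        )
    if sims.min() < 0 or sims.max() > 1:
        raise ValidationError("similarities must lie in [0, 1]")
    block = sims[:, n:]
    if np.abs(block - block.T).max() > _SYM_TOL:
        raise ValidationError("query-query similarity block is not symmetric")

    if new_interactions is None:
        new_rows = sp.csr_matrix((q, R.m))
    else:
        new_rows = sp.csr_matrix(new_interactions, dtype=np.float64)
        if new_rows.shape != (q, R.m):
            raise ValidationError(
                f"new_interactions shape {new_rows.shape} != ({q}, {R.m})"
            )
    R_aug = InteractionMatrix(
        sp.vstack([R.values, new_rows]).tocsr(),
        list(R.chemical_ids) + list(new_ids),
        list(R.protein_ids),
    )

    C_dense = C.values.toarray()
    top = np.hstack([C_dense, sims[:, :n].T])
    bottom = sims.copy()
    np.fill_diagonal(bottom[:, n:], 0.0)
    C_aug = SimilarityMatrix(
        sp.csr_matrix(np.vstack([top, bottom])),
        list(C.entity_ids) + list(new_ids),
    )
    return R_aug, C_aug, list(range(n, n + q))


def extract_ltip(
    model: LatentModel, query_indices, ids: list[str]
) -> LTIPFeatures:
    """Rows of U at the query indices, in query order.  Never alters the model."""
    query_indices = list(query_indices)
    n = model.U.shape[0]
    bad = [i for i in query_indices if not 0 <= i < n]
    if bad:
        raise ValidationError(f"query indices out of range for {n} chemicals: {bad}")
    if len(query_indices) != len(ids):
        raise ValidationError("query_indices and ids differ in length")
    return LTIPFeatures(
        matrix=model.U[query_indices].copy(),
        chemical_ids=list(ids),
        rank=model.U.shape[1],
        provenance=model.config,
    )


def fold_in_chemicals(
    model: LatentModel,
    R_aug: InteractionMatrix,
    C_aug: SimilarityMatrix,
    query_indices,
    n_iter: int = 25,
    rel_tol: float = 1e-8,
) -> LTIPFeatures:
    """Solve the query rows of U against the frozen factors of a fitted model.

    The non-query rows of U and all of V stay fixed; the query rows are
    re-solved (Gauss-Seidel over the query set, which is coupled only through
    query-query similarity edges) until the objective stabilizes.  Queries
    start at zero, the score the one-class prior assigns a chemical with no
    evidence.
    """
    query_indices = list(query_indices)
    cfg = model.config
    k = model.U.shape[1]
    if R_aug.n != C_aug.size:
        raise ValidationError("augmented R and C disagree on chemical count")
    U = np.zeros((R_aug.n, k))
    U[: model.U.shape[0]] = model.U
    V = model.V
    prev = None
    for _ in range(n_iter):
        update_rows_U(R_aug, U, V, C_aug, cfg, rows=query_indices)
        cur = occf_loss(R_aug, U, V, C_aug, None, cfg)
        if prev is not None and abs(prev - cur) <= rel_tol * max(abs(prev), 1.0):
            break
        prev = cur
    ids = [R_aug.chemical_ids[i] for i in query_indices]
    return LTIPFeatures(U[query_indices].copy(), ids, k, provenance=cfg)


def write_ltip_tsv(features: LTIPFeatures, path) -> None:
    """TSV: chemical id followed by the rank latent coordinates, full precision."""
    with open(path, "w") as fh:
        header = "chemical_id\t" + "\t".join(f"z{j}" for j in range(features.rank))
        fh.write(header + "\n")
        for cid, row in zip(features.chemical_ids, features.matrix):
            fh.write(cid + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_ltip_tsv(path) -> LTIPFeatures:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    matrix = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return LTIPFeatures(matrix, ids, matrix.shape[1])
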