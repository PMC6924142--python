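"""Weighted, imputed, dual graph-regularized one-class matrix factorization.

The objective factorizes a binary chemical-protein interaction matrix R
(n x m) into low-rank factors U (n x k) and V (m x k):

    min_{U,V}  sum_ij P_wt(i,j) * (R(i,j) + P_imp(i,j) - U_i . V_j)^2
             + p_reg * (||U||_F^2 + ||V||_F^2)
             + p_chem * tr(U^T (D_c - C) U)
             + p_prot * tr(V^T (D_T - T) V)

Observed interactions carry weight P_wt = 1 and imputation P_imp = 0;
unobserved cells carry a uniform weight ``w_unobserved`` in [0, 1] and a
uniform imputed value ``imp_unobserved`` in [0, 1].  C and T are chemical and
protein similarity graphs whose Laplacian penalties pull similar entities
toward nearby latent rows — this is what gives target-less (cold-start)
chemicals a meaningful embedding.

The solver is alternating Gauss-Seidel: each row of U (then V) is replaced by
the exact minimizer of the objective with everything else fixed, which is a
k x k linear solve.  Exact block minimization makes the recorded loss trace
non-increasing by construction.  The uniform unobserved weight admits the
usual one-class acceleration: the full weighted Gram sum collapses to
``w * V^T V`` plus a sparse correction over each row's observed entries, so a
sweep costs O((n + m) k^2 + (nnz(R) + nnz(C) + nnz(T)) k) instead of O(n m k).

An optional second pass re-fits after imputing the top fraction of unobserved
predictions as soft positives (``impute_refit``), realizing the "imputed"
part of the scheme without committing to a particular neighborhood rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .data_io import InteractionMatrix
from .errors import NumericError, ValidationError
from .similarity import SimilarityMatrix, laplacian_quadratic

logger = logging.getLogger(__name__)

_SINGULAR_RIDGE = 1e-10


@dataclass
class WinOCCFConfig:
    """All scalars of the factorization objective and its solver.

    rank
        Latent dimension k.  The full-scale chemical-protein network uses
        600; desk-scale problems use the planted rank.
    p_reg, p_chem, p_prot
        Frobenius ridge and the two Laplacian penalty weights.
    w_unobserved, imp_unobserved
        Uniform weight and imputed value for unobserved cells, both in
        [0, 1].  Observed cells are fixed at weight 1, imputation 0.
    init_scale
        Factors start uniform(0, init_scale); defaults to 0.01 / sqrt(rank)
        so initial scores sit near zero, matching the one-class prior.
    """

    rank: int = 600
    p_reg: float = 0.1
    p_chem: float = 0.1
    p_prot: float = 0.1
    w_unobserved: float = 0.1
    imp_unobserved: float = 0.0
    max_sweeps: int = 100
    rel_tol: float = 1e-4
    seed: int = 0
    init_scale: float | None = None
    impute_refit: bool = False
    impute_top_frac: float = 0.01

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValidationError(f"rank must be >= 1, got {self.rank}")
        for name in ("p_reg", "p_chem", "p_prot"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name in ("w_unobserved", "imp_unobserved"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.max_sweeps < 0:
            raise ValidationError("max_sweeps must be >= 0")
        if not self.rel_tol > 0:
            raise ValidationError("rel_tol must be positive")
        if self.init_scale is not None and not self.init_scale > 0:
            raise ValidationError("init_scale must be positive")
        if not 0.0 < self.impute_top_frac <= 1.0:
            raise ValidationError("impute_top_frac must lie in (0, 1]")

    @property
    def resolved_init_scale(self) -> float:
        return self.init_scale if self.init_scale is not None else 0.01 / math.sqrt(self.rank)


@dataclass
class LatentModel:
    """Fitted factors with the per-sweep loss trace."""

    U: np.ndarray
    V: np.ndarray
    loss_trace: list[float]
    converged: bool
    config: WinOCCFConfig


def _check_dims(R: InteractionMatrix, U, V, C, T) -> None:
    n, m = R.n, R.m
    if U.shape[0] != n or V.shape[0] != m or U.shape[1] != V.shape[1]:
        raise ValidationError(
            f"factor shapes {U.shape} x {V.shape} inconsistent with R {n}x{m}"
        )
    if C is not None and C.size != n:
        raise ValidationError(f"chemical similarity size {C.size} != {n} chemicals")
    if T is not None and T.size != m:
        raise ValidationError(f"protein similarity size {T.size} != {m} proteins")


def occf_loss(
    R: InteractionMatrix,
    U: np.ndarray,
    V: np.ndarray,
    C: SimilarityMatrix | None,
    T: SimilarityMatrix | None,
    cfg: WinOCCFConfig,
    imp_extra: sp.csr_matrix | None = None,
) -> float:
    """Evaluate the full objective.

    Computed without materializing U V^T: the uniform unobserved part uses
    ||a - U V^T||_F^2 = n m a^2 - 2 a (sum U)(sum V) + <U^T U, V^T V>, then
    observed cells (and any entries of ``imp_extra``) are corrected sparsely.
    """
    U = np.asarray(U, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    _check_dims(R, U, V, C, T)
    if not (np.isfinite(U).all() and np.isfinite(V).all()):
        raise NumericError("non-finite factor entries")

    w, a = cfg.w_unobserved, cfg.imp_unobserved
    n, m = R.n, R.m
    Gu, Gv = U.T @ U, V.T @ V
    # w * || a*ones - U V^T ||_F^2 over ALL cells
    full = n * m * a * a - 2.0 * a * float(U.sum(0) @ V.sum(0)) + float(np.sum(Gu * Gv))
    loss = w * full

    coo = R.values.tocoo()
    if coo.nnz:
        s = np.einsum("ij,ij->i", U[coo.row], V[coo.col])
        # replace the uniform contribution w*(a - s)^2 with the observed 1*(1 - s)^2
        loss += float(np.sum((1.0 - s) ** 2 - w * (a - s) ** 2))
    if imp_extra is not None and imp_extra.nnz:
        extra = imp_extra.tocoo()
        s = np.einsum("ij,ij->i", U[extra.row], V[extra.col])
        # unobserved cells whose imputed value differs from the uniform a
        loss += float(np.sum(w * (extra.data - s) ** 2 - w * (a - s) ** 2))

    loss += cfg.p_reg * (float(np.sum(U * U)) + float(np.sum(V * V)))
    if cfg.p_chem and C is not None:
        loss += cfg.p_chem * laplacian_quadratic(C, U)
    if cfg.p_prot and T is not None:
        loss += cfg.p_prot * laplacian_quadratic(T, V)
    if not np.isfinite(loss):
        raise NumericError("non-finite loss")
    return float(loss)


def _sweep_rows(
    Rcsr: sp.csr_matrix,
    X: np.ndarray,
    Y: np.ndarray,
    S: SimilarityMatrix | None,
    p_side: float,
    cfg: WinOCCFConfig,
    imp_csr: sp.csr_matrix | None = None,
    rows: Sequence[int] | None = None,
) -> np.ndarray:
    """One Gauss-Seidel sweep over the rows of X against fixed Y.

    Row i is replaced by the solution of

        (w Y^T Y + (1-w) Yo^T Yo + (p_reg + p_side d_i) I) x
            = w a sum(Y) + (1 - w a) sum(Yo) + p_side S_i X + corrections,

    where Yo stacks Y over row i's observed columns and S_i X uses
    already-updated rows within the sweep (Gauss-Seidel), so the objective
    never increases.
    """
    w, a = cfg.w_unobserved, cfg.imp_unobserved
    k = X.shape[1]
    G = Y.T @ Y
    sy = Y.sum(axis=0)
    eye = np.eye(k)
    deg = S.degree if (S is not None and p_side > 0) else None
    Scsr = S.values if (S is not None and p_side > 0) else None

    for i in rows if rows is not None else range(X.shape[0]):
        start, stop = Rcsr.indptr[i], Rcsr.indptr[i + 1]
        obs = Rcsr.indices[start:stop]
        M = w * G + cfg.p_reg * eye
        b = (w * a) * sy.copy()
        if obs.size:
            Yo = Y[obs]
            M += (1.0 - w) * (Yo.T @ Yo)
            b += (1.0 - w * a) * Yo.sum(axis=0)
        if imp_csr is not None:
            s0, s1 = imp_csr.indptr[i], imp_csr.indptr[i + 1]
            if s1 > s0:
                cols, vals = imp_csr.indices[s0:s1], imp_csr.data[s0:s1]
                b += w * ((vals - a) @ Y[cols])
        if deg is not None:
            M += (p_side * deg[i]) * eye
            c0, c1 = Scsr.indptr[i], Scsr.indptr[i + 1]
            if c1 > c0:
                b += p_side * (Scsr.data[c0:c1] @ X[Scsr.indices[c0:c1]])
        try:
            X[i] = np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            logger.warning("singular row system at row %d; applying %g ridge", i, _SINGULAR_RIDGE)
            X[i] = np.linalg.solve(M + _SINGULAR_RIDGE * eye, b)
    return X


def update_rows_U(
    R: InteractionMatrix,
    U: np.ndarray,
    V: np.ndarray,
    C: SimilarityMatrix | None,
    cfg: WinOCCFConfig,
    imp_extra: sp.csr_matrix | None = None,
    rows: Sequence[int] | None = None,
) -> np.ndarray:
    """In-place Gauss-Seidel sweep over chemical rows of U."""
    _check_dims(R, U, V, C, None)
    if not np.isfinite(V).all():
        raise NumericError("non-finite entries in V")
    return _sweep_rows(R.values.tocsr(), U, V, C, cfg.p_chem, cfg, imp_extra, rows)


def update_rows_V(
    R: InteractionMatrix,
    U: np.ndarray,
    V: np.ndarray,
    T: SimilarityMatrix | None,
    cfg: WinOCCFConfig,
    imp_extra: sp.csr_matrix | None = None,
    rows: Sequence[int] | None = None,
) -> np.ndarray:
    """In-place Gauss-Seidel sweep over protein rows of V."""
    _check_dims(R, U, V, None, T)
    if not np.isfinite(U).all():
        raise NumericError("non-finite entries in U")
    imp_t = imp_extra.T.tocsr() if imp_extra is not None else None
    return _sweep_rows(R.values.T.tocsr(), V, U, T, cfg.p_prot, cfg, imp_t, rows)


def _alternate(R, C, T, U, V, cfg, imp_extra) -> tuple[list[float], bool]:
    trace = [occf_loss(R, U, V, C, T, cfg, imp_extra)]
    converged = False
    for sweep in range(cfg.max_sweeps):
        update_rows_U(R, U, V, C, cfg, imp_extra)
        update_rows_V(R, U, V, T, cfg, imp_extra)
        trace.append(occf_loss(R, U, V, C, T, cfg, imp_extra))
        logger.info("sweep %d: loss %.6g", sweep + 1, trace[-1])
        denom = abs(trace[-2]) if trace[-2] else 1.0
        if (trace[-2] - trace[-1]) / denom < cfg.rel_tol:
            converged = True
            break
    return trace, converged


def fit_winoccf(
    R: InteractionMatrix,
    C: SimilarityMatrix | None,
    T: SimilarityMatrix | None,
    cfg: WinOCCFConfig,
) -> LatentModel:
    """Fit the factorization by alternating exact row minimization.

    Factors are initialized uniform(0, init_scale) from the configured seed;
    the same seed and inputs give a bitwise-identical loss trace.  The trace
    records the objective at initialization and after each full (U then V)
    sweep; iteration stops when the relative decrease falls below
    ``rel_tol``.  With ``impute_refit`` the model is refit once after
    imputing the top ``impute_top_frac`` of unobserved predictions (clipped
    to [0, 1]) as soft positives; the reported trace is the refit phase's.
    """
    _check_dims(R, np.empty((R.n, cfg.rank)), np.empty((R.m, cfg.rank)), C, T)
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.resolved_init_scale
    U = rng.uniform(0.0, scale, size=(R.n, cfg.rank))
    V = rng.uniform(0.0, scale, size=(R.m, cfg.rank))

    trace, converged = _alternate(R, C, T, U, V, cfg, None)

    if cfg.impute_refit and cfg.max_sweeps > 0:
        imp = _top_unobserved_imputations(R, U, V, cfg.impute_top_frac)
        trace, converged = _alternate(R, C, T, U, V, cfg, imp)
    return LatentModel(U=U, V=V, loss_trace=trace, converged=converged, config=cfg)


def _top_unobserved_imputations(
    R: InteractionMatrix, U: np.ndarray, V: np.ndarray, top_frac: float
) -> sp.csr_matrix:
    """Clipped scores of the top fraction of unobserved cells, as sparse P_imp."""
    scores = U @ V.T
    dense = R.values.toarray().astype(bool)
    scores[dense] = -np.inf
    q = max(1, int(round(top_frac * (R.n * R.m - R.nnz))))
    flat = np.argpartition(scores, -q, axis=None)[-q:]
    rows, cols = np.unravel_index(flat, scores.shape)
    vals = np.clip(scores[rows, cols], 0.0, 1.0)
    keep = vals > 0
    return sp.csr_matrix((vals[keep], (rows[keep], cols[keep])), shape=(R.n, R.m))


def predict_interactions(
    model: LatentModel, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Scores U_i . V_j for a list of (chemical index, protein index) pairs."""
    pairs = np.asarray(pairs, dtype=int)
    if pairs.size == 0:
        return np.zeros(0)
    rows, cols = pairs[:, 0], pairs[:, 1]
    n, m = model.U.shape[0], model.V.shape[0]
    if rows.min() < 0 or rows.max() >= n or cols.min() < 0 or cols.max() >= m:
        raise ValidationError(f"pair index outside {n} chemicals x {m} proteins")
    return np.einsum("ij,ij->i", model.U[rows], model.V[cols])


# -- model persistence --------------------------------------------------------


def save_model(model: LatentModel, directory) -> None:
    """Write U.mtx, V.mtx, loss_trace.tsv and the resolved config (JSON)."""
    import json
    import os

    from .data_io import write_matrix

    os.makedirs(directory, exist_ok=True)
    write_matrix(model.U, os.path.join(directory, "U.mtx"))
    write_matrix(model.V, os.path.join(directory, "V.mtx"))
    with open(os.path.join(directory, "loss_trace.tsv"), "w") as fh:
        fh.write("sweep\tloss\n")
        for t, value in enumerate(model.loss_trace):
            fh.write(f"{t}\t{value!r}\n")
    payload = asdict(model.config) | {"converged": model.converged}
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(directory) -> LatentModel:
    import json
    import os

    from .data_io import read_matrix

    U = np.asarray(read_matrix(os.path.join(directory, "U.mtx")))
    V = np.asarray(read_matrix(os.path.join(directory, "V.mtx")))
    with open(os.path.join(directory, "loss_trace.tsv")) as fh:
        next(fh)
        trace = [float(line.split("\t")[1]) for line in fh if line.strip()]
    with open(os.path.join(directory, "config.json")) as fh:
        payload = json.load(fh)
    converged = payload.pop("converged")
    return LatentModel(U, V, trace, converged, WinOCCFConfig(**payload))
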