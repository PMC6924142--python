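import numpy as np
import pytest
import scipy.sparse as sp

from ltip.data_io import InteractionMatrix
from ltip.similarity import SimilarityMatrix
from ltip.winoccf import WinOCCFConfig


def random_interactions(rng, n, m, density=0.3):
    """Random binary interaction matrix with id registries."""
    dense = (rng.random((n, m)) < density).astype(float)
    return InteractionMatrix(
        sp.csr_matrix(dense),
        [f"c{i}" for i in range(n)],
        [f"p{j}" for j in range(m)],
    )


def random_similarity(rng, n, density=0.5, prefix="e"):
    """Random symmetric [0,1] similarity matrix with zero diagonal."""
    S = rng.random((n, n)) * (rng.random((n, n)) < density)
    S = np.triu(S, 1)
    S = S + S.T
    return SimilarityMatrix(sp.csr_matrix(S), [f"{prefix}{i}" for i in range(n)])


def small_config(rank=2, **kw):
    defaults = dict(
        rank=rank, p_reg=0.05, p_chem=0.1, p_prot=0.1,
        w_unobserved=0.2, imp_unobserved=0.05,
        max_sweeps=50, rel_tol=1e-6, seed=0,
    )
    defaults.update(kw)
    return WinOCCFConfig(**defaults)


def brute_force_loss(R_dense, U, V, C_dense, T_dense, cfg):
    """Elementwise reference for the factorization objective.

    Sums the weighted reconstruction term cell by cell and uses the pairwise
    half-sum form of the graph penalties, staying independent of the
    production implementation's algebra.
    """
    n, m = R_dense.shape
    loss = 0.0
    for i in range(n):
        for j in range(m):
            if R_dense[i, j] == 1:
                wt, imp = 1.0, 0.0
            else:
                wt, imp = cfg.w_unobserved, cfg.imp_unobserved
            loss += wt * (R_dense[i, j] + imp - float(U[i] @ V[j])) ** 2
    loss += cfg.p_reg * (float((U**2).sum()) + float((V**2).sum()))
    for A, X, pen in ((C_dense, U, cfg.p_chem), (T_dense, V, cfg.p_prot)):
        acc = 0.0
        for i in range(A.shape[0]):
            for j in range(A.shape[0]):
                acc += A[i, j] * float(((X[i] - X[j]) ** 2).sum())
        loss += pen * 0.5 * acc
    return loss


@pytest.fixture(scope="session")
def tiny_world():
    """Small planted world shared by the slower end-to-end tests."""
    from ltip.synthetic import WorldParams, simulate_world

    return simulate_world(WorldParams(n=60, m=40, rank=3, density=0.05), seed=7)
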