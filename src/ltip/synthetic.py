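"""Synthetic bipartite worlds with planted low-rank structure.

The generator emulates the statistical regime the factorization assumes: a
sparse one-class interaction matrix generated by thresholding the scores of
non-negative latent archetype factors, similarity graphs consistent with
those factors, a held-out slice of true positives for link-prediction
evaluation, and per-cell-line bioactivity responses that are linear in the
chemical latent factors.  Responses depending on the latent factors — not on
raw structure — encodes the working hypothesis that the genome-scale target
interaction profile correlates with bioactivity more directly than chemical
structure does; a bit-vector "fingerprint" control correlated with cluster
membership (plus bit-flip noise) gives the benchmark a non-trivial
structure-based competitor.

All randomness flows from a single seed through one generator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data_io import (
    InteractionMatrix,
    load_interaction_matrix,
    read_matrix,
    save_interaction_matrix,
    write_id_list,
    write_matrix,
    read_id_list,
)
from .errors import ValidationError
from .qsar import FeatureTable
from .similarity import SimilarityMatrix


@dataclass
class WorldParams:
    """Generator settings.

    Defaults give a 200 x 100 network at rank 5 and 2% interaction density
    (about 1.6 observed links per chemical after hold-out — the severe
    sparsity the one-class setting implies), 20% of positives held out,
    mild similarity noise, 7 pseudo-cell-lines with response noise sd 0.1
    on responses whose latent signal has roughly unit scale.
    """

    n: int = 200
    m: int = 100
    rank: int = 5
    density: float = 0.02
    holdout_frac: float = 0.2
    sim_noise: float = 0.05
    response_noise_sd: float = 0.1
    n_cell_lines: int = 7
    n_fp_bits: int = 64
    fp_flip_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.rank > min(self.n, self.m):
            raise ValidationError("rank must be <= min(n, m)")
        if not 0.0 < self.density < 1.0:
            raise ValidationError("density must lie in (0, 1)")
        if not 0.0 <= self.holdout_frac < 1.0:
            raise ValidationError("holdout_frac must lie in [0, 1)")


@dataclass
class SyntheticWorld:
    """Everything a full pipeline run needs, generated from one seed."""

    U_true: np.ndarray
    V_true: np.ndarray
    R: InteractionMatrix
    C: SimilarityMatrix
    T: SimilarityMatrix
    held_out_positives: list[tuple[int, int]]
    responses: dict[str, np.ndarray]
    fingerprints: FeatureTable
    seed: int
    params: WorldParams


def _archetype_factors(rng, n_rows: int, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative factors clustered around one-hot archetypes."""
    cluster = rng.integers(0, rank, size=n_rows)
    X = rng.uniform(0.0, 0.1, size=(n_rows, rank))
    X[np.arange(n_rows), cluster] = rng.uniform(0.8, 1.2, size=n_rows)
    return X, cluster


def _cosine_similarity_graph(X: np.ndarray, noise: float, rng) -> SimilarityMatrix:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    S = (X / norms) @ (X / norms).T
    if noise > 0:
        jitter = rng.normal(0.0, noise, size=S.shape)
        S = S + (jitter + jitter.T) / 2.0
    S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 0.0)
    ids = [f"E{i:04d}" for i in range(X.shape[0])]
    return SimilarityMatrix(sp.csr_matrix(S), ids)


def simulate_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a world; identical seed and params give identical worlds."""
    params = params or WorldParams()
    rng = np.random.default_rng(seed)

    U_true, _ = _archetype_factors(rng, params.n, params.rank)
    V_true, _ = _archetype_factors(rng, params.m, params.rank)
    scores = U_true @ V_true.T

    n_pos = int(round(params.density * params.n * params.m))
    threshold = np.quantile(scores, 1.0 - params.density)
    if threshold >= scores.max():
        raise ValidationError("requested density is infeasible: degenerate quantile")
    rows, cols = np.nonzero(scores > threshold)
    # quantile ties can leave a surplus/deficit of a few cells; trim by score
    order = np.argsort(scores[rows, cols])[::-1][:n_pos]
    rows, cols = rows[order], cols[order]

    perm = rng.permutation(rows.size)
    n_hold = int(round(params.holdout_frac * rows.size))
    held = [(int(rows[p]), int(cols[p])) for p in perm[:n_hold]]
    obs = perm[n_hold:]
    chemical_ids = [f"CHEM{i:04d}" for i in range(params.n)]
    protein_ids = [f"PROT{j:04d}" for j in range(params.m)]
    R = InteractionMatrix(
        sp.csr_matrix(
            (np.ones(obs.size), (rows[obs], cols[obs])),
            shape=(params.n, params.m),
        ),
        chemical_ids,
        protein_ids,
    )

    C = _cosine_similarity_graph(U_true, params.sim_noise, rng)
    C.entity_ids = list(chemical_ids)
    T = _cosine_similarity_graph(V_true, params.sim_noise, rng)
    T.entity_ids = list(protein_ids)

    responses: dict[str, np.ndarray] = {}
    for line in range(params.n_cell_lines):
        beta = rng.normal(0.0, 1.0, size=params.rank)
        eps = rng.normal(0.0, params.response_noise_sd, size=params.n)
        responses[f"CL{line + 1}"] = U_true @ beta + eps

    bit_cluster = rng.integers(0, params.rank, size=params.n_fp_bits)
    chem_cluster = np.argmax(U_true, axis=1)
    p_on = np.where(
        chem_cluster[:, None] == bit_cluster[None, :], 0.8, 0.1
    )
    bits = (rng.random((params.n, params.n_fp_bits)) < p_on).astype(np.float64)
    flips = rng.random((params.n, params.n_fp_bits)) < params.fp_flip_prob
    bits = np.abs(bits - flips)
    fingerprints = FeatureTable("FP_CTRL", bits, list(chemical_ids))

    return SyntheticWorld(
        U_true=U_true,
        V_true=V_true,
        R=R,
        C=C,
        T=T,
        held_out_positives=held,
        responses=responses,
        fingerprints=fingerprints,
        seed=seed,
        params=params,
    )


def default_fit_config(params: WorldParams, seed: int = 0, **overrides):
    """Analysis configuration for fitting the factorization on a planted world.

    Fits at the planted rank.  In this regime a chemical averages about one
    observed link, so the similarity graphs carry much of the signal; strong
    Laplacian weights (2.0) with a light ridge (0.05) and the usual
    one-class unobserved weight 0.1 let data-poor chemicals inherit their
    neighborhood's latent position.
    """
    from .winoccf import WinOCCFConfig

    settings = dict(
        rank=params.rank,
        p_reg=0.05,
        p_chem=2.0,
        p_prot=2.0,
        w_unobserved=0.1,
        seed=seed,
    )
    settings.update(overrides)
    return WinOCCFConfig(**settings)


def responses_frame(world: SyntheticWorld) -> pd.DataFrame:
    """Long-form (chemical_id, cell_line, auc) response table."""
    frames = []
    for cell_line, y in world.responses.items():
        frames.append(
            pd.DataFrame(
                {
                    "chemical_id": world.R.chemical_ids,
                    "cell_line": cell_line,
                    "auc": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def world_to_files(world: SyntheticWorld, directory) -> None:
    """Write the world in exactly the formats the pipeline CLI consumes."""
    os.makedirs(directory, exist_ok=True)
    join = lambda name: os.path.join(directory, name)
    save_interaction_matrix(world.R, join("R"))
    write_matrix(world.C.values, join("C.mtx"))
    write_matrix(world.T.values, join("T.mtx"))
    write_id_list(world.C.entity_ids, join("C.ids.txt"))
    write_id_list(world.T.entity_ids, join("T.ids.txt"))
    responses_frame(world).to_csv(join("responses.tsv"), sep="\t", index=False)
    with open(join("held_out_positives.tsv"), "w") as fh:
        fh.write("chemical_index\tprotein_index\n")
        for i, j in world.held_out_positives:
            fh.write(f"{i}\t{j}\n")
    fp = world.fingerprints
    with open(join("fingerprints.tsv"), "w") as fh:
        for cid, row in zip(fp.chemical_ids, fp.matrix):
            fh.write(cid + "\t" + "".join(str(int(b)) for b in row) + "\n")


def world_from_files(directory) -> dict:
    """Reload the on-disk pieces (matrices, ids, responses, held-out pairs)."""
    join = lambda name: os.path.join(directory, name)
    R = load_interaction_matrix(join("R"))
    C = SimilarityMatrix(sp.csr_matrix(read_matrix(join("C.mtx"))), read_id_list(join("C.ids.txt")))
    T = SimilarityMatrix(sp.csr_matrix(read_matrix(join("T.mtx"))), read_id_list(join("T.ids.txt")))
    responses = pd.read_csv(join("responses.tsv"), sep="\t")
    held = pd.read_csv(join("held_out_positives.tsv"), sep="\t")
    held_pairs = [(int(i), int(j)) for i, j in held.itertuples(index=False)]
    return {"R": R, "C": C, "T": T, "responses": responses, "held_out_positives": held_pairs}


def sample_negative_pairs(
    world: SyntheticWorld, count: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Uniform unobserved, non-held-out pairs, for link-prediction evaluation."""
    forbidden = set(world.held_out_positives)
    dense = world.R.values.toarray().astype(bool)
    negatives: list[tuple[int, int]] = []
    while len(negatives) < count:
        i = int(rng.integers(0, world.params.n))
        j = int(rng.integers(0, world.params.m))
        if not dense[i, j] and (i, j) not in forbidden:
            negatives.append((i, j))
            forbidden.add((i, j))
    return negatives
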