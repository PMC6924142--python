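"""QSAR benchmarking: do latent interaction profiles predict drug response?

The protocol mirrors a standard cell-line drug-sensitivity benchmark: for
each cancer cell line, a regressor maps a chemical feature matrix (latent
profile or fingerprint) to the area under the dose-response curve (AUC).
Chemicals are split into a training/development set and a hold-out test set
(default 124/20 of 144); hyperparameters are selected on the training set by
leave-one-out cross-validation (scored by squared error on each left-out
chemical); the selected model is refit on all training chemicals and scored
by the Pearson correlation between predicted and observed AUC on the
hold-out set.  Feature sets are compared by their mean correlation and by
their mean rank across cell lines (rank 1 = best within a cell line, ties
averaged).

Feature standardization — required by the distance- and margin-based models
(KNR, SVR) — is fit on training folds only, via a pipeline, so no test
statistics leak into training.  Tree ensembles and gradient boosting consume
raw features.  Cell-line genomic features are deliberately absent from the
models so that chemical representations are compared on equal footing.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import DegenerateVarianceError, ValidationError

logger = logging.getLogger(__name__)

MODEL_NAMES = ("SVR", "XGB", "KNR", "RF", "RF_EXTR")
#: Models whose features are standardized inside each training fold.
STANDARDIZED_MODELS = frozenset({"SVR", "KNR"})

#: Default hyperparameter grids, config-overridable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVR": {"kernel": ["rbf", "linear"], "C": [0.1, 1.0, 10.0, 100.0], "epsilon": [0.01, 0.1]},
    "XGB": {"n_estimators": [100, 300], "max_depth": [3, 6], "learning_rate": [0.05, 0.1]},
    "KNR": {"n_neighbors": [3, 5, 7, 9], "weights": ["uniform", "distance"]},
    "RF": {"n_estimators": [100, 300], "max_features": ["sqrt", 1.0], "min_samples_leaf": [1, 3]},
    "RF_EXTR": {"n_estimators": [100, 300], "max_features": ["sqrt", 1.0], "min_samples_leaf": [1, 3]},
}


@dataclass
class FeatureTable:
    """Named feature matrix aligned to chemical ids."""

    name: str
    matrix: np.ndarray
    chemical_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != len(self.chemical_ids):
            raise ValidationError(
                f"{self.matrix.shape[0]} feature rows for "
                f"{len(self.chemical_ids)} ids in {self.name!r}"
            )

    def subset(self, ids: list[str]) -> "FeatureTable":
        index = {c: i for i, c in enumerate(self.chemical_ids)}
        missing = [c for c in ids if c not in index]
        if missing:
            raise ValidationError(f"ids missing from {self.name!r}: {missing[:5]}")
        rows = [index[c] for c in ids]
        return FeatureTable(self.name, self.matrix[rows], list(ids))


@dataclass
class QSARDataset:
    """Features plus per-chemical drug-response AUC for one cell line."""

    features: np.ndarray
    response: np.ndarray
    chemical_ids: list[str]
    feature_name: str
    cell_line: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64)
        if not (
            self.features.shape[0] == self.response.shape[0] == len(self.chemical_ids)
        ):
            raise ValidationError("features, response and ids differ in length")
        if np.isnan(self.response).any():
            raise ValidationError("missing responses are not allowed")


@dataclass
class EvalRecord:
    """Hold-out result for one (cell line, feature set, model) cell."""

    cell_line: str
    feature_name: str
    model_name: str
    pcc: float | None
    best_hyperparams: dict
    n_train: int
    n_test: int

    @property
    def undefined(self) -> bool:
        return self.pcc is None


def pearson_cc(x, y) -> float:
    """Product-moment correlation; errors on constant input rather than NaN."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("pearson_cc needs two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def split_train_test(ids, n_test: int = 20, seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded random partition into train/development and hold-out test ids."""
    ids = list(ids)
    if not 0 < n_test < len(ids):
        raise ValidationError(f"n_test must lie in (0, {len(ids)}), got {n_test}")
    order = np.random.default_rng(seed).permutation(len(ids))
    test = sorted(order[:n_test])
    train = sorted(order[n_test:])
    return [ids[i] for i in train], [ids[i] for i in test]


def build_estimator(model_name: str, hyperparams: dict, seed: int = 0):
    """Instantiate a regressor; SVR and KNR get an in-pipeline standardizer."""
    params = dict(hyperparams)
    if model_name == "SVR":
        # libsvm can crawl on noisy, barely-separable data at larger C; a
        # generous iteration cap changes fits negligibly but bounds runtime
        params.setdefault("max_iter", 20000)
        est = SVR(**params)
    elif model_name == "KNR":
        est = KNeighborsRegressor(**params)
    elif model_name == "RF":
        est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    elif model_name == "RF_EXTR":
        est = ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
    elif model_name == "XGB":
        from xgboost import XGBRegressor

        est = XGBRegressor(random_state=seed, n_jobs=1, verbosity=0, **params)
    else:
        raise ValidationError(f"unknown model {model_name!r}; expected {MODEL_NAMES}")
    if model_name in STANDARDIZED_MODELS:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def loocv_grid_search(
    ds: QSARDataset, model_name: str, grid: dict[str, list], seed: int = 0
) -> tuple[dict, float]:
    """Pick hyperparameters by leave-one-out mean squared error.

    Every grid point is scored by fitting n_train models, each leaving one
    chemical out, and averaging the squared error on the left-out chemical
    (a per-singleton correlation is undefined, so squared error is the
    selection metric).  Ties break toward the earlier grid point; a grid
    point whose fit fails is skipped with a warning.
    """
    n = ds.features.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 training samples for LOOCV")
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    points = _grid_points(grid)
    if not points:
        raise ValidationError("empty hyperparameter grid")

    best_params, best_score = None, np.inf
    for params in points:
        try:
            errors = np.empty(n)
            with warnings.catch_warnings():
                # the SVR iteration cap is deliberate; see build_estimator
                warnings.simplefilter("ignore", ConvergenceWarning)
                for left_out in range(n):
                    mask = np.ones(n, dtype=bool)
                    mask[left_out] = False
                    est = build_estimator(model_name, params, seed=seed)
                    est.fit(ds.features[mask], ds.response[mask])
                    pred = est.predict(ds.features[~mask])[0]
                    errors[left_out] = (pred - ds.response[left_out]) ** 2
            score = float(errors.mean())
        except Exception as exc:  # a bad grid point must not sink the search
            warnings.warn(f"grid point {params} failed for {model_name}: {exc}")
            continue
        if score < best_score:
            best_params, best_score = params, score
    if best_params is None:
        raise ValidationError(f"every grid point failed for {model_name}")
    return best_params, best_score


def evaluate_holdout(
    train: QSARDataset,
    test: QSARDataset,
    model_name: str,
    hyperparams: dict,
    seed: int = 0,
) -> EvalRecord:
    """Fit on all training chemicals, score hold-out Pearson correlation.

    Constant predictions leave the correlation undefined; the record carries
    ``pcc=None`` rather than a silent zero.
    """
    if train.feature_name != test.feature_name or train.cell_line != test.cell_line:
        raise ValidationError("train and test datasets disagree on feature/cell line")
    overlap = set(train.chemical_ids) & set(test.chemical_ids)
    if overlap:
        raise ValidationError(f"train/test chemical overlap: {sorted(overlap)[:5]}")
    est = build_estimator(model_name, hyperparams, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(train.features, train.response)
    pred = est.predict(test.features)
    try:
        pcc = pearson_cc(pred, test.response)
    except DegenerateVarianceError:
        pcc = None
    return EvalRecord(
        cell_line=train.cell_line,
        feature_name=train.feature_name,
        model_name=model_name,
        pcc=pcc,
        best_hyperparams=dict(hyperparams),
        n_train=len(train.chemical_ids),
        n_test=len(test.chemical_ids),
    )


def concatenate_features(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Column-wise concatenation after aligning b's rows to a's id order."""
    if set(a.chemical_ids) != set(b.chemical_ids):
        only_a = sorted(set(a.chemical_ids) - set(b.chemical_ids))
        only_b = sorted(set(b.chemical_ids) - set(a.chemical_ids))
        raise ValidationError(
            f"id mismatch between {a.name!r} and {b.name!r}: "
            f"only in a: {only_a[:5]}, only in b: {only_b[:5]}"
        )
    b_aligned = b.subset(a.chemical_ids)
    return FeatureTable(
        f"{a.name}+{b.name}",
        np.hstack([a.matrix, b_aligned.matrix]),
        list(a.chemical_ids),
    )


@dataclass
class BenchmarkConfig:
    """What to run: feature sets, responses, models, grids, split settings."""

    features: dict[str, FeatureTable]
    responses: pd.DataFrame  # columns: chemical_id, cell_line, auc
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    grids: dict[str, dict[str, list]] = field(default_factory=dict)
    n_test: int = 20
    split_seeds: list[int] = field(default_factory=lambda: [0])
    model_seed: int = 0


def run_benchmark(
    config: BenchmarkConfig,
) -> tuple[list[EvalRecord], pd.DataFrame, pd.DataFrame]:
    """One hold-out evaluation per (cell line x feature set x model x split).

    Returns the records plus two summaries over cell lines (averaged over
    split seeds first when several are given): mean Pearson correlation per
    (feature set, model), and mean rank per (feature set, model) where
    feature sets are ranked within each (cell line, model), rank 1 best,
    ties averaged, undefined correlations ranked worst and excluded from the
    mean correlation.
    """
    records: list[EvalRecord] = []
    cell_lines = sorted(config.responses["cell_line"].unique())
    for split_seed in config.split_seeds:
        for cell_line in cell_lines:
            sub = config.responses[config.responses["cell_line"] == cell_line]
            response = dict(zip(sub["chemical_id"].astype(str), sub["auc"].astype(float)))
            for feat_name, table in config.features.items():
                ids = [c for c in table.chemical_ids if c in response]
                train_ids, test_ids = split_train_test(ids, config.n_test, split_seed)
                tr_feat = table.subset(train_ids)
                te_feat = table.subset(test_ids)
                train = QSARDataset(
                    tr_feat.matrix,
                    np.array([response[c] for c in train_ids]),
                    train_ids,
                    feat_name,
                    cell_line,
                )
                test = QSARDataset(
                    te_feat.matrix,
                    np.array([response[c] for c in test_ids]),
                    test_ids,
                    feat_name,
                    cell_line,
                )
                for model_name in config.models:
                    grid = config.grids.get(model_name, DEFAULT_GRIDS[model_name])
                    try:
                        params, _ = loocv_grid_search(
                            train, model_name, grid, seed=config.model_seed
                        )
                        record = evaluate_holdout(
                            train, test, model_name, params, seed=config.model_seed
                        )
                    except Exception as exc:
                        logger.warning(
                            "benchmark cell (%s, %s, %s) failed: %s",
                            cell_line, feat_name, model_name, exc,
                        )
                        record = EvalRecord(
                            cell_line, feat_name, model_name, None, {}, len(train_ids), len(test_ids)
                        )
                    records.append(record)
    mean_pcc = summarize_mean_pcc(records)
    mean_rank = summarize_mean_rank(records)
    return records, mean_pcc, mean_rank


def records_to_frame(records: list[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in records],
            "feature_name": [r.feature_name for r in records],
            "model_name": [r.model_name for r in records],
            "pcc": [np.nan if r.pcc is None else r.pcc for r in records],
            "n_train": [r.n_train for r in records],
            "n_test": [r.n_test for r in records],
        }
    )


def summarize_mean_pcc(records: list[EvalRecord]) -> pd.DataFrame:
    """Mean correlation across cell lines, feature sets x models; undefined excluded."""
    df = records_to_frame(records)
    return df.pivot_table(
        index="feature_name", columns="model_name", values="pcc", aggfunc="mean"
    )


def summarize_mean_rank(records: list[EvalRecord]) -> pd.DataFrame:
    """Mean rank of each feature set within (cell line, model); rank 1 = best.

    Ranks average ties; an undefined correlation takes the worst rank in its
    group.  Invariant to any monotone transformation of the correlations
    within a cell line.
    """
    df = records_to_frame(records)
    ranked = []
    for (cell_line, model), group in df.groupby(["cell_line", "model_name"]):
        values = group["pcc"].to_numpy()
        filled = np.where(np.isnan(values), -np.inf, values)
        ranks = stats.rankdata(-filled, method="average")
        ranked.append(
            pd.DataFrame(
                {
                    "feature_name": group["feature_name"],
                    "model_name": model,
                    "rank": ranks,
                }
            )
        )
    allranks = pd.concat(ranked, ignore_index=True)
    return allranks.pivot_table(
        index="feature_name", columns="model_name", values="rank", aggfunc="mean"
    )
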