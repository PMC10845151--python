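"""Regression heads for the barrier-height correction.

Three model kinds predict the correction delta = BH_high - BH_low from the
feature matrix: gradient-boosted trees (XGBoost, hyperparameters by seeded
random search with k-fold cross-validation), Gaussian-process regression
(Matern-5/2 plus white noise on standardized inputs, giving a predictive
standard deviation), and a multitask neural head (shared fully connected
trunk with two linear outputs, the correction and the reaction energy,
weighted equally).  The corrected barrier is simply BH_low + predicted
delta.  Attributions use exact TreeSHAP for the tree head and a seeded
permutation-Shapley estimate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    DotProduct,
    Matern,
    WhiteKernel,
)
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

MODEL_KINDS = ("xgb", "gp", "multitask_nn")


@dataclass
class SplitSpec:
    """Train/validation/test fractions with a seed and CV fold count."""

    fractions: tuple[float, float, float] = (0.85, 0.05, 0.10)
    seed: int = 0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


def split(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seeded train/validation/test index arrays."""
    if n < 20:
        raise ValueError(f"need at least 20 samples to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_test = int(round(spec.fractions[2] * n))
    n_val = int(round(spec.fractions[1] * n))
    test = np.sort(perm[:n_test])
    val = np.sort(perm[n_test : n_test + n_val])
    train = np.sort(perm[n_test + n_val :])
    return train, val, test


# Small documented XGB search space; configurations are drawn from it by a
# seeded random search with k-fold CV.
XGB_SEARCH_SPACE: dict[str, list] = {
    "max_depth": [3, 4, 6, 8],
    "learning_rate": [0.03, 0.05, 0.1],
    "n_estimators": [300, 600, 1200],
    "subsample": [0.8, 1.0],
    "colsample_bytree": [0.6, 1.0],
    "min_child_weight": [1, 5],
}

_XGB_FIXED = dict(
    objective="reg:squarederror", tree_method="exact", n_jobs=1, verbosity=0
)


@dataclass
class CorrectionModel:
    """A fitted correction head; predict() requires the training columns in order."""

    kind: str
    feature_names: list[str]
    _estimator: object = field(repr=False)
    _scaler: StandardScaler | None = field(default=None, repr=False)
    _y_mean: float = 0.0
    best_params: dict = field(default_factory=dict)

    def _check(self, X: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        df = X.df if isinstance(X, FeatureMatrix) else X
        if list(df.columns) != self.feature_names:
            raise ValueError(
                "feature names/order differ from the training matrix; "
                f"expected {len(self.feature_names)} columns"
            )
        return df.to_numpy(dtype=float)

    @property
    def explainer(self):
        """Float64 tree evaluator (tree head only); built lazily and cached."""
        if self.kind != "xgb":
            raise ValueError("tree explainer requires the xgb head")
        if getattr(self, "_explainer_cache", None) is None:
            from ._treeshap import TreeExplainer

            object.__setattr__(
                self, "_explainer_cache", TreeExplainer(self._estimator.get_booster())
            )
        return self._explainer_cache

    def predict(self, X: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        x = self._check(X)
        if self.kind == "xgb":
            # double-precision traversal of the fitted trees: identical
            # routing to xgboost, but reproducible float64 accumulation
            # consistent with the Shapley decomposition
            return self.explainer.predict(x)
        x = self._scaler.transform(x)
        if self.kind == "gp":
            return self._estimator.predict(x) + self._y_mean
        pred = self._estimator.predict(x)
        return pred[:, 0]  # first head is the barrier correction

    def predict_std(self, X: FeatureMatrix | pd.DataFrame) -> np.ndarray:
        if self.kind != "gp":
            raise ValueError("predictive standard deviation requires the gp head")
        x = self._scaler.transform(self._check(X))
        _, std = self._estimator.predict(x, return_std=True)
        return std

    def gain_importances(self) -> dict[str, float]:
        if self.kind != "xgb":
            raise ValueError("gain importances require the xgb head")
        booster = self._estimator.get_booster()
        raw = booster.get_score(importance_type="gain")
        # booster keys are f0, f1, ... in column order
        return {
            self.feature_names[int(key[1:])]: val for key, val in raw.items()
        }


def _validate_xy(X: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    if np.ptp(y, axis=0).min() == 0:
        raise ValueError("degenerate target: zero variance")


def _xgb_random_search(
    x: np.ndarray, y: np.ndarray, hpo_budget: int, cv_folds: int, seed: int
) -> dict:
    rng = np.random.default_rng(seed)
    tried: list[dict] = []
    for _ in range(hpo_budget):
        params = {k: v[int(rng.integers(len(v)))] for k, v in XGB_SEARCH_SPACE.items()}
        if params not in tried:
            tried.append(params)
    if len(tried) <= 1:
        return tried[0] if tried else {}
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    best, best_mae = None, np.inf
    for params in tried:
        maes = []
        for tr, te in kf.split(x):
            model = xgb.XGBRegressor(**_XGB_FIXED, random_state=seed, **params)
            model.fit(x[tr], y[tr])
            maes.append(np.abs(model.predict(x[te]) - y[te]).mean())
        mae = float(np.mean(maes))
        if mae < best_mae:
            best, best_mae = params, mae
    return best


def train(
    kind: str,
    X: FeatureMatrix | pd.DataFrame,
    y: np.ndarray | pd.DataFrame,
    hpo_budget: int = 25,
    seed: int = 0,
    cv_folds: int = 5,
    gp_max_train: int | None = 1000,
) -> CorrectionModel:
    """Fit one correction head.

    For ``multitask_nn`` pass a two-column y (delta, reaction energy); the
    other heads take the one-dimensional delta.  ``gp_max_train`` caps the
    GP training set by a seeded subsample (cubic cost in n).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    df = X.df if isinstance(X, FeatureMatrix) else X
    names = list(df.columns)
    x = df.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_xy(x, np.atleast_2d(y.T).T)

    if kind == "xgb":
        if y.ndim != 1:
            raise ValueError("xgb head takes a one-dimensional target")
        params = _xgb_random_search(x, y, hpo_budget, cv_folds, seed)
        est = xgb.XGBRegressor(**_XGB_FIXED, random_state=seed, **params)
        est.fit(x, y)
        return CorrectionModel("xgb", names, est, best_params=params)

    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)

    if kind == "gp":
        if y.ndim != 1:
            raise ValueError("gp head takes a one-dimensional target")
        if gp_max_train is not None and x.shape[0] > gp_max_train:
            idx = np.sort(
                np.random.default_rng(seed).choice(
                    x.shape[0], gp_max_train, replace=False
                )
            )
            xs, y = xs[idx], y[idx]
        y_mean = float(y.mean())
        # linear + Matern-5/2 + noise: the linear term captures the smooth
        # dominant trend of the correction, the Matern term local deviations
        kernel = (
            DotProduct(sigma_0=1.0, sigma_0_bounds=(1e-5, 1e3))
            + ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(
                length_scale=np.sqrt(x.shape[1]),
                length_scale_bounds=(1e-2, 1e4),
                nu=2.5,
            )
            + WhiteKernel(1e-1, (1e-12, 1e3))
        )
        est = GaussianProcessRegressor(
            kernel=kernel, normalize_y=False, random_state=seed, n_restarts_optimizer=0
        )
        est.fit(xs, y - y_mean)
        return CorrectionModel("gp", names, est, _scaler=scaler, _y_mean=y_mean)

    # multitask_nn: shared trunk, two linear heads with equal loss weights
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("multitask_nn takes a two-column target (delta, de_r)")
    est = MLPRegressor(
        hidden_layer_sizes=(128, 128),
        early_stopping=True,
        validation_fraction=0.1,
        max_iter=1000,
        random_state=seed,
    )
    est.fit(xs, y)
    return CorrectionModel("multitask_nn", names, est, _scaler=scaler)


def corrected_bh(
    model: CorrectionModel, X: FeatureMatrix | pd.DataFrame, bh_low: np.ndarray
) -> np.ndarray:
    """Corrected barrier heights: low-level BH plus the predicted delta."""
    bh_low = np.asarray(bh_low, dtype=float)
    pred = model.predict(X)
    if pred.shape[0] != bh_low.shape[0]:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs {bh_low.shape[0]} barriers"
        )
    return bh_low + pred


@dataclass
class EvalReport:
    mae: float
    errors: np.ndarray
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    predictions: np.ndarray


def evaluate(
    model: CorrectionModel, X: FeatureMatrix | pd.DataFrame, y: np.ndarray, bins: int = 20
) -> EvalReport:
    """Signed-error report for the corrected barrier (equivalently for delta)."""
    pred = model.predict(X)
    errors = pred - np.asarray(y, dtype=float)
    counts, edges = np.histogram(errors, bins=bins)
    return EvalReport(
        mae=float(np.abs(errors).mean()),
        errors=errors,
        histogram_counts=counts,
        histogram_edges=edges,
        predictions=pred,
    )


def learning_curve(
    kind: str,
    X: FeatureMatrix | pd.DataFrame,
    y: np.ndarray,
    sizes: list[int],
    reps: int = 3,
    seed: int = 0,
    test_fraction: float = 0.2,
    **train_kwargs,
) -> pd.DataFrame:
    """MAE vs training-set size on a fixed held-out test set."""
    df = X.df if isinstance(X, FeatureMatrix) else X
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(df)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx, pool = perm[:n_test], perm[n_test:]
    if max(sizes) > len(pool):
        raise ValueError(f"largest size {max(sizes)} exceeds train pool {len(pool)}")
    rows = []
    for size in sizes:
        maes = []
        for rep in range(reps):
            sub = rng.choice(pool, size, replace=False)
            model = train(
                kind, df.iloc[sub], y[sub], seed=seed + rep, **train_kwargs
            )
            maes.append(evaluate(model, df.iloc[test_idx], y[test_idx]).mae)
        rows.append(
            {"n_train": size, "mae_mean": float(np.mean(maes)), "mae_sd": float(np.std(maes, ddof=1)) if reps > 1 else 0.0}
        )
    return pd.DataFrame(rows)


@dataclass
class Attribution:
    """Per-record, per-feature attributions plus the expected model output."""

    values: pd.DataFrame
    base_value: float
    ranking: list[str]

    def check_additivity(self, predictions: np.ndarray, tol: float = 1e-6) -> bool:
        total = self.values.to_numpy().sum(axis=1) + self.base_value
        return bool(np.max(np.abs(total - predictions)) <= tol)


def explain(
    model: CorrectionModel,
    X: FeatureMatrix | pd.DataFrame,
    n_permutations: int = 64,
    seed: int = 0,
) -> Attribution:
    """Shapley-value attributions.

    Tree head: exact TreeSHAP (path-dependent), additive to the prediction.
    Other heads: a seeded permutation-Shapley estimate against the dataset
    background (slower, approximate).
    """
    df = X.df if isinstance(X, FeatureMatrix) else X
    x = model._check(df)
    if model.kind == "xgb":
        explainer = model.explainer
        phi = explainer.shap_values(x, len(model.feature_names))
        values = pd.DataFrame(phi, columns=model.feature_names)
        base = float(explainer.expected_value)
    else:
        values, base = _permutation_shapley(model, df, n_permutations, seed)
    ranking = list(
        values.abs().mean(axis=0).sort_values(ascending=False, kind="stable").index
    )
    return Attribution(values=values, base_value=base, ranking=ranking)


def _permutation_shapley(
    model: CorrectionModel, df: pd.DataFrame, n_permutations: int, seed: int
) -> tuple[pd.DataFrame, float]:
    rng = np.random.default_rng(seed)
    x = df.to_numpy(dtype=float)
    n, f = x.shape
    background = x.mean(axis=0)
    base = float(model.predict(pd.DataFrame([background], columns=df.columns))[0])
    attr = np.zeros((n, f))
    for _ in range(n_permutations):
        order = rng.permutation(f)
        current = np.tile(background, (n, 1))
        prev = model.predict(pd.DataFrame(current, columns=df.columns))
        for j in order:
            current[:, j] = x[:, j]
            nxt = model.predict(pd.DataFrame(current, columns=df.columns))
            attr[:, j] += nxt - prev
            prev = nxt
    attr /= n_permutations
    return pd.DataFrame(attr, columns=list(df.columns)), base


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

_ARCHIVE_FORMAT = 1


def save_model(model: CorrectionModel, path) -> None:
    """Persist a fitted head to a versioned pickle archive."""
    import pickle
    from pathlib import Path

    from . import __version__

    state = dict(model.__dict__)
    state.pop("_explainer_cache", None)  # rebuilt lazily on load
    payload = {
        "archive_format": _ARCHIVE_FORMAT,
        "deltabh_version": __version__,
        "state": state,
    }
    Path(path).write_bytes(pickle.dumps(payload))


def load_model(path) -> CorrectionModel:
    """Load a head saved by save_model; rejects unknown archive formats."""
    import pickle
    from pathlib import Path

    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("archive_format") != _ARCHIVE_FORMAT:
        raise ValueError(
            f"unsupported model archive format {payload.get('archive_format')!r}"
        )
    model = CorrectionModel.__new__(CorrectionModel)
    model.__dict__.update(payload["state"])
    return model
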