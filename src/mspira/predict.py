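"""Nested-cross-validated PIRA prediction benchmark.

Four model families (elastic-net logistic regression, random forest,
XGBoost, single-hidden-layer neural network) are evaluated over four
cumulatively nested predictor sets (demographics -> + MS characteristics ->
+ pre-specified comorbidity flags -> + ICD-10 categories) with:

* leakage-safe preprocessing fitted inside every training partition:
  normalization of numerics, bagged-tree imputation (25 trees; the
  imputation model sees the outcome and the current predictor set except
  the ICD-category block), dummy encoding of nominals;
* hyperparameter tuning on a full-factorial regular grid with four levels
  per tuned parameter, selected by mean inner-CV Brier score;
* outer resampling of 10 folds x 3 repeats (stratified), inner 5 folds;
* AUC (Mann-Whitney form), Brier score, and quantile calibration bins
  (bin edges from the predicted probabilities of outcome-positive
  observations).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PredictorSetSpec",
    "ModelSpec",
    "PredictionEval",
    "MODEL_SPECS",
    "DEMOGRAPHIC_COLS",
    "MS_CHARACTERISTIC_COLS",
    "make_predictor_sets",
    "Preprocessor",
    "brier_score",
    "auc",
    "calibration_bins",
    "nested_cv_evaluate",
]

DEMOGRAPHIC_COLS = ("age_at_start", "sex", "born_in_country", "income", "education", "area")
MS_CHARACTERISTIC_COLS = (
    "therapy_start_year",
    "years_since_onset",
    "n_prior_dmts",
    "n_prior_relapses",
    "baseline_edss",
    "sdmt",
    "msis_physical",
    "msis_psychological",
)
NOMINAL_COLS = ("sex", "education", "area")


@dataclass(frozen=True)
class PredictorSetSpec:
    name: str
    columns: tuple[str, ...]
    icd_columns: tuple[str, ...] = ()  # excluded from the imputation model


@dataclass(frozen=True)
class ModelSpec:
    family: str
    fixed: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)  # name -> tuple of candidate values

    def configurations(self) -> list[dict]:
        names = sorted(self.grid)
        return [dict(zip(names, vals)) for vals in itertools.product(*(self.grid[n] for n in names))]


#: Tuned grids: four levels per tuned hyperparameter, full factorial.
#: Fixed values: rf 1000 trees; xgb 1000 trees with 10 stopping rounds;
#: nn 50 hidden units.
MODEL_SPECS: dict[str, ModelSpec] = {
    "elastic_net": ModelSpec(
        "elastic_net",
        fixed={},
        grid={"penalty": (1e-4, 1e-3, 1e-2, 1e-1), "mixture": (0.0, 1 / 3, 2 / 3, 1.0)},
    ),
    "random_forest": ModelSpec(
        "random_forest",
        fixed={"n_trees": 1000},
        grid={"mtry_factor": (0.5, 1.0, 2.0, 4.0), "min_node": (2, 5, 10, 20)},
    ),
    "xgboost": ModelSpec(
        "xgboost",
        fixed={"n_trees": 1000, "stopping_rounds": 10},
        grid={
            "learning_rate": (0.01, 0.05, 0.1, 0.3),
            "max_depth": (2, 4, 6, 8),
            "min_child_weight": (1, 3, 5, 10),
        },
    ),
    "neural_net": ModelSpec(
        "neural_net",
        fixed={"hidden_units": 50},
        grid={"weight_decay": (1e-4, 1e-3, 1e-2, 1e-1), "epochs": (25, 50, 100, 200)},
    ),
}


@dataclass
class PredictionEval:
    model: str
    predictor_set: str
    auc_mean: float
    auc_se: float
    brier_mean: float
    brier_se: float
    fold_auc: list[float]
    fold_brier: list[float]
    calibration: pd.DataFrame
    tuning_trace: list[dict]


def make_predictor_sets(features: pd.DataFrame, icd_columns) -> list[PredictorSetSpec]:
    """The four cumulative predictor sets; raises on missing columns."""
    icd_columns = tuple(icd_columns)
    sets = [
        PredictorSetSpec("demographics", DEMOGRAPHIC_COLS),
        PredictorSetSpec("ms_characteristics", DEMOGRAPHIC_COLS + MS_CHARACTERISTIC_COLS),
    ]
    prespec = tuple(
        c
        for c in features.columns
        if c not in DEMOGRAPHIC_COLS + MS_CHARACTERISTIC_COLS + icd_columns + ("pira", "patient_id")
    )
    sets.append(PredictorSetSpec("prespecified", sets[1].columns + prespec))
    sets.append(
        PredictorSetSpec("data_driven", sets[2].columns + icd_columns, icd_columns=icd_columns)
    )
    for s in sets:
        missing = [c for c in s.columns if c not in features.columns]
        if missing:
            raise ValueError(f"predictor set {s.name!r}: missing columns {missing}")
    return sets


class Preprocessor:
    """Train-fitted preprocessing applied unchanged to new data.

    Nominal columns: missing values become an explicit level; dummy
    encoding uses the categories seen in training (unseen categories map to
    an all-zero block). `drop_first` gives a full-rank encoding for the
    linear/NN families. Numeric columns with missing values are imputed by
    a bagged-tree model (25 trees) whose predictors are the outcome plus
    the other predictors, excluding ICD-category columns; numerics are then
    normalized with training means/SDs.
    """

    def __init__(self, columns, nominal=NOMINAL_COLS, icd_columns=(), drop_first=False, n_bags=25, seed=0):
        self.columns = tuple(columns)
        self.nominal = tuple(c for c in nominal if c in self.columns)
        self.numeric = tuple(c for c in self.columns if c not in self.nominal)
        self.icd_columns = tuple(c for c in icd_columns if c in self.columns)
        self.drop_first = drop_first
        self.n_bags = n_bags
        self.seed = seed
        self._categories: dict[str, list] = {}
        self._imputers: dict[str, object] = {}
        self._means: pd.Series | None = None
        self._sds: pd.Series | None = None

    # -- helpers ----------------------------------------------------------
    def _encode_nominal(self, df: pd.DataFrame) -> pd.DataFrame:
        blocks = []
        for c in self.nominal:
            vals = df[c].astype(object).where(df[c].notna(), "(missing)")
            cats = self._categories[c]
            use = cats[1:] if self.drop_first else cats
            block = pd.DataFrame(
                {f"{c}__{lvl}": (vals == lvl).astype(float).to_numpy() for lvl in use},
                index=df.index,
            )
            blocks.append(block)
        return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)

    def _impute_base(self, df: pd.DataFrame, y: np.ndarray | None) -> np.ndarray:
        """Predictor matrix for the imputation model (outcome + non-ICD
        predictors; NaNs allowed, trees split on them natively)."""
        num = [c for c in self.numeric if c not in self.icd_columns]
        parts = [df[num].to_numpy(dtype=float)]
        enc = self._encode_nominal(df)
        if enc.shape[1]:
            parts.append(enc.to_numpy(dtype=float))
        out = y if y is not None else np.full(len(df), np.nan)
        parts.append(np.asarray(out, dtype=float).reshape(-1, 1))
        return np.column_stack(parts)

    # -- fit / transform ---------------------------------------------------
    def fit(self, df: pd.DataFrame, y: np.ndarray) -> "Preprocessor":
        from sklearn.ensemble import BaggingRegressor
        from sklearn.tree import DecisionTreeRegressor

        df = df[list(self.columns)]
        for c in self.nominal:
            vals = df[c].astype(object).where(df[c].notna(), "(missing)")
            self._categories[c] = sorted(set(vals))
        base = self._impute_base(df, y)
        for j, c in enumerate(self.numeric):
            col = df[c].to_numpy(dtype=float)
            na = np.isnan(col)
            if not na.any() or c in self.icd_columns:
                continue
            X = np.delete(base, self._numeric_pos(c), axis=1)
            imp = BaggingRegressor(
                DecisionTreeRegressor(random_state=self.seed),
                n_estimators=self.n_bags,
                random_state=self.seed,
            )
            obs_rows = ~na
            X_obs = np.nan_to_num(X[obs_rows], nan=-9e9)  # sentinel for residual NaNs
            imp.fit(X_obs, col[obs_rows])
            self._imputers[c] = imp
        filled = self._fill_numeric(df, y)
        self._means = filled.mean()
        sds = filled.std(ddof=0).replace(0.0, 1.0)
        self._sds = sds
        return self

    def _numeric_pos(self, c: str) -> int:
        num = [x for x in self.numeric if x not in self.icd_columns]
        return num.index(c) if c in num else -1  # ICD cols are never imputed

    def _fill_numeric(self, df: pd.DataFrame, y: np.ndarray | None) -> pd.DataFrame:
        base = self._impute_base(df, y)
        out = df[list(self.numeric)].astype(float).copy()
        for c, imp in self._imputers.items():
            col = out[c].to_numpy()
            na = np.isnan(col)
            if na.any():
                X = np.delete(base, self._numeric_pos(c), axis=1)
                col[na] = imp.predict(np.nan_to_num(X[na], nan=-9e9))
                out[c] = col
        # any numeric still missing (e.g. no imputer fitted) -> training mean
        if self._means is not None:
            out = out.fillna(self._means[list(self.numeric)])
        else:
            out = out.fillna(out.mean())
        return out

    def transform(self, df: pd.DataFrame, y: np.ndarray | None = None) -> pd.DataFrame:
        df = df[list(self.columns)]
        num = self._fill_numeric(df, y)
        num = (num - self._means[list(self.numeric)]) / self._sds[list(self.numeric)]
        enc = self._encode_nominal(df)
        return pd.concat([num, enc], axis=1)


def preprocess_fit_apply(
    train: pd.DataFrame,
    y_train: np.ndarray,
    apply_to: pd.DataFrame,
    y_apply: np.ndarray | None = None,
    columns=None,
    icd_columns=(),
    drop_first=False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, "Preprocessor"]:
    """Fit preprocessing on the training partition only, apply to both."""
    columns = tuple(columns) if columns is not None else tuple(train.columns)
    prep = Preprocessor(columns, icd_columns=icd_columns, drop_first=drop_first, seed=seed)
    prep.fit(train, np.asarray(y_train, dtype=float))
    return prep.transform(train, y_train), prep.transform(apply_to, y_apply), prep


# ---------------------------------------------------------------------------
# metrics


def brier_score(probs, labels) -> float:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probs and labels differ in length")
    return float(np.mean((p - y) ** 2))


def auc(probs, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    from scipy.stats import rankdata

    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def calibration_bins(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Quantile calibration table.

    Bin edges are quantiles of the predicted probabilities restricted to
    outcome-positive observations; all observations are then assigned by
    those edges. Duplicate edges (few distinct positive probabilities)
    collapse into fewer bins.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.sum() < 1:
        raise ValueError("calibration bins need at least one positive label")
    pos = p[y == 1]
    edges = np.unique(np.quantile(pos, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        edges = np.array([pos[0] - 1e-9, pos[0] + 1e-9])
    inner = edges[1:-1]
    idx = np.searchsorted(inner, p, side="right")
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_predicted": float(p[sel].mean()) if sel.any() else np.nan,
                "observed_rate": float(y[sel].mean()) if sel.any() else np.nan,
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model construction


def _build_estimator(family: str, fixed: dict, params: dict, n_features: int, seed: int):
    if family == "elastic_net":
        from sklearn.linear_model import LogisticRegression

        lam = params["penalty"]
        return LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            C=1.0 / max(lam, 1e-12),
            l1_ratio=params["mixture"],
            max_iter=5000,
            random_state=seed,
        )
    if family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        mtry = max(1, min(n_features, int(round(math.sqrt(n_features) * params["mtry_factor"]))))
        return RandomForestClassifier(
            n_estimators=fixed.get("n_trees", 1000),
            max_features=mtry,
            min_samples_leaf=params["min_node"],
            random_state=seed,
            n_jobs=1,
        )
    if family == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=fixed.get("n_trees", 1000),
            early_stopping_rounds=fixed.get("stopping_rounds", 10),
            learning_rate=params["learning_rate"],
            max_depth=params["max_depth"],
            min_child_weight=params["min_child_weight"],
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    if family == "neural_net":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=(fixed.get("hidden_units", 50),),
            alpha=params["weight_decay"],
            max_iter=params["epochs"],
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


def _fit_predict(family, fixed, params, X_tr, y_tr, X_te, seed):
    import warnings

    est = _build_estimator(family, fixed, params, X_tr.shape[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "xgboost":
            from sklearn.model_selection import train_test_split

            X_fit, X_val, y_fit, y_val = train_test_split(
                X_tr, y_tr, test_size=0.2, stratify=y_tr, random_state=seed
            )
            est.fit(X_fit, y_fit, eval_set=[(X_val, y_val)], verbose=False)
        else:
            est.fit(X_tr, y_tr)
    return est.predict_proba(X_te)[:, 1]


def nested_cv_evaluate(
    features: pd.DataFrame,
    outcome: np.ndarray,
    model: ModelSpec | str,
    predictor_set: PredictorSetSpec,
    outer: tuple[int, int] = (10, 3),
    inner: int = 5,
    seed: int = 0,
    n_calibration_bins: int = 10,
) -> PredictionEval:
    """Nested cross-validation for one model x predictor-set cell.

    For each outer split, the full hyperparameter grid is scored by inner
    CV (mean Brier) on the outer-training part only, the winning
    configuration is refit on the outer-training part, and probabilities
    are predicted for the outer-test part. Preprocessing is fitted inside
    every training partition. Calibration bins are computed on the pooled
    out-of-fold predictions.
    """
    from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

    if isinstance(model, str):
        model = MODEL_SPECS[model]
    y = np.asarray(outcome, dtype=int)
    X = features[list(predictor_set.columns)]
    drop_first = model.family in ("elastic_net", "neural_net")
    configs = model.configurations()

    outer_cv = RepeatedStratifiedKFold(n_splits=outer[0], n_repeats=outer[1], random_state=seed)
    fold_auc, fold_brier, trace = [], [], []
    pooled_p, pooled_y = [], []
    for fold_i, (tr, te) in enumerate(outer_cv.split(X, y)):
        X_tr, y_tr = X.iloc[tr], y[tr]
        X_te, y_te = X.iloc[te], y[te]
        fold_seed = seed * 1000 + fold_i

        # inner tuning on the outer-training part only
        best_cfg, best_brier = None, math.inf
        if len(configs) == 1:
            best_cfg = configs[0]
        else:
            inner_cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=fold_seed)
            inner_splits = list(inner_cv.split(X_tr, y_tr))
            prepped = []
            for itr, ite in inner_splits:
                a, b, _ = preprocess_fit_apply(
                    X_tr.iloc[itr], y_tr[itr], X_tr.iloc[ite], y_tr[ite],
                    icd_columns=predictor_set.icd_columns, drop_first=drop_first, seed=fold_seed,
                )
                prepped.append((a.to_numpy(), y_tr[itr], b.to_numpy(), y_tr[ite]))
            for cfg in configs:
                briers = []
                for Xa, ya, Xb, yb in prepped:
                    try:
                        p = _fit_predict(model.family, model.fixed, cfg, Xa, ya, Xb, fold_seed)
                        briers.append(brier_score(p, yb))
                    except Exception:
                        briers = None
                        break
                if briers is not None:
                    mb = float(np.mean(briers))
                    if mb < best_brier:
                        best_brier, best_cfg = mb, cfg
            if best_cfg is None:
                raise RuntimeError("no hyperparameter configuration converged")

        A, B, _ = preprocess_fit_apply(
            X_tr, y_tr, X_te, y_te,
            icd_columns=predictor_set.icd_columns, drop_first=drop_first, seed=fold_seed,
        )
        p_te = _fit_predict(model.family, model.fixed, best_cfg, A.to_numpy(), y_tr, B.to_numpy(), fold_seed)
        fold_auc.append(auc(p_te, y_te))
        fold_brier.append(brier_score(p_te, y_te))
        trace.append({"fold": fold_i, "config": dict(best_cfg)})
        pooled_p.append(p_te)
        pooled_y.append(y_te)

    n_folds = len(fold_auc)
    calib = calibration_bins(np.concatenate(pooled_p), np.concatenate(pooled_y), n_calibration_bins)
    return PredictionEval(
        model=model.family,
        predictor_set=predictor_set.name,
        auc_mean=float(np.mean(fold_auc)),
        auc_se=float(np.std(fold_auc, ddof=1) / math.sqrt(n_folds)),
        brier_mean=float(np.mean(fold_brier)),
        brier_se=float(np.std(fold_brier, ddof=1) / math.sqrt(n_folds)),
        fold_auc=fold_auc,
        fold_brier=fold_brier,
        calibration=calib,
        tuning_trace=trace,
    )
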