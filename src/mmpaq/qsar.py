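"""Consensus QSAR modeling on molecular fingerprints and 2D descriptors.

Four machine-learning algorithms (random forest, gradient boosting, SVM,
XGBoost) are each trained on two molecular representations (166-key MACCS
structural fingerprint, and a panel of open 2D physicochemical/topological
descriptors), giving eight single models.  The consensus model averages their
outputs — predicted values in regression, positive-class probabilities in
classification.  Hyperparameters are chosen by exhaustive grid search on a
scaffold-based validation split; evaluation uses scaffold-stratified k-fold
cross-validation and a held-out test set.

:class:`ConsensusModel` is a scikit-learn compatible estimator whose X is a
sequence of SMILES strings (featurization is part of the model, since each
inner model owns its descriptor set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.feature_selection import RFE
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import ParameterGrid
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from xgboost import XGBClassifier, XGBRegressor

from mmpaq.molprep import MoleculeRecord, compute_scaffold

logger = logging.getLogger(__name__)

#: value reported when a metric's denominator is empty (e.g. SE with no positives)
UNDEFINED_METRIC = None

#: Open 2D descriptor panel: physicochemical, topological and pharmacophore-count
#: descriptors computable from the molecular graph alone.
OPEN2D_DESCRIPTORS = [
    "MolWt",
    "HeavyAtomCount",
    "MolLogP",
    "MolMR",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "NumAromaticRings",
    "NumAliphaticRings",
    "NumSaturatedRings",
    "RingCount",
    "FractionCSP3",
    "NumHeteroatoms",
    "NHOHCount",
    "NOCount",
    "LabuteASA",
    "BalabanJ",
    "BertzCT",
    "Chi0",
    "Chi1",
    "Chi0v",
    "Chi1v",
    "Chi2v",
    "Chi3v",
    "Kappa1",
    "Kappa2",
    "Kappa3",
    "HallKierAlpha",
    "MaxPartialCharge",
    "MinPartialCharge",
    "PEOE_VSA1",
    "PEOE_VSA2",
    "PEOE_VSA6",
    "PEOE_VSA7",
    "PEOE_VSA8",
    "SMR_VSA5",
    "SMR_VSA7",
    "SlogP_VSA2",
    "SlogP_VSA5",
    "EState_VSA2",
    "EState_VSA8",
    "qed",
]

DEFAULT_ALGORITHMS = ("rf", "gb", "svm", "xgboost")
DEFAULT_DESCRIPTOR_SETS = ("maccs", "open2d")

#: compact default grids; override per algorithm via the ``grid`` argument
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "rf": [{"n_estimators": [200], "min_samples_leaf": [1, 3]}],
    "gb": [{"n_estimators": [200], "learning_rate": [0.1], "max_depth": [3]}],
    "svm": [{"C": [1.0, 10.0], "gamma": ["scale"]}],
    "xgboost": [{"n_estimators": [200], "learning_rate": [0.1], "max_depth": [4]}],
}


# ---------------------------------------------------------------------------
# featurization


def _featurize_one(smiles: str, descriptor_set: str) -> np.ndarray | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        if descriptor_set == "maccs":
            fp = MACCSkeys.GenMACCSKeys(mol)
            return np.array(fp, dtype=float)[1:]  # bit 0 is always unset padding
        values = []
        for name in OPEN2D_DESCRIPTORS:
            fn = getattr(Descriptors, name)
            values.append(float(fn(mol)))
        arr = np.asarray(values, dtype=float)
        if not np.all(np.isfinite(arr)):
            return None
        return arr
    except Exception:
        return None


def featurize(
    records: list[MoleculeRecord] | list[str], descriptor_set: str = "maccs"
) -> pd.DataFrame:
    """Feature matrix for a set of curated molecules.

    Rows are indexed by record id (or positional index for raw SMILES); a
    molecule that fails featurization is dropped with a log entry.
    """
    if descriptor_set not in {"maccs", "open2d"}:
        raise ValueError(f"unknown descriptor set: {descriptor_set!r}")
    ids, smiles_list = [], []
    for i, rec in enumerate(records):
        if isinstance(rec, MoleculeRecord):
            ids.append(rec.id)
            smiles_list.append(rec.smiles_canonical)
        else:
            ids.append(str(i))
            smiles_list.append(rec)
    if descriptor_set == "maccs":
        columns = [f"maccs_{i}" for i in range(1, 167)]
    else:
        columns = list(OPEN2D_DESCRIPTORS)
    rows, kept = [], []
    for mol_id, smi in zip(ids, smiles_list):
        row = _featurize_one(smi, descriptor_set)
        if row is None:
            logger.info("featurization failed for %s (%s); row dropped", mol_id, smi)
            continue
        rows.append(row)
        kept.append(mol_id)
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(columns))),
                        index=kept, columns=columns)


def select_features(
    X: pd.DataFrame,
    variance_floor: float = 1e-8,
    corr_ceiling: float = 0.95,
    rfe_target: int | None = None,
    rfe_estimator=None,
    y: np.ndarray | None = None,
) -> list[str]:
    """Three-stage feature selection; returns surviving column names in order.

    Stage 1 drops columns whose variance is zero or close to zero; stage 2
    drops, from each pair with |r| above ``corr_ceiling``, the later column in
    the current order; stage 3 (optional) runs recursive feature elimination
    down to ``rfe_target`` columns with the given base learner.
    """
    if X.shape[1] < 2:
        raise ValueError("feature matrix must have at least two columns")
    variances = X.var(axis=0, ddof=1)
    cols = [c for c in X.columns if variances[c] > variance_floor]
    if cols:
        corr = X[cols].corr().abs().to_numpy()
        keep: list[int] = []
        for j in range(len(cols)):
            if all(corr[j, i] <= corr_ceiling for i in keep):
                keep.append(j)
        cols = [cols[j] for j in keep]
    if not cols:
        raise ValueError(
            "all columns removed; loosen variance_floor or corr_ceiling"
        )
    if rfe_target is not None and rfe_target < len(cols):
        if y is None:
            raise ValueError("recursive elimination requires y")
        est = rfe_estimator or RandomForestRegressor(
            n_estimators=100, random_state=0, n_jobs=1
        )
        rfe = RFE(est, n_features_to_select=rfe_target)
        rfe.fit(X[cols].to_numpy(), y)
        cols = [c for c, kept in zip(cols, rfe.support_) if kept]
    return cols


# ---------------------------------------------------------------------------
# splitting


def _scaffold_groups(records: list[MoleculeRecord]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(compute_scaffold(rec, "murcko"), []).append(i)
    return groups


def scaffold_split(
    records: list[MoleculeRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], list[MoleculeRecord]]:
    """Train/validation/test split keeping each Murcko-scaffold group intact.

    Scaffold groups are shuffled with the seed, ordered largest-first, and
    assigned greedily to the partition with the largest remaining deficit
    (train, then validation, then test on ties).
    """
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError("ratios must sum to 1")
    groups = _scaffold_groups(records)
    if len(groups) < 3:
        raise ValueError(
            f"need at least 3 distinct scaffolds for a 3-way split, got {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: shuffle breaks ties
    n = len(records)
    targets = [r * n for r in ratios]
    filled = [0.0, 0.0, 0.0]
    parts: list[list[int]] = [[], [], []]
    for key in keys:
        # relative deficit: keeps the small partitions from starving
        deficits = [
            (targets[p] - filled[p]) / targets[p] if targets[p] > 0 else -1.0
            for p in range(3)
        ]
        p = int(np.argmax(deficits))
        parts[p].extend(groups[key])
        filled[p] += len(groups[key])
    train, val, test = ([records[i] for i in sorted(part)] for part in parts)
    return train, val, test


# ---------------------------------------------------------------------------
# single-model construction


def _make_estimator(algorithm: str, task: str, params: dict, seed: int):
    if algorithm == "rf":
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(random_state=seed, n_jobs=1, **params)
    if algorithm == "gb":
        cls = (
            GradientBoostingRegressor
            if task == "regression"
            else GradientBoostingClassifier
        )
        return cls(random_state=seed, **params)
    if algorithm == "svm":
        # SVMs need standardized inputs; scaling statistics come from the
        # training set only (the pipeline refits the scaler on .fit)
        if task == "regression":
            return make_pipeline(StandardScaler(), SVR(**params))
        return make_pipeline(StandardScaler(), SVC(probability=True,
                                                   random_state=seed, **params))
    if algorithm == "xgboost":
        cls = XGBRegressor if task == "regression" else XGBClassifier
        return cls(random_state=seed, n_jobs=1, verbosity=0, **params)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def _predict(est, X: np.ndarray, task: str) -> np.ndarray:
    if task == "regression":
        return np.asarray(est.predict(X), dtype=float)
    proba = est.predict_proba(X)
    positive = list(est.classes_).index(1)
    return np.asarray(proba[:, positive], dtype=float)


def tune_and_fit(
    algorithm: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid: list[dict] | dict | None = None,
    task: str = "regression",
    seed: int = 0,
):
    """Exhaustive grid search against a validation set; refit on train.

    Selection criterion: validation RMSE (regression, lower better) or
    validation AUC (classification, higher better); ties keep the earlier
    grid point.  Returns (fitted estimator, chosen params, grid table).
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[algorithm]
    param_sets = list(ParameterGrid(grid))
    if not param_sets:
        raise ValueError("empty hyperparameter grid")
    if task == "classification" and len(np.unique(y_train)) < 2:
        raise ValueError("degenerate labels: single class in training data")
    table = []
    best_score, best_params = None, None
    for params in param_sets:
        est = _make_estimator(algorithm, task, params, seed)
        est.fit(X_train, y_train)
        pred = _predict(est, X_val, task)
        if task == "regression":
            score = -float(np.sqrt(np.mean((y_val - pred) ** 2)))
        else:
            score = float(roc_auc_score(y_val, pred))
        table.append({"params": params, "score": score})
        if best_score is None or score > best_score:
            best_score, best_params = score, params
    est = _make_estimator(algorithm, task, best_params, seed)
    est.fit(X_train, y_train)
    return est, best_params, table


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ClassificationMetrics:
    TP: int
    TN: int
    FP: int
    FN: int
    ACC: float
    SE: float | None
    SP: float | None
    precision: float | None
    recall: float | None
    F1: float | None
    AUC: float | None


@dataclass
class RegressionMetrics:
    Q2_or_R2: float
    MAE: float
    RMSE: float


def evaluate(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    task: str = "regression",
    scores: np.ndarray | None = None,
) -> ClassificationMetrics | RegressionMetrics:
    """Standard QSAR evaluation metrics.

    Classification expects hardened 0/1 labels in ``y_pred`` (and optionally
    continuous ``scores`` for AUC); regression reports the coefficient of
    determination (Q2/R2), mean absolute error and root mean squared error.
    A metric whose denominator is empty is reported as None, never NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    if task == "regression":
        resid = y_true - y_pred
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        return RegressionMetrics(
            Q2_or_R2=r2,
            MAE=float(np.mean(np.abs(resid))),
            RMSE=float(np.sqrt(np.mean(resid**2))),
        )
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num, den):
        return num / den if den > 0 else UNDEFINED_METRIC

    se = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    f1 = (
        2 * prec * se / (prec + se)
        if prec is not None and se is not None and (prec + se) > 0
        else UNDEFINED_METRIC
    )
    auc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return ClassificationMetrics(
        TP=tp,
        TN=tn,
        FP=fp,
        FN=fn,
        ACC=(tp + tn) / (tp + tn + fp + fn),
        SE=se,
        SP=ratio(tn, tn + fp),
        precision=prec,
        recall=se,
        F1=f1,
        AUC=auc,
    )


# ---------------------------------------------------------------------------
# consensus estimator


class ConsensusModel(BaseEstimator):
    """Averaging consensus over (algorithm x descriptor set) single models.

    scikit-learn compatible: ``fit(X, y)`` where X is a sequence of SMILES
    strings.  A validation set for grid search may be passed to ``fit``; with
    none given, a scaffold split of the training data supplies it.

    Fitted attributes: ``single_models_`` (list of fitted estimators),
    ``model_specs_`` (algorithm, descriptor set per single model),
    ``hyperparameters_``, ``feature_columns_``, ``n_models_``.

    The consensus prediction is the arithmetic mean of the single-model
    outputs: predicted value (regression) or positive-class probability
    (classification).
    """

    def __init__(
        self,
        task: str = "regression",
        algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
        descriptor_sets: tuple[str, ...] = DEFAULT_DESCRIPTOR_SETS,
        grid: dict | None = None,
        variance_floor: float = 1e-8,
        corr_ceiling: float = 0.95,
        seed: int = 0,
    ):
        self.task = task
        self.algorithms = algorithms
        self.descriptor_sets = descriptor_sets
        self.grid = grid
        self.variance_floor = variance_floor
        self.corr_ceiling = corr_ceiling
        self.seed = seed

    def _featurize(self, smiles: list[str], descriptor_set: str) -> np.ndarray:
        X = featurize(list(smiles), descriptor_set)
        if X.shape[0] != len(smiles):
            raise ValueError("featurization failed for some fitted/query molecules")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        smiles = list(X)
        y = np.asarray(y, dtype=float)
        if X_val is None:
            # hold out ~20% by scaffold for hyperparameter selection
            recs = [
                MoleculeRecord(id=str(i), smiles_canonical=s, property=v)
                for i, (s, v) in enumerate(zip(smiles, y))
            ]
            tr, va, te = scaffold_split(recs, (0.8, 0.1, 0.1), seed=self.seed)
            va = va + te
            smiles_tr = [r.smiles_canonical for r in tr]
            y_tr = np.array([r.property for r in tr])
            smiles_va = [r.smiles_canonical for r in va]
            y_va = np.array([r.property for r in va])
        else:
            smiles_tr, y_tr = smiles, y
            smiles_va, y_va = list(X_val), np.asarray(y_val, dtype=float)

        self.single_models_ = []
        self.model_specs_ = []
        self.hyperparameters_ = {}
        self.feature_columns_ = {}
        for descriptor_set in self.descriptor_sets:
            Xtr = self._featurize(smiles_tr, descriptor_set)
            Xva = self._featurize(smiles_va, descriptor_set)
            cols = select_features(
                Xtr, self.variance_floor, self.corr_ceiling
            )
            self.feature_columns_[descriptor_set] = cols
            for algorithm in self.algorithms:
                grid = (self.grid or {}).get(algorithm) if self.grid else None
                est, params, _ = tune_and_fit(
                    algorithm,
                    Xtr[cols].to_numpy(),
                    y_tr,
                    Xva[cols].to_numpy(),
                    y_va,
                    grid=grid,
                    task=self.task,
                    seed=self.seed,
                )
                self.single_models_.append(est)
                self.model_specs_.append((algorithm, descriptor_set))
                self.hyperparameters_[(algorithm, descriptor_set)] = params
        self.n_models_ = len(self.single_models_)
        return self

    def predict_singles(self, X) -> np.ndarray:
        """Matrix of single-model outputs, shape (n_molecules, n_models)."""
        smiles = list(X)
        features = {
            ds: self._featurize(smiles, ds)[self.feature_columns_[ds]].to_numpy()
            for ds in self.descriptor_sets
        }
        cols = []
        for est, (algorithm, ds) in zip(self.single_models_, self.model_specs_):
            cols.append(_predict(est, features[ds], self.task))
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        """Consensus output: mean of single-model values/probabilities."""
        return self.predict_singles(X).mean(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is classification-only")
        p = self.predict(X)
        return np.column_stack([1 - p, p])

    def predict_labels(self, X, cutoff: float = 0.5) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_labels is classification-only")
        return (self.predict(X) >= cutoff).astype(int)


# ---------------------------------------------------------------------------
# cross-validation


def _assign_folds(groups: dict[str, list[int]], k: int, rng) -> list[list[int]]:
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda g: -len(groups[g]))
    folds: list[list[int]] = [[] for _ in range(k)]
    sizes = [0] * k
    for key in keys:
        f = int(np.argmin(sizes))
        folds[f].extend(groups[key])
        sizes[f] += len(groups[key])
    return folds


def cross_validate(
    model,
    records: list[MoleculeRecord],
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    task: str = "regression",
) -> dict:
    """Repeated scaffold-stratified k-fold cross-validation.

    Folds group by Murcko scaffold; each repeat reshuffles the fold
    assignment with a fresh seed derived from ``seed``.  Metrics are computed
    on predictions pooled across the k folds of a repeat, and summarized as
    the mean across repeats.  ``model`` is any clonable estimator taking
    SMILES X (e.g. :class:`ConsensusModel`).
    """
    smiles = [r.smiles_canonical for r in records]
    y = np.array([r.property for r in records], dtype=float)
    groups = _scaffold_groups(records)
    if len(groups) < k:
        raise ValueError(f"need at least {k} scaffold groups, got {len(groups)}")
    per_repeat = []
    oof_last = None
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        folds = _assign_folds(groups, k, rng)
        oof = np.full(len(records), np.nan)
        for fold in folds:
            test_idx = sorted(fold)
            train_idx = sorted(set(range(len(records))) - set(fold))
            est = clone(model)
            est.fit([smiles[i] for i in train_idx], y[train_idx])
            oof[test_idx] = est.predict([smiles[i] for i in test_idx])
        if task == "regression":
            per_repeat.append(evaluate(y, oof, "regression"))
        else:
            labels = (oof >= 0.5).astype(int)
            per_repeat.append(evaluate(y.astype(int), labels, "classification", scores=oof))
        oof_last = oof
    summary = {}
    fields = (
        ("Q2_or_R2", "MAE", "RMSE")
        if task == "regression"
        else ("ACC", "SE", "SP", "precision", "F1", "AUC")
    )
    for f in fields:
        vals = [getattr(m, f) for m in per_repeat if getattr(m, f) is not None]
        summary[f] = float(np.mean(vals)) if vals else None
    return {"mean": summary, "per_repeat": per_repeat, "oof_predictions": oof_last}
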