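import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from mmpaq.fixtures import FixtureSpec, extended_spec, generate_library
from mmpaq.molprep import MoleculeRecord
from mmpaq.qsar import (
    ConsensusModel,
    cross_validate,
    evaluate,
    featurize,
    scaffold_split,
    select_features,
    tune_and_fit,
)


def _rec(mol_id, smiles, value=1.0):
    return MoleculeRecord(id=mol_id, smiles_canonical=smiles, property=value)


# ---------------------------------------------------------------------------
# featurization


def test_featurize_deterministic_and_structure_function():
    X1 = featurize(["CCO", "CCO", "CCN"], "maccs")
    X2 = featurize(["CCO", "CCO", "CCN"], "maccs")
    assert np.array_equal(X1.to_numpy(), X2.to_numpy())
    assert np.array_equal(X1.iloc[0].to_numpy(), X1.iloc[1].to_numpy())
    assert not np.array_equal(X1.iloc[0].to_numpy(), X1.iloc[2].to_numpy())
    assert X1.shape[1] == 166


def test_featurize_matches_independent_maccs():
    smiles = [f"{'C' * i}O" for i in range(1, 51)]
    X = featurize(smiles, "maccs")
    for i, smi in enumerate(smiles):
        direct = np.array(MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(smi)))[1:]
        assert np.array_equal(X.iloc[i].to_numpy(), direct)


def test_featurize_drops_failed_rows():
    X = featurize(["CCO", "CCCC"], "open2d")
    assert X.shape[0] == 2
    assert X.shape[1] > 20
    assert np.all(np.isfinite(X.to_numpy()))


# ---------------------------------------------------------------------------
# feature selection


def test_select_features_three_stages():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(100, 17))
    X = pd.DataFrame(base, columns=[f"f{i}" for i in range(17)])
    X["const"] = 1.0  # stage 1 victim
    # three near-duplicates of existing columns: stage 2 victims
    for i in range(3):
        X[f"dup{i}"] = X[f"f{i}"] * 1.0 + rng.normal(scale=1e-4, size=100)
    X = X[[*X.columns]]
    cols = select_features(X, variance_floor=1e-8, corr_ceiling=0.95)
    assert "const" not in cols
    assert len(cols) == 17
    assert not any(c.startswith("dup") for c in cols)


def test_select_features_duplicated_column_one_survivor():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4], "c": [4.0, 1, 3, 2]})
    cols = select_features(X, corr_ceiling=0.95)
    assert cols == ["a", "c"]


def test_select_features_all_removed_raises():
    X = pd.DataFrame({"a": [1.0, 1, 1], "b": [2.0, 2, 2]})
    with pytest.raises(ValueError, match="loosen"):
        select_features(X)


def test_select_features_rfe_reduces_to_target():
    rng = np.random.default_rng(1)
    X = pd.DataFrame(rng.normal(size=(80, 10)), columns=[f"f{i}" for i in range(10)])
    y = X["f0"].to_numpy() * 2 + rng.normal(scale=0.01, size=80)
    cols = select_features(X, rfe_target=3, y=y)
    assert len(cols) == 3
    assert "f0" in cols


# ---------------------------------------------------------------------------
# splitting


def test_scaffold_split_equal_groups_exact():
    scaffolds = [f"c1ccc(cc1){'C' * i}c1ccncc1" for i in range(1, 11)]
    records = []
    for s_i, scaffold in enumerate(scaffolds):
        for j in range(10):
            records.append(_rec(f"m{s_i}_{j}", f"{'N' if j % 2 else 'O'}{scaffold}"))
    # every derivative keeps its parent scaffold: 10 groups of 10
    train, val, test = scaffold_split(records, (0.8, 0.1, 0.1), seed=3)
    assert (len(train), len(val), len(test)) == (80, 10, 10)


def test_scaffold_split_no_leakage_and_deterministic():
    records, _ = generate_library(extended_spec(noise_sd=0.0, seed=2))
    from mmpaq.molprep import compute_scaffold

    train, val, test = scaffold_split(records, seed=5)
    again = scaffold_split(records, seed=5)
    assert [r.id for r in train] == [r.id for r in again[0]]
    sets = [
        {compute_scaffold(r) for r in part} for part in (train, val, test)
    ]
    assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])


def test_scaffold_split_too_few_scaffolds():
    with pytest.raises(ValueError, match="scaffold"):
        scaffold_split([_rec("a", "c1ccccc1C"), _rec("b", "c1ccccc1CC")])


# ---------------------------------------------------------------------------
# tuning


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(120, 5))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    return X[:80], y[:80], X[80:], y[80:]


def test_tune_grid_of_one(linear_data):
    Xtr, ytr, Xva, yva = linear_data
    est, params, table = tune_and_fit(
        "rf", Xtr, ytr, Xva, yva, grid={"n_estimators": [30]}, seed=0
    )
    assert params == {"n_estimators": 30}
    assert len(table) == 1


def test_tune_selects_best_validation_rmse(linear_data):
    Xtr, ytr, Xva, yva = linear_data
    grid = {"C": [0.01, 1.0, 100.0]}
    est, params, table = tune_and_fit("svm", Xtr, ytr, Xva, yva, grid=grid, seed=0)
    best = max(t["score"] for t in table)
    chosen = next(t for t in table if t["params"] == params)
    assert chosen["score"] == best


def test_tune_degenerate_labels_raise():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError, match="single class"):
        tune_and_fit("rf", X, np.ones(10), X, np.ones(10),
                     grid={"n_estimators": [5]}, task="classification")


# ---------------------------------------------------------------------------
# metrics


def test_classification_metrics_hand_case():
    y_true = np.array([1] * 50 + [0] * 50)
    y_pred = np.array([1] * 50 + [1] * 10 + [0] * 40)
    m = evaluate(y_true, y_pred, "classification")
    assert (m.TP, m.TN, m.FP, m.FN) == (50, 40, 10, 0)
    assert m.ACC == pytest.approx(0.9)
    assert m.SE == pytest.approx(1.0)
    assert m.SP == pytest.approx(0.8)
    assert m.precision == pytest.approx(0.8333, abs=1e-4)
    assert m.F1 == pytest.approx(0.9091, abs=1e-4)


def test_perfect_classifier_metrics():
    y = np.array([0, 1, 1, 0, 1])
    m = evaluate(y, y, "classification")
    assert m.ACC == m.SE == m.SP == m.precision == m.recall == m.F1 == 1.0


def test_empty_class_metric_is_sentinel_not_nan():
    m = evaluate(np.zeros(5, dtype=int), np.zeros(5, dtype=int), "classification")
    assert m.SE is None and m.precision is None
    assert m.SP == 1.0


def test_constant_prediction_q2_zero():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    m = evaluate(y, np.full_like(y, y.mean()), "regression")
    assert m.Q2_or_R2 == pytest.approx(0.0)
    assert m.RMSE**2 == pytest.approx(np.mean((y - y.mean()) ** 2))


def test_metrics_match_confusion_recomputation():
    rng = np.random.default_rng(0)
    y_true = rng.integers(0, 2, 200)
    y_pred = rng.integers(0, 2, 200)
    m = evaluate(y_true, y_pred, "classification")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    assert m.ACC == pytest.approx((tp + tn) / 200)
    assert m.SE == pytest.approx(tp / (tp + fn))
    assert m.SP == pytest.approx(tn / (tn + fp))


# ---------------------------------------------------------------------------
# consensus model


@pytest.fixture(scope="module")
def small_consensus():
    records, _ = generate_library(extended_spec(noise_sd=0.0, seed=9))
    train, val, test = scaffold_split(records, seed=1)
    model = ConsensusModel(
        task="regression",
        grid={a: {"n_estimators": [50]} if a != "svm" else {"C": [10.0]}
              for a in ("rf", "gb", "svm", "xgboost")},
        seed=1,
    )
    model.fit(
        [r.smiles_canonical for r in train],
        [r.property for r in train],
        X_val=[r.smiles_canonical for r in val],
        y_val=[r.property for r in val],
    )
    return model, test


def test_consensus_has_eight_single_models(small_consensus):
    model, _ = small_consensus
    assert model.n_models_ == 8
    assert len({spec for spec in model.model_specs_}) == 8


def test_consensus_is_mean_of_singles(small_consensus):
    model, test = small_consensus
    smiles = [r.smiles_canonical for r in test]
    singles = model.predict_singles(smiles)
    consensus = model.predict(smiles)
    assert np.max(np.abs(consensus - singles.mean(axis=1))) < 1e-9


def test_consensus_q2_on_planted_linear_fixture(small_consensus):
    model, test = small_consensus
    y = np.array([r.property for r in test])
    pred = model.predict([r.smiles_canonical for r in test])
    m = evaluate(y, pred, "regression")
    assert m.Q2_or_R2 >= 0.9


def test_consensus_sklearn_clonable():
    from sklearn.base import clone

    model = ConsensusModel(task="regression", seed=7)
    cloned = clone(model)
    assert cloned.get_params()["seed"] == 7


def test_cross_validate_scaffold_folds():
    records, _ = generate_library(
        extended_spec(noise_sd=0.1, seed=4, n_molecules=150)
    )
    model = ConsensusModel(
        task="regression",
        algorithms=("rf",),
        descriptor_sets=("open2d",),
        grid={"rf": {"n_estimators": [50]}},
        seed=0,
    )
    out = cross_validate(model, records, k=5, repeats=2, seed=0)
    assert out["mean"]["Q2_or_R2"] > 0.7
    assert len(out["per_repeat"]) == 2
    assert np.all(np.isfinite(out["oof_predictions"]))
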