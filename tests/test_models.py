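"""Splitting, balanced batching, model training and SHAP summaries."""

import numpy as np
import pytest

import nucleoff as nf
from nucleoff.models import (
    CA_FLOOR,
    ModelError,
    TrainedModel,
    balanced_batches,
    build_feature_matrix,
    evaluate,
    shap_summarize,
    stratified_split,
    train_model,
)
from nucleoff.records import COMPUTED_FEATURES, TARGET_LEN
from nucleoff.shapley import permutation_shap


@pytest.fixture(scope="module")
def feature_matrices(scored_dataset):
    ds, truth = scored_dataset
    train_ds, test_ds = stratified_split(ds, nf.SplitSpec(seed=5))
    return build_feature_matrix(train_ds), build_feature_matrix(test_ds), truth


@pytest.fixture(scope="module")
def gbt_model(feature_matrices):
    train_fm, _, _ = feature_matrices
    return train_model(train_fm, nf.ModelConfig.reduced("gbt", seed=5))


def test_split_preserves_class_ratio_and_is_disjoint(scored_dataset):
    ds, _ = scored_dataset
    train, test = stratified_split(ds, nf.SplitSpec(seed=1))
    n_put = sum(r.is_putative for r in ds.records)
    tr_put = sum(r.is_putative for r in train.records)
    assert abs(tr_put - round(0.8 * n_put)) <= 1
    assert abs(len(train) - round(0.8 * len(ds))) <= 1
    assert not {r.record_id for r in train.records} & {r.record_id for r in test.records}
    train2, _ = stratified_split(ds, nf.SplitSpec(seed=1))
    assert [r.record_id for r in train.records] == [r.record_id for r in train2.records]


def test_split_requires_minimum_stratum_size(scored_dataset):
    ds, _ = scored_dataset
    few = nf.Dataset(records=[r for r in ds.records if not r.is_putative][:20]
                     + [r for r in ds.records if r.is_putative][:3])
    with pytest.raises(ModelError, match="stratum"):
        stratified_split(few, nf.SplitSpec(seed=0))


def test_balanced_batches_class_counts():
    y = np.array([-4.0] * 30 + [1.0] * 10)
    batches = balanced_batches(y, batch_size=101, n_epochs=3, seed=0)
    assert len(batches) == 3
    for idx in batches:
        assert len(idx) == 101
        n_active = int((y[idx] > CA_FLOOR).sum())
        assert abs(n_active - (101 - n_active)) <= 1
    again = balanced_batches(y, batch_size=101, n_epochs=3, seed=0)
    assert all(np.array_equal(a, b) for a, b in zip(batches, again))
    with pytest.raises(ModelError):
        balanced_batches(np.array([-4.0, -4.0]), 10, 1, 0)


def test_feature_matrix_layout(feature_matrices):
    train_fm, _, _ = feature_matrices
    assert train_fm.X.shape[1] == 13 * TARGET_LEN + 3 + 6 + 13
    # groups partition the columns
    all_cols = np.concatenate(list(train_fm.groups.values()))
    assert sorted(all_cols) == list(range(train_fm.X.shape[1]))
    assert len(train_fm.groups) == 22
    # presence masks are 1 for the fully annotated dataset
    assert np.all(train_fm.X[:, -13:] == 1.0)


def test_gbt_learns_planted_signal(feature_matrices, gbt_model):
    _, test_fm, _ = feature_matrices
    rs, rp = evaluate(gbt_model, test_fm)
    assert rs > 0.3
    assert rp > 0.3


def test_gbt_training_is_reproducible(feature_matrices):
    train_fm, test_fm, _ = feature_matrices
    cfg = nf.ModelConfig.reduced("gbt", seed=9)
    cfg.gbt.epochs = 10
    m1 = train_model(train_fm, cfg)
    m2 = train_model(train_fm, cfg)
    assert np.allclose(m1.predict(test_fm.X), m2.predict(test_fm.X))


def test_near_constant_response_gives_near_constant_predictions(feature_matrices):
    """A degenerate fit: labels equal up to 1e-9 (the activity classes must
    remain distinguishable for batching) yields flat predictions."""
    train_fm, _, _ = feature_matrices
    const = train_fm.subset(np.arange(len(train_fm.y)))
    const.y = np.where(const.is_putative, -4.0, -4.0 + 1e-9)
    cfg = nf.ModelConfig.reduced("gbt", seed=0)
    cfg.gbt.epochs = 5
    model = train_model(const, cfg)
    pred = model.predict(const.X)
    assert pred.max() - pred.min() < 1e-6


def test_evaluate_perfect_and_inverted_predictions(feature_matrices):
    _, test_fm, _ = feature_matrices

    class Oracle:
        def __init__(self, sign):
            self.sign = sign

        def predict(self, X):
            return self.sign * test_fm.y

    rs, rp = evaluate(Oracle(+1), test_fm)  # type: ignore[arg-type]
    assert (rs, rp) == (pytest.approx(1.0), pytest.approx(1.0))
    rs, rp = evaluate(Oracle(-1), test_fm)  # type: ignore[arg-type]
    assert (rs, rp) == (pytest.approx(-1.0), pytest.approx(-1.0))


def test_gbt_shap_additivity_and_summation_rule(feature_matrices, gbt_model):
    _, test_fm, _ = feature_matrices
    summary = shap_summarize(gbt_model, test_fm, sample_size=100, seed=3)
    total = summary.base_values + sum(
        summary.shap_values[f] for f in summary.feature_names
    )
    assert np.allclose(total, summary.predictions, rtol=1e-3, atol=1e-3)
    # the per-feature value of a computed score is the sum of its 23
    # positional contributions (plus its presence column)
    import xgboost as xgb

    rng = np.random.default_rng(3)
    idx = rng.choice(len(test_fm.y), size=100, replace=False)
    contribs = gbt_model.booster.predict(
        xgb.DMatrix(test_fm.X[idx], feature_names=test_fm.columns), pred_contribs=True
    )
    cols = test_fm.groups["Nucleotide BDM"]
    assert np.allclose(
        summary.shap_values["Nucleotide BDM"], contribs[:, cols].sum(axis=1)
    )


def test_shap_sample_size_validated(feature_matrices, gbt_model):
    _, test_fm, _ = feature_matrices
    with pytest.raises(ModelError, match="sample_size"):
        shap_summarize(gbt_model, test_fm, sample_size=len(test_fm.y) + 1)


def test_constant_column_has_zero_importance(feature_matrices, gbt_model):
    """Experimental noise features never split on a constant column; a
    feature identical for every row gets importance 0."""
    _, test_fm, _ = feature_matrices
    fm = test_fm.subset(np.arange(len(test_fm.y)))
    fm.X = fm.X.copy()
    cols = fm.groups["RRBS"]
    fm.X[:, cols] = 0.5
    cfg = nf.ModelConfig.reduced("gbt", seed=1)
    cfg.gbt.epochs = 10
    model = train_model(fm, cfg)
    summary = shap_summarize(model, fm, sample_size=50, seed=1)
    assert summary.importance["RRBS"] == pytest.approx(0.0, abs=1e-12)


def test_planted_informative_feature_ranks_first():
    """With one informative computed channel and all else noise, that
    channel tops the SHAP ranking."""
    rng = np.random.default_rng(0)
    ds_n = 2000
    d_bp = 13 * TARGET_LEN
    X = rng.normal(size=(ds_n, d_bp + 3 + 6 + 13))
    X[:, -13:] = 1.0
    y = np.where(rng.uniform(size=ds_n) < 0.5, -4.0, 0.0)
    active = y > -4.0
    signal = rng.normal(size=ds_n)
    y[active] = np.clip(2 * signal[active], -3.9, 4.0)
    k = [f.name for f in COMPUTED_FEATURES].index("GC147")
    X[:, k * TARGET_LEN : (k + 1) * TARGET_LEN] = signal[:, None] + 0.1 * rng.normal(
        size=(ds_n, TARGET_LEN)
    )
    fm = nf.FeatureMatrix(
        X=X, y=y,
        columns=[f"c{i}" for i in range(X.shape[1])],
        groups={
            **{
                f.name: np.concatenate(
                    [np.arange(i * TARGET_LEN, (i + 1) * TARGET_LEN), [d_bp + 9 + i]]
                )
                for i, f in enumerate(COMPUTED_FEATURES)
            },
            **{name: np.array([d_bp + j]) for j, name in enumerate(nf.records.ENERGY_FEATURES)},
            **{
                f.name: np.array([d_bp + 3 + j])
                for j, f in enumerate(nf.records.EXPERIMENTAL_FEATURES)
            },
        },
        record_ids=[str(i) for i in range(ds_n)],
        is_putative=~active,
    )
    cfg = nf.ModelConfig.reduced("gbt", seed=0)
    cfg.gbt.epochs = 30
    model = train_model(fm, cfg)
    summary = shap_summarize(model, fm, sample_size=500, seed=0)
    assert summary.ranking[0] == "GC147"


# --- permutation Shapley explainer -------------------------------------------


def test_permutation_shap_exact_on_linear_model(rng):
    """For a linear model with a fixed background, sampled Shapley values
    equal w_g . (x_g - b_g) exactly, for any number of permutations."""
    d = 12
    w = rng.normal(size=d)
    X = rng.normal(size=(20, d))
    background = rng.normal(size=(1, d))
    groups = [np.array([0, 1, 2]), np.array([3, 4]), np.arange(5, 12)]
    phi, base = permutation_shap(lambda Z: Z @ w, X, background, groups, n_permutations=2, seed=0)
    for g, cols in enumerate(groups):
        expected = (X[:, cols] - background[0, cols]) @ w[cols]
        assert np.allclose(phi[:, g], expected, atol=1e-10)
    assert np.allclose(base, background @ w)


def test_permutation_shap_additivity_nonlinear(rng):
    def f(Z):
        return np.sin(Z[:, 0]) * Z[:, 1] + Z[:, 2] ** 2

    X = rng.normal(size=(30, 3))
    bg = rng.normal(size=(8, 3))
    groups = [np.array([0]), np.array([1]), np.array([2])]
    phi, base = permutation_shap(f, X, bg, groups, n_permutations=5, seed=1)
    assert np.allclose(base + phi.sum(axis=1), f(X), atol=1e-10)


def test_permutation_shap_requires_partition(rng):
    with pytest.raises(ValueError):
        permutation_shap(
            lambda Z: Z.sum(1), rng.normal(size=(3, 4)), rng.normal(size=(2, 4)),
            [np.array([0, 1]), np.array([1, 2, 3])],
        )


# --- CNN ---------------------------------------------------------------------


@pytest.fixture(scope="module")
def cnn_model(feature_matrices):
    train_fm, _, _ = feature_matrices
    cfg = nf.ModelConfig.reduced("cnn", seed=2)
    cfg.cnn.epochs = 15
    cfg.cnn.batch_size = 1000
    return train_model(train_fm, cfg)


def test_cnn_learns_planted_signal(feature_matrices, cnn_model):
    _, test_fm, _ = feature_matrices
    rs, _ = evaluate(cnn_model, test_fm)
    assert rs > 0.15


def test_cnn_shap_additivity(feature_matrices, cnn_model):
    _, test_fm, _ = feature_matrices
    summary = shap_summarize(
        cnn_model, test_fm, sample_size=40, seed=0, n_permutations=3, background_size=10
    )
    total = summary.base_values + sum(
        summary.shap_values[f] for f in summary.feature_names
    )
    rel = np.abs(total - summary.predictions) / (np.abs(summary.predictions) + 1e-9)
    assert np.all(rel < 1e-3)
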