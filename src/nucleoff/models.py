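"""Activity-prediction models and SHAP feature-importance summaries.

Two regressors predict normalized cleavage activity from the three
binding-energy features, the six per-site experimental epigenetic
scalars and the 13 computed nucleosome-organization scores at base-pair
resolution (13 channels x 23 positions); gRNA/target sequence identity
is deliberately excluded so that feature importance reflects the
epigenetic descriptors alone.

* ``gbt`` — an XGBoost tree model (eta=0.5, colsample_bytree=0.7,
  max_depth=7) trained for 70 epochs, each on a freshly bootstrapped
  class-balanced batch; SHAP values come from the exact TreeSHAP
  algorithm built into XGBoost (``pred_contribs``).
* ``cnn`` — a small numpy convolutional network over the base-pair
  block merged with the scalar block (see ``nn``); SHAP values come
  from the in-package permutation-sampling Shapley explainer.

Per-feature SHAP contributions of a computed score are the sum of its
23 base-pair-resolved contributions; features are ranked by mean
absolute summed SHAP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .nn import CnnHyperparams, ConvRegressor
from .records import (
    COMPUTED_FEATURES,
    ENERGY_FEATURES,
    EXPERIMENTAL_FEATURES,
    FEATURE_BY_NAME,
    TARGET_LEN,
    Dataset,
)
from .shapley import permutation_shap

logger = logging.getLogger(__name__)

CA_FLOOR = -4.0


class ModelError(ValueError):
    pass


@dataclass
class GbtHyperparams:
    eta: float = 0.5
    colsample_bytree: float = 0.7
    max_depth: int = 7
    epochs: int = 70
    batch_size: int = 50_000


@dataclass
class ModelConfig:
    model_kind: str = "gbt"  # "gbt" | "cnn"
    gbt: GbtHyperparams = field(default_factory=GbtHyperparams)
    cnn: CnnHyperparams = field(default_factory=CnnHyperparams)
    seed: int = 0

    @classmethod
    def reduced(cls, model_kind: str = "gbt", seed: int = 0) -> "ModelConfig":
        """Desk-scale constants: smaller batches, same learning dynamics."""
        cfg = cls(model_kind=model_kind, seed=seed)
        cfg.gbt.batch_size = 5_000
        cfg.cnn.batch_size = 2_000
        cfg.cnn.epochs = 40
        return cfg


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ModelError("train_fraction must lie in (0, 1)")


# --- feature matrix ----------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Model inputs with a fixed, ordered column manifest.

    Layout: 13 computed scores x 23 positions (channel-major), then the
    3 energy features, 6 experimental scalars and 13 per-score presence
    masks.  Absent adapter-backed scores are imputed as all-zero
    channels with presence 0.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    groups: dict[str, np.ndarray]
    record_ids: list[str]
    is_putative: np.ndarray
    n_channels: int = len(COMPUTED_FEATURES)
    length: int = TARGET_LEN

    @property
    def n_scalars(self) -> int:
        return self.X.shape[1] - self.n_channels * self.length

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[idx],
            y=self.y[idx],
            columns=self.columns,
            groups=self.groups,
            record_ids=[self.record_ids[i] for i in idx],
            is_putative=self.is_putative[idx],
        )


def build_feature_matrix(ds: Dataset) -> FeatureMatrix:
    """Assemble the model matrix from an annotated dataset."""
    n = len(ds.records)
    columns: list[str] = []
    for f in COMPUTED_FEATURES:
        columns += [f"bp_{f.slug}_{i:02d}" for i in range(TARGET_LEN)]
    columns += list(ENERGY_FEATURES)
    columns += [f"epi_{f.slug}" for f in EXPERIMENTAL_FEATURES]
    columns += [f"has_{f.slug}" for f in COMPUTED_FEATURES]
    d = len(columns)
    X = np.zeros((n, d))
    y = np.zeros(n)
    is_put = np.zeros(n, dtype=bool)
    bp_dim = len(COMPUTED_FEATURES) * TARGET_LEN
    for i, rec in enumerate(ds.records):
        y[i] = rec.cleavage_activity
        is_put[i] = rec.is_putative
        for k, f in enumerate(COMPUTED_FEATURES):
            if rec.basepair_scores is not None and f.name in rec.basepair_scores.scores:
                X[i, k * TARGET_LEN : (k + 1) * TARGET_LEN] = rec.basepair_scores.scores[f.name]
                X[i, bp_dim + 9 + k] = 1.0  # presence mask after energy+experimental
        if rec.energy is None or not all(
            np.isfinite([rec.energy.e_rna_dna, rec.energy.e_rna_dna_corr, rec.energy.e_grnafold])
        ):
            raise ModelError(f"{rec.record_id}: missing or non-finite energy features")
        X[i, bp_dim + 0] = rec.energy.e_rna_dna
        X[i, bp_dim + 1] = rec.energy.e_rna_dna_corr
        X[i, bp_dim + 2] = rec.energy.e_grnafold
        for j, f in enumerate(EXPERIMENTAL_FEATURES):
            X[i, bp_dim + 3 + j] = rec.experimental_scores.get(f.name, 0.0)
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ModelError("non-finite values in the feature matrix")
    groups: dict[str, np.ndarray] = {}
    for k, f in enumerate(COMPUTED_FEATURES):
        cols = list(range(k * TARGET_LEN, (k + 1) * TARGET_LEN))
        cols.append(bp_dim + 9 + k)  # presence mask travels with its score
        groups[f.name] = np.array(cols)
    for j, name in enumerate(ENERGY_FEATURES):
        groups[name] = np.array([bp_dim + j])
    for j, f in enumerate(EXPERIMENTAL_FEATURES):
        groups[f.name] = np.array([bp_dim + 3 + j])
    return FeatureMatrix(
        X=X,
        y=y,
        columns=columns,
        groups=groups,
        record_ids=[r.record_id for r in ds.records],
        is_putative=is_put,
    )


# --- splitting and batching --------------------------------------------------


def stratified_split(ds: Dataset, spec: SplitSpec) -> tuple[Dataset, Dataset]:
    """80/20 split preserving the putative:experimental ratio (+-1)."""
    rng = np.random.default_rng(spec.seed)
    idx_put = [i for i, r in enumerate(ds.records) if r.is_putative]
    idx_act = [i for i, r in enumerate(ds.records) if not r.is_putative]
    for name, idx in (("putative", idx_put), ("experimental", idx_act)):
        if len(idx) < 5:
            raise ModelError(f"stratum {name!r} has {len(idx)} records (<5)")
    train_idx: list[int] = []
    test_idx: list[int] = []
    for idx in (idx_put, idx_act):
        perm = rng.permutation(len(idx))
        n_train = int(round(spec.train_fraction * len(idx)))
        train_idx += [idx[p] for p in perm[:n_train]]
        test_idx += [idx[p] for p in perm[n_train:]]
    train = Dataset(
        records=[ds.records[i] for i in sorted(train_idx)],
        feature_manifest=list(ds.feature_manifest),
    )
    test = Dataset(
        records=[ds.records[i] for i in sorted(test_idx)],
        feature_manifest=list(ds.feature_manifest),
    )
    return train, test


def balanced_batches(
    y: np.ndarray, batch_size: int, n_epochs: int, seed: int
) -> list[np.ndarray]:
    """Bootstrapped class-balanced batch indices, one batch per epoch.

    Each batch holds ``batch_size`` rows sampled with replacement, half
    active (CA > -4) and half inactive/putative (CA = -4); for odd
    batch sizes the class counts differ by one.
    """
    rng = np.random.default_rng(seed)
    active = np.flatnonzero(y > CA_FLOOR)
    inactive = np.flatnonzero(y <= CA_FLOOR)
    if active.size == 0 or inactive.size == 0:
        raise ModelError("both activity classes must be present for balancing")
    n_act = batch_size // 2
    n_inact = batch_size - n_act
    batches = []
    for _ in range(n_epochs):
        a = rng.choice(active, size=n_act, replace=True)
        b = rng.choice(inactive, size=n_inact, replace=True)
        batches.append(np.concatenate([a, b]))
    return batches


# --- training / evaluation ----------------------------------------------------


@dataclass
class TrainedModel:
    kind: str
    booster: xgb.Booster | None
    net: ConvRegressor | None
    columns: list[str]
    groups: dict[str, np.ndarray]
    config: ModelConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "gbt":
            return self.booster.predict(xgb.DMatrix(X, feature_names=self.columns))
        return self.net.predict(X)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        if self.kind == "gbt":
            self.booster.save_model(str(path))
        else:
            np.savez(path, **self.net.get_state())
        return path


def train_model(train_fm: FeatureMatrix, cfg: ModelConfig) -> TrainedModel:
    """Train the configured model on class-balanced bootstrap batches."""
    if not np.isfinite(train_fm.X).all():
        raise ModelError("non-finite features")
    if cfg.model_kind == "gbt":
        params = {
            "eta": cfg.gbt.eta,
            "colsample_bytree": cfg.gbt.colsample_bytree,
            "max_depth": cfg.gbt.max_depth,
            "objective": "reg:squarederror",
            "seed": cfg.seed,
            "nthread": 1,
            "verbosity": 0,
        }
        batches = balanced_batches(
            train_fm.y, cfg.gbt.batch_size, cfg.gbt.epochs, cfg.seed
        )
        booster: xgb.Booster | None = None
        for idx in batches:
            dmat = xgb.DMatrix(
                train_fm.X[idx], label=train_fm.y[idx], feature_names=train_fm.columns
            )
            booster = xgb.train(params, dmat, num_boost_round=1, xgb_model=booster)
        return TrainedModel("gbt", booster, None, train_fm.columns, train_fm.groups, cfg)
    if cfg.model_kind == "cnn":
        rng = np.random.default_rng(cfg.seed)
        n = len(train_fm.y)
        perm = rng.permutation(n)
        n_val = max(1, int(cfg.cnn.val_fraction * n))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        net = ConvRegressor(
            n_channels=train_fm.n_channels,
            length=train_fm.length,
            n_scalars=train_fm.n_scalars,
            hp=cfg.cnn,
            seed=cfg.seed,
        )
        batch_idx = balanced_batches(
            train_fm.y[fit_idx], cfg.cnn.batch_size, cfg.cnn.epochs, cfg.seed + 1
        )
        batches = (
            (train_fm.X[fit_idx][idx], train_fm.y[fit_idx][idx]) for idx in batch_idx
        )
        net.fit(batches, X_val=train_fm.X[val_idx], y_val=train_fm.y[val_idx])
        return TrainedModel("cnn", None, net, train_fm.columns, train_fm.groups, cfg)
    raise ModelError(f"unknown model kind {cfg.model_kind!r}")


def evaluate(model: TrainedModel, test_fm: FeatureMatrix) -> tuple[float, float]:
    """(Spearman, Pearson) correlation of predictions vs CA on held-out data.

    Spearman is flagged undefined (NaN) when predictions are constant.
    """
    if len(test_fm.y) == 0:
        raise ModelError("empty test set")
    pred = model.predict(test_fm.X)
    if np.all(pred == pred[0]):
        logger.warning("constant predictions; correlations undefined")
        return float("nan"), float("nan")
    rs = float(stats.spearmanr(pred, test_fm.y).statistic)
    rp = float(stats.pearsonr(pred, test_fm.y).statistic)
    return rs, rp


# --- SHAP summaries -----------------------------------------------------------


@dataclass
class ShapSummary:
    feature_names: list[str]
    shap_values: dict[str, np.ndarray]  # feature -> per-datapoint summed SHAP
    base_values: np.ndarray
    predictions: np.ndarray
    importance: dict[str, float]
    ranking: list[str]
    evaluation: tuple[float, float]

    def rank_of(self, feature: str) -> int:
        return self.ranking.index(feature) + 1

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [
            {"feature": f, "mean_abs_shap": self.importance[f], "rank": i + 1}
            for i, f in enumerate(self.ranking)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    def attribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f: self.shap_values[f] for f in self.feature_names})


def shap_summarize(
    model: TrainedModel,
    test_fm: FeatureMatrix,
    sample_size: int = 2_000,
    seed: int = 0,
    n_permutations: int = 8,
    background_size: int = 100,
) -> ShapSummary:
    """Per-feature SHAP attribution distributions on a test sample.

    For each computed score the 23 positional attributions (plus its
    presence mask) are summed into a single per-datapoint value;
    features are ranked by mean absolute summed SHAP, descending.
    """
    n = len(test_fm.y)
    if sample_size > n:
        raise ModelError(f"sample_size {sample_size} exceeds test size {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=sample_size, replace=False)
    Xs = test_fm.X[idx]
    feature_names = list(test_fm.groups)
    if model.kind == "gbt":
        dmat = xgb.DMatrix(Xs, feature_names=test_fm.columns)
        contribs = model.booster.predict(dmat, pred_contribs=True)
        phi_cols, base = contribs[:, :-1], contribs[:, -1]
        shap_values = {
            name: phi_cols[:, cols].sum(axis=1)
            for name, cols in test_fm.groups.items()
        }
    else:
        background = test_fm.X[rng.choice(n, size=min(background_size, n), replace=False)]
        groups = [test_fm.groups[name] for name in feature_names]
        phi, base = permutation_shap(
            model.predict, Xs, background, groups,
            n_permutations=n_permutations, seed=seed,
        )
        shap_values = {name: phi[:, g] for g, name in enumerate(feature_names)}
    predictions = model.predict(Xs)
    importance = {
        name: float(np.mean(np.abs(v))) for name, v in shap_values.items()
    }
    ranking = sorted(feature_names, key=lambda f: -importance[f])
    return ShapSummary(
        feature_names=feature_names,
        shap_values=shap_values,
        base_values=np.asarray(base, dtype=float),
        predictions=predictions,
        importance=importance,
        ranking=ranking,
        evaluation=evaluate(model, test_fm),
    )
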