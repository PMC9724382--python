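"""Feature-activity association analysis.

Base-pair-resolved computed scores are first aggregated to one value
per site (mean across the 23 target base pairs, median for binary
scores), then Spearman and Pearson correlations with normalized
cleavage activity are tabulated per stratum: each cell line, gene-body
vs non-gene-body sites, and all data pooled.  Putative records
(CA = -4) are included by default, as in the augmented corpus; a flag
excludes them for sensitivity analysis.  Distribution summaries split
sites into the lowest (CA = -4), low (-4 < CA <= 2) and high (CA > 2)
activity bins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import ACTIVITY_BINS, bin_activity
from .records import (
    FEATURE_BY_NAME,
    TARGET_LEN,
    Dataset,
    SchemaError,
)

logger = logging.getLogger(__name__)

STRATUM_ALL = "all"
STRATUM_GENE_BODY = "gene body"
STRATUM_NON_GENE_BODY = "non-gene body"


class AssociationError(ValueError):
    pass


def aggregate_basepair(vec, is_binary: bool) -> float:
    """Aggregate a 23-vector to one per-site value.

    Mean for continuous scores, median (average-of-middle order
    statistics) for binary ones.
    """
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (TARGET_LEN,):
        raise AssociationError(f"expected a {TARGET_LEN}-vector, got shape {vec.shape}")
    return float(np.median(vec)) if is_binary else float(np.mean(vec))


def feature_values(
    ds: Dataset, feature: str, extra_features: dict[str, dict[str, float]] | None = None
) -> np.ndarray:
    """Per-record aggregated values for one feature (NaN where absent).

    ``extra_features`` may supply additional per-record columns (name ->
    record_id -> value), e.g. a planted synthetic covariate.
    """
    if extra_features and feature in extra_features:
        col = extra_features[feature]
        return np.array([col.get(rec.record_id, np.nan) for rec in ds.records])
    if feature not in FEATURE_BY_NAME:
        raise SchemaError(f"unknown feature {feature!r}")
    f = FEATURE_BY_NAME[feature]
    out = np.full(len(ds.records), np.nan)
    for i, rec in enumerate(ds.records):
        if f.kind == "experimental":
            if feature in rec.experimental_scores:
                out[i] = rec.experimental_scores[feature]
        elif rec.basepair_scores is not None and feature in rec.basepair_scores.scores:
            out[i] = aggregate_basepair(rec.basepair_scores.scores[feature], f.is_binary)
    return out


def _correlations(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """(spearman, pearson) with average-rank ties; None when undefined."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size <= 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rs = float(stats.spearmanr(x, y).statistic)
    rp = float(stats.pearsonr(x, y).statistic)
    return rs, rp


@dataclass
class CorrelationCell:
    spearman: float
    pearson: float
    n: int


@dataclass
class CorrelationTable:
    strata: list[str]
    features: list[str]
    cells: dict[tuple[str, str], CorrelationCell | None] = field(default_factory=dict)

    def frame(self, stat: str = "spearman") -> pd.DataFrame:
        data = {}
        for feat in self.features:
            data[feat] = [
                getattr(self.cells[(s, feat)], stat) if self.cells[(s, feat)] else np.nan
                for s in self.strata
            ]
        return pd.DataFrame(data, index=self.strata)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.strata:
            for feat in self.features:
                cell = self.cells[(s, feat)]
                rows.append(
                    {
                        "stratum": s,
                        "feature": feat,
                        "spearman": cell.spearman if cell else np.nan,
                        "pearson": cell.pearson if cell else np.nan,
                        "n": cell.n if cell else 0,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        obj = {
            s: {
                feat: (
                    None
                    if self.cells[(s, feat)] is None
                    else {
                        "spearman": self.cells[(s, feat)].spearman,
                        "pearson": self.cells[(s, feat)].pearson,
                        "n": self.cells[(s, feat)].n,
                    }
                )
                for feat in self.features
            }
            for s in self.strata
        }
        path.write_text(json.dumps(obj, indent=2))
        return path


def default_strata(ds: Dataset) -> dict[str, np.ndarray]:
    """Cell-line rows, gene-body / non-gene-body rows, and the pooled row."""
    cell_lines = sorted({rec.cell_line for rec in ds.records})
    gb = np.array([rec.in_gene_body for rec in ds.records])
    strata = {
        cl: np.array([rec.cell_line == cl for rec in ds.records]) for cl in cell_lines
    }
    strata[STRATUM_GENE_BODY] = gb
    strata[STRATUM_NON_GENE_BODY] = ~gb
    strata[STRATUM_ALL] = np.ones(len(ds.records), dtype=bool)
    return strata


def correlation_table(
    ds: Dataset,
    strata_spec: dict[str, np.ndarray] | None = None,
    features: list[str] | None = None,
    extra_features: dict[str, dict[str, float]] | None = None,
    include_putative: bool = True,
) -> CorrelationTable:
    """Spearman/Pearson correlations of every feature with CA, per stratum.

    Cells where the feature or CA is constant (or the stratum is empty)
    are flagged undefined (None), never reported as 0.
    """
    if features is None:
        features = list(ds.feature_manifest)
        if extra_features:
            features += [f for f in extra_features if f not in features]
    strata = strata_spec if strata_spec is not None else default_strata(ds)
    ca = np.array([rec.cleavage_activity for rec in ds.records])
    keep = np.ones(len(ds.records), dtype=bool)
    if not include_putative:
        keep = ~np.array([rec.is_putative for rec in ds.records])
    table = CorrelationTable(strata=list(strata), features=list(features))
    for feat in features:
        vals = feature_values(ds, feat, extra_features)
        for name, mask in strata.items():
            m = mask & keep & np.isfinite(vals) & np.isfinite(ca)
            res = _correlations(vals[m], ca[m]) if m.any() else None
            table.cells[(name, feat)] = (
                None if res is None else CorrelationCell(res[0], res[1], int(m.sum()))
            )
    return table


@dataclass
class DistributionSummary:
    feature: str
    values: dict[str, list[float]] = field(default_factory=dict)  # bin -> values
    stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {b: len(v) for b, v in self.values.items()}

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        rows = [
            dict(feature=self.feature, bin=b, **st) for b, st in self.stats.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path


def distribution_summary(
    ds: Dataset,
    feature: str,
    extra_features: dict[str, dict[str, float]] | None = None,
) -> DistributionSummary:
    """Per-activity-bin value lists and summary statistics for one feature."""
    vals = feature_values(ds, feature, extra_features)
    summary = DistributionSummary(feature=feature, values={b: [] for b in ACTIVITY_BINS})
    for rec, v in zip(ds.records, vals):
        summary.values[bin_activity(rec.cleavage_activity)].append(float(v))
    for b, vlist in summary.values.items():
        arr = np.array([v for v in vlist if np.isfinite(v)])
        if arr.size:
            q1, q2, q3 = np.percentile(arr, [25, 50, 75])
            summary.stats[b] = {
                "count": int(len(vlist)),
                "mean": float(arr.mean()),
                "q1": float(q1),
                "median": float(q2),
                "q3": float(q3),
            }
        else:
            summary.stats[b] = {
                "count": int(len(vlist)),
                "mean": np.nan, "q1": np.nan, "median": np.nan, "q3": np.nan,
            }
    return summary
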