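"""Experiment orchestration: feature-set comparisons, selection frequencies,
proteome scans.

Each runner returns a plain table plus a manifest (config hash, seed,
library versions) so any report can be tied back to the exact configuration
that produced it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy
import sklearn

from . import __version__
from .data_model import ProteinRecord, StructuralAnnotation
from .features import (
    DEFAULT_SELECTION_SETS,
    assemble_features,
    selection_pool,
    ttest_prefilter,
)
from .model_eval import (
    DEFAULT_C_GRID,
    TrainedModel,
    decision_scores,
    forward_feature_selection,
    nested_cv,
)
from .synthetic_data import EffectConfig, generate_proteins, labels_vector


@dataclass
class ExperimentConfig:
    """What to run: feature sets, CV layout, seed, and the data source.

    Data comes either from ``n_pos``/``n_neg``/``effect`` (simulated) or is
    passed directly to the runners.
    """

    feature_sets: tuple[str, ...] = ("f2",)
    folds: int = 10
    inner_folds: int = 10
    seed: int = 0
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_pos: int | None = None
    n_neg: int | None = None
    effect: EffectConfig | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def make_manifest(config: ExperimentConfig) -> dict:
    """Reproducibility metadata embedded in every report."""
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "secprod": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


def _resolve_dataset(
    config: ExperimentConfig,
    records: Sequence[ProteinRecord] | None,
    annotations: Mapping[str, StructuralAnnotation] | None,
):
    if records is not None and annotations is not None:
        return list(records), dict(annotations)
    if config.n_pos is None or config.n_neg is None:
        raise ValueError("provide records+annotations or n_pos/n_neg in the config")
    effect = config.effect or EffectConfig()
    return generate_proteins(config.n_pos, config.n_neg, effect, seed=config.seed)


def run_feature_set_comparison(
    config: ExperimentConfig,
    records: Sequence[ProteinRecord] | None = None,
    annotations: Mapping[str, StructuralAnnotation] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Nested-CV AUROC per requested feature set.

    Returns (table with feature_set / mean_auroc / fold_aurocs, manifest).
    Deterministic given the config seed.
    """
    records, annotations = _resolve_dataset(config, records, annotations)
    y = labels_vector(records)
    rows = []
    for set_name in config.feature_sets:
        X = assemble_features(records, annotations, set_name, seed=config.seed)
        result = nested_cv(
            X,
            y,
            outer_folds=config.folds,
            C_grid=config.C_grid,
            seed=config.seed,
            inner_folds=config.inner_folds,
        )
        rows.append(
            {
                "feature_set": set_name,
                "mean_auroc": result.mean_auroc,
                "fold_aurocs": tuple(result.fold_aurocs),
            }
        )
    return pd.DataFrame(rows), make_manifest(config)


def _correlation_groups(X: pd.DataFrame, threshold: float) -> dict[str, str]:
    """Map each feature to a group label (connected |r| >= threshold comps)."""
    cols = list(X.columns)
    if threshold >= 1.0:
        return {c: c for c in cols}
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.abs(np.corrcoef(X.values.T))
    corr = np.nan_to_num(corr, nan=0.0)
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            if corr[i, j] >= threshold:
                parent[find(cols[j])] = find(a)
    groups: dict[str, list[str]] = {}
    for c in cols:
        groups.setdefault(find(c), []).append(c)
    label = {root: "|".join(sorted(members)[:1]) for root, members in groups.items()}
    return {c: label[find(c)] for c in cols}


def run_selection_frequency(
    config: ExperimentConfig,
    records: Sequence[ProteinRecord] | None = None,
    annotations: Mapping[str, StructuralAnnotation] | None = None,
    pool_sets: Sequence[str] = DEFAULT_SELECTION_SETS,
    alpha: float = 0.05,
    C_fixed: float = 1.0,
    max_iterations: int = 3,
    corr_threshold: float = 0.7,
) -> tuple[pd.DataFrame, dict]:
    """How often each feature is picked in the first selection iterations.

    Per outer fold: univariate t-test prefilter on the training portion, then
    greedy forward selection (fixed C, inner CV); counts are aggregated over
    folds for iterations 1..max_iterations, with features grouped when their
    absolute correlation reaches ``corr_threshold`` (group labelled by its
    alphabetically first member).
    """
    from sklearn.model_selection import StratifiedKFold

    records, annotations = _resolve_dataset(config, records, annotations)
    y = labels_vector(records)
    pool = selection_pool(records, annotations, pool_sets, seed=config.seed)
    group_of = _correlation_groups(pool, corr_threshold)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    counts: dict[tuple[int, str], int] = {}
    for train_idx, _ in skf.split(pool.values, y):
        X_tr = pool.iloc[train_idx]
        y_tr = y[train_idx]
        kept = ttest_prefilter(X_tr, y_tr, alpha)["feature"].tolist()
        if not kept:
            continue
        sel = forward_feature_selection(
            X_tr,
            y_tr,
            kept,
            C_fixed=C_fixed,
            folds=config.inner_folds,
            seed=config.seed,
            max_steps=max_iterations,
        )
        for it, feat in enumerate(sel.selected[:max_iterations], start=1):
            key = (it, group_of[feat])
            counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(
        [
            {"iteration": it, "feature": feat, "count": n}
            for (it, feat), n in sorted(counts.items())
        ]
    )
    return table, make_manifest(config)


def run_proteome_scan(
    model: TrainedModel,
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, StructuralAnnotation],
    feature_set: str = "f2",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Score a protein collection with a trained model.

    Returns per-protein decision scores (with signal-peptide flags carried
    through) and a summary of the fraction scoring above zero;
    unfeaturizable records are skipped with a warning.
    """
    rows = []
    for rec in records:
        try:
            X = assemble_features([rec], annotations, feature_set, seed=seed)
            score = float(decision_scores(model, X)[0])
        except (ValueError, KeyError) as exc:
            warnings.warn(f"skipping {rec.id!r}: {exc}", stacklevel=2)
            continue
        ann = annotations.get(rec.id)
        rows.append(
            {
                "id": rec.id,
                "score": score,
                "sp_flag": bool(ann.sp_flag) if ann is not None else False,
                "label": rec.label,
            }
        )
    table = pd.DataFrame(rows, columns=["id", "score", "sp_flag", "label"])
    summary = {
        "n": len(table),
        "fraction_positive": float((table["score"] > 0).mean()) if len(table) else 0.0,
    }
    return table, summary
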