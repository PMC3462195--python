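"""Data-driven greedy amino-acid clustering.

The method groups the 20 amino acids into disjoint clusters whose summed
fractions (a reduced-alphabet composition) best separate the production
classes. It starts by selecting the single best-performing amino acid (as a
one-feature classifier), then repeatedly considers every remaining amino
acid either as a new singleton cluster or merged into each existing cluster,
committing the single best-scoring placement per iteration until no amino
acids remain. The output is the best-scoring intermediate state ever
observed, so amino acids placed late may be absent from the result.

Candidates are evaluated in alphabetical order with the new-cluster option
before merges, and the first maximum wins — the procedure is fully
deterministic given a deterministic evaluator. The default evaluator is the
mean AUROC of a seeded inner 10-fold cross-validation of a linear SVM at
fixed C on the cluster-composition features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AMINO_ACIDS
from .features import ClusterSet
from .model_eval import _cv_auroc

Evaluator = Callable[[ClusterSet], float]


@dataclass(frozen=True)
class ClusteringStep:
    """One committed placement: which amino acid went where, at what score."""

    amino_acid: str
    action: str  # "start", "new" or "merge:<index>"
    score: float
    state: ClusterSet


@dataclass
class ClusteringTrace:
    steps: tuple[ClusteringStep, ...]
    best_score: float
    best_clusters: ClusterSet


def _state(clusters: Sequence[frozenset]) -> ClusterSet:
    return ClusterSet(tuple(clusters))


def greedy_aa_clustering(
    evaluator: Evaluator,
    alphabet: Sequence[str] = AMINO_ACIDS,
) -> tuple[ClusterSet, ClusteringTrace]:
    """Run the greedy clustering; return (best clusters, full trace).

    ``evaluator`` maps any non-empty ClusterSet to a score (higher is
    better) and must be deterministic for reproducible traces.
    """
    remaining = sorted(alphabet)
    if not remaining:
        raise ValueError("alphabet must be non-empty")

    steps: list[ClusteringStep] = []
    clusters: list[frozenset] = []

    def evaluate(cands: list[tuple[str, str, list[frozenset]]]):
        """Pick the first maximum among (aa, action, state) candidates."""
        best = None
        for aa, action, cand in cands:
            try:
                score = evaluator(_state(cand))
            except Exception as exc:  # pragma: no cover - evaluator contract
                raise RuntimeError(
                    f"evaluator failed on state {[sorted(c) for c in cand]}"
                ) from exc
            if best is None or score > best[3]:
                best = (aa, action, cand, score)
        return best

    # iteration 0: best single amino acid
    aa, action, clusters, score = evaluate(
        [(a, "start", [frozenset({a})]) for a in remaining]
    )
    remaining.remove(aa)
    steps.append(ClusteringStep(aa, action, score, _state(clusters)))
    best_score, best_clusters = score, _state(clusters)

    while remaining:
        cands = []
        for a in remaining:
            cands.append((a, "new", clusters + [frozenset({a})]))
            for j, cl in enumerate(clusters):
                merged = list(clusters)
                merged[j] = cl | {a}
                cands.append((a, f"merge:{j}", merged))
        aa, action, clusters, score = evaluate(cands)
        remaining.remove(aa)
        steps.append(ClusteringStep(aa, action, score, _state(clusters)))
        if score > best_score:
            best_score, best_clusters = score, _state(clusters)

    trace = ClusteringTrace(tuple(steps), best_score, best_clusters)
    return best_clusters, trace


def make_cv_evaluator(
    composition: pd.DataFrame,
    y: Sequence[int],
    C: float = 1.0,
    folds: int = 10,
    seed: int = 0,
) -> Evaluator:
    """Default clustering evaluator: inner-CV AUROC on cluster compositions.

    ``composition`` is a per-protein amino-acid composition matrix whose
    columns are either bare letters or ``comp:<letter>`` names (as produced
    by the f2 feature set).
    """
    y = np.asarray(y)
    cols = {}
    for c in composition.columns:
        letter = c.split(":", 1)[1] if ":" in c else c
        cols[letter] = c

    def evaluator(clusters: ClusterSet) -> float:
        data = {
            f"cluster:{label}": sum(
                (composition[cols[a]] for a in sorted(cl)),
                start=pd.Series(0.0, index=composition.index),
            )
            for label, cl in zip(clusters.labels(), clusters.clusters)
        }
        X = pd.DataFrame(data, index=composition.index)
        return _cv_auroc(X, y, C, folds, seed)

    return evaluator


def cluster_cooccurrence(
    clusterings: Sequence[ClusterSet],
    alphabet: Sequence[str] = AMINO_ACIDS,
) -> pd.DataFrame:
    """Aggregate clusterings into a symmetric co-occurrence count matrix.

    Off-diagonal (a, b): number of clusterings in which a and b share a
    cluster. Diagonal (a, a): number of clusterings in which a appears in any
    cluster.
    """
    if not clusterings:
        raise ValueError("need at least one clustering")
    letters = list(alphabet)
    mat = pd.DataFrame(0, index=letters, columns=letters, dtype=int)
    for cs in clusterings:
        for cl in cs.clusters:
            members = sorted(cl)
            for a in members:
                mat.loc[a, a] += 1
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    mat.loc[a, b] += 1
                    mat.loc[b, a] += 1
    return mat
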