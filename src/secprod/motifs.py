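"""Fixed-pattern motif counting: N-glycosylation sequons and ER retention.

The canonical N-glycosylation acceptor site (sequon) is N-X-[S/T] with X any
residue except proline; secreted proteins of successful producers carry
markedly more sequons than unsuccessful ones, so the per-class sequon count
is a compact univariate summary of that signal. A permissive N-X-[S/T]
variant (proline allowed) is available via ``allow_proline``.

ER retention is flagged by the C-terminal HDEL/KDEL tetrapeptide, the most
common retrieval signal; proteins carrying it are withheld from secretion
and are excluded from production datasets upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import ER_RETENTION_SUFFIXES, ProteinRecord, StructuralAnnotation
from .representations import split_signal_peptide


def count_nglyc_sequons(seq: str, allow_proline: bool = False) -> int:
    """Count N-X-[S/T] sequons (X != P unless ``allow_proline``); overlaps count."""
    if not seq:
        raise ValueError("empty sequence")
    count = 0
    for i in range(len(seq) - 2):
        if (
            seq[i] == "N"
            and (allow_proline or seq[i + 1] != "P")
            and seq[i + 2] in "ST"
        ):
            count += 1
    return count


def has_er_retention(seq: str) -> bool:
    """True iff the sequence ends with HDEL or KDEL."""
    if not seq:
        raise ValueError("empty sequence")
    return seq.endswith(ER_RETENTION_SUFFIXES)


@dataclass(frozen=True)
class MotifSummary:
    """Per-protein sequon counts with class and overall means."""

    per_protein: Mapping[str, int]
    class_means: Mapping[int, float]
    overall_mean: float
    scope: str  # "full" or "mature"


def class_motif_summary(
    records: Sequence[ProteinRecord],
    scope: str = "full",
    annotations: Mapping[str, StructuralAnnotation] | None = None,
    allow_proline: bool = False,
) -> MotifSummary:
    """Sequon counts per protein plus per-class means.

    ``scope="mature"`` counts on the mature sequence only and requires
    annotations (for the cleavage position); the default counts on the full
    sequence. Both labels must be present.
    """
    if scope not in ("full", "mature"):
        raise ValueError("scope must be 'full' or 'mature'")
    per_protein: dict[str, int] = {}
    by_label: dict[int, list[int]] = {}
    for rec in records:
        seq = rec.protein_seq
        if scope == "mature":
            if annotations is None or rec.id not in annotations:
                raise KeyError(
                    f"scope='mature' needs an annotation for record {rec.id!r}"
                )
            _, seq = split_signal_peptide(seq, annotations[rec.id].cleavage_pos)
        n = count_nglyc_sequons(seq, allow_proline=allow_proline)
        per_protein[rec.id] = n
        if rec.label is not None:
            by_label.setdefault(rec.label, []).append(n)
    if not (1 in by_label and -1 in by_label):
        raise ValueError("both classes must be present")
    class_means = {label: float(np.mean(v)) for label, v in by_label.items()}
    return MotifSummary(
        per_protein=per_protein,
        class_means=class_means,
        overall_mean=float(np.mean(list(per_protein.values()))),
        scope=scope,
    )
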