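"""Domain types, input validation, dataset filters and redundancy reduction.

The central objects are :class:`ProteinRecord` (a protein with optional coding
sequence and a binary production label) and :class:`StructuralAnnotation`
(signal-peptide cleavage position plus per-residue solvent-accessibility and
secondary-structure state strings, as produced by external structure
predictors and consumed here as plain annotation input).

Dataset construction follows the screening protocol for secreted-protein
production libraries: keep proteins with a predicted signal peptide and more
than ``min_length`` residues, drop proteins carrying the most common
ER-retention signal (C-terminal HDEL/KDEL) or predicted to be transmembrane,
then reduce sequence redundancy so homologous proteins cannot inflate
cross-validation estimates.

Redundancy is decided from an optimal local alignment (match +1, mismatch -1,
gap -2; configurable in :class:`FilterConfig`): two sequences are redundant
when identity over the aligned columns exceeds ``identity_threshold`` and the
aligned span covers at least ``coverage_threshold`` of at least one of the
two sequences. Redundant pairs are single-linkage clustered and each cluster
is replaced by the member with the shortest average distance (1 - identity)
to all other members; a cluster mixing production labels keeps one
representative per label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = ("TAA", "TAG", "TGA")
ER_RETENTION_SUFFIXES = ("HDEL", "KDEL")

POSITIVE = 1
NEGATIVE = -1


@dataclass(frozen=True)
class OrfValidation:
    """Outcome of checking an ORF against its protein sequence."""

    valid: bool
    reasons: tuple[str, ...] = ()


def validate_orf(protein_seq: str, orf_seq: str) -> OrfValidation:
    """Check that ``orf_seq`` encodes ``protein_seq`` exactly.

    An ORF is valid when it runs exactly from the start ATG until a stop
    codon: its length is ``3 * (len(protein_seq) + 1)``, it starts with ATG,
    ends with TAA/TAG/TGA, and standard-genetic-code translation of the
    non-stop codons reproduces the protein sequence.

    Failure reasons are ``"alphabet"`` (non-ACGT characters), ``"length"``
    (wrong length, e.g. missing stop codon) and ``"translation"`` (wrong
    start/stop codon or translation mismatch).
    """
    if not protein_seq or not orf_seq:
        raise ValueError("protein and ORF sequences must be non-empty")
    orf = orf_seq.upper()
    if set(orf) - set("ACGT"):
        return OrfValidation(False, ("alphabet",))
    if len(orf) != 3 * (len(protein_seq) + 1):
        return OrfValidation(False, ("length",))
    if not orf.startswith("ATG") or orf[-3:] not in STOP_CODONS:
        return OrfValidation(False, ("translation",))
    translated = str(Seq(orf[:-3]).translate())
    if translated != protein_seq.upper():
        return OrfValidation(False, ("translation",))
    return OrfValidation(True)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, sequence, optional ORF, label, organism tag.

    ``label`` is +1 for successful high-level production, -1 for
    unsuccessful, ``None`` for unknown. If ``orf_seq`` is present it must
    validate against the protein sequence (see :func:`validate_orf`).
    """

    id: str
    protein_seq: str
    orf_seq: str | None = None
    label: int | None = None
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.protein_seq:
            raise ValueError(f"record {self.id!r}: empty protein sequence")
        if self.protein_seq != self.protein_seq.upper():
            raise ValueError(f"record {self.id!r}: protein sequence must be uppercase")
        bad = set(self.protein_seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-standard amino acid(s) {sorted(bad)}"
            )
        if self.label not in (POSITIVE, NEGATIVE, None):
            raise ValueError(f"record {self.id!r}: label must be +1, -1 or None")
        if self.orf_seq is not None:
            report = validate_orf(self.protein_seq, self.orf_seq)
            if not report.valid:
                raise ValueError(
                    f"record {self.id!r}: ORF invalid ({', '.join(report.reasons)})"
                )

    def __len__(self) -> int:
        return len(self.protein_seq)


@dataclass(frozen=True)
class StructuralAnnotation:
    """Per-protein structural annotation from external predictors.

    ``cleavage_pos`` is the 1-based length of the signal peptide in residues;
    the mature sequence is everything after it. ``acc_states`` is over {B, E}
    (buried/exposed), ``ss_states`` over {H, E, C} (helix/strand/coil); both
    must exactly cover the mature sequence. ``tm_flag`` marks proteins
    predicted transmembrane by both external predictors, ``sp_flag`` marks a
    predicted signal peptide.
    """

    cleavage_pos: int
    acc_states: str
    ss_states: str
    tm_flag: bool = False
    sp_flag: bool = True

    def __post_init__(self) -> None:
        if self.cleavage_pos <= 0:
            raise ValueError("cleavage_pos must be positive (1-based residue count)")
        if set(self.acc_states) - set("BE"):
            raise ValueError("acc_states must be over {B, E}")
        if set(self.ss_states) - set("HEC"):
            raise ValueError("ss_states must be over {H, E, C}")
        if len(self.acc_states) != len(self.ss_states):
            raise ValueError("acc_states and ss_states must have equal length")

    def check_against(self, record: ProteinRecord) -> None:
        """Raise unless this annotation is consistent with ``record``."""
        n = len(record.protein_seq)
        if not 0 < self.cleavage_pos < n:
            raise ValueError(
                f"record {record.id!r}: cleavage_pos {self.cleavage_pos} out of "
                f"range for length-{n} sequence"
            )
        mature_len = n - self.cleavage_pos
        if len(self.acc_states) != mature_len:
            raise ValueError(
                f"record {record.id!r}: acc_states length {len(self.acc_states)} "
                f"!= mature length {mature_len}"
            )


@dataclass(frozen=True)
class FilterConfig:
    """Dataset filter and redundancy-reduction parameters.

    Length filter is strict (``> min_length`` residues). Alignment scoring for
    the redundancy criterion is fixed here so the identity definition is
    reproducible: local alignment with match +1, mismatch -1, linear gap -2.
    """

    min_length: int = 100
    require_signal_peptide: bool = True
    drop_er_retention: bool = True
    drop_transmembrane: bool = True
    identity_threshold: float = 0.8
    coverage_threshold: float = 0.8
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        for name in ("identity_threshold", "coverage_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class FilterResult:
    retained: tuple[ProteinRecord, ...]
    exclusions: Mapping[str, tuple[str, ...]]


def apply_filters(
    records: Iterable[ProteinRecord],
    annotations: Mapping[str, StructuralAnnotation],
    config: FilterConfig = FilterConfig(),
) -> FilterResult:
    """Apply the dataset inclusion filters; record a reason per dropped record.

    Retained records have a predicted signal peptide, are longer than
    ``min_length`` residues, do not end in HDEL/KDEL and are not flagged
    transmembrane. Raises ``KeyError`` for a record without annotation.
    """
    retained: list[ProteinRecord] = []
    exclusions: dict[str, tuple[str, ...]] = {}
    for rec in records:
        if rec.id not in annotations:
            raise KeyError(f"no structural annotation for record {rec.id!r}")
        ann = annotations[rec.id]
        reasons: list[str] = []
        if config.require_signal_peptide and not ann.sp_flag:
            reasons.append("no_signal_peptide")
        if len(rec.protein_seq) <= config.min_length:
            reasons.append("too_short")
        if config.drop_er_retention and rec.protein_seq.endswith(ER_RETENTION_SUFFIXES):
            reasons.append("er_retention")
        if config.drop_transmembrane and ann.tm_flag:
            reasons.append("transmembrane")
        if reasons:
            exclusions[rec.id] = tuple(reasons)
        else:
            retained.append(rec)
    return FilterResult(tuple(retained), exclusions)


@dataclass(frozen=True)
class IdentityResult:
    identity: float
    coverage_a: float
    coverage_b: float


def _make_aligner(config: FilterConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match_score
    aligner.mismatch_score = config.mismatch_score
    aligner.open_gap_score = config.gap_score
    aligner.extend_gap_score = config.gap_score
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, config: FilterConfig = FilterConfig()
) -> IdentityResult:
    """Identity and per-sequence coverage of the optimal local alignment.

    Identity is matches divided by aligned columns (gap columns included);
    coverage of each sequence is the aligned span divided by its length. If
    no positive-scoring local alignment exists (e.g. no residue in common),
    identity and coverages are 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignments = _make_aligner(config).align(seq_a, seq_b)
    if len(alignments) == 0:
        return IdentityResult(0.0, 0.0, 0.0)
    aln = alignments[0]
    columns = aln.length
    if columns == 0:
        return IdentityResult(0.0, 0.0, 0.0)
    identities = aln.counts().identities
    span_a = aln.coordinates[0][-1] - aln.coordinates[0][0]
    span_b = aln.coordinates[1][-1] - aln.coordinates[1][0]
    return IdentityResult(
        identities / columns, span_a / len(seq_a), span_b / len(seq_b)
    )


def is_redundant_pair(
    seq_a: str, seq_b: str, config: FilterConfig = FilterConfig()
) -> bool:
    """True when the two sequences meet the redundancy criterion."""
    res = pairwise_identity(seq_a, seq_b, config)
    return res.identity > config.identity_threshold and (
        res.coverage_a >= config.coverage_threshold
        or res.coverage_b >= config.coverage_threshold
    )


class _UnionFind:
    def __init__(self, items: Sequence[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _identity_cache(
    records: Sequence[ProteinRecord], config: FilterConfig
) -> dict[frozenset, IdentityResult]:
    cache: dict[frozenset, IdentityResult] = {}
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            cache[frozenset((a.id, b.id))] = pairwise_identity(
                a.protein_seq, b.protein_seq, config
            )
    return cache


def _representative(
    members: Sequence[ProteinRecord],
    all_members: Sequence[ProteinRecord],
    cache: Mapping[frozenset, IdentityResult],
) -> ProteinRecord:
    """Member of ``members`` with shortest average distance to ``all_members``.

    Distance is 1 - identity; ties break on lexicographic id.
    """

    def mean_distance(rec: ProteinRecord) -> float:
        others = [m for m in all_members if m.id != rec.id]
        if not others:
            return 0.0
        return sum(
            1.0 - cache[frozenset((rec.id, o.id))].identity for o in others
        ) / len(others)

    return min(sorted(members, key=lambda r: r.id), key=mean_distance)


def reduce_redundancy(
    records: Sequence[ProteinRecord], config: FilterConfig = FilterConfig()
) -> tuple[ProteinRecord, ...]:
    """Single-linkage cluster redundant records and keep representatives.

    Per cluster the member minimizing mean (1 - identity) to all other
    members is retained; a cluster containing both labels retains exactly one
    positive and one negative (each chosen within its label group, distances
    still measured to the whole cluster). Singletons pass through. Output
    preserves input order.
    """
    if not records:
        raise ValueError("need at least one record")
    records = list(records)
    cache = _identity_cache(records, config)
    uf = _UnionFind([r.id for r in records])
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            res = cache[frozenset((a.id, b.id))]
            if res.identity > config.identity_threshold and (
                res.coverage_a >= config.coverage_threshold
                or res.coverage_b >= config.coverage_threshold
            ):
                uf.union(a.id, b.id)
    clusters: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        clusters.setdefault(uf.find(rec.id), []).append(rec)

    keep: set[str] = set()
    for members in clusters.values():
        labels = {m.label for m in members}
        if len(labels) == 1:
            keep.add(_representative(members, members, cache).id)
        else:
            for label in labels:
                group = [m for m in members if m.label == label]
                keep.add(_representative(group, members, cache).id)
    return tuple(r for r in records if r.id in keep)


def cross_set_reduce(
    test_set: Sequence[ProteinRecord],
    train_set: Sequence[ProteinRecord],
    config: FilterConfig = FilterConfig(),
) -> tuple[ProteinRecord, ...]:
    """Drop test records redundant with any training record.

    Uses the same redundancy criterion as :func:`reduce_redundancy`; the
    training set is left unchanged.
    """
    reduced = []
    for rec in test_set:
        if not any(
            is_redundant_pair(rec.protein_seq, tr.protein_seq, config)
            for tr in train_set
        ):
            reduced.append(rec)
    return tuple(reduced)
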