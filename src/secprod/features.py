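"""Feature extraction: compositions, codon statistics, k-mers, physicochemistry.

Feature sets (names follow the catalogue used throughout the package):

========  ================================================  ========
set       description                                       columns
========  ================================================  ========
f0        ORF codon composition (64-letter codon alphabet)  64
f1        signal-peptide amino-acid composition             20
f2        mature-protein amino-acid composition             20
f3        buried/exposed state composition                  2
f4/f5     buried / exposed amino-acid composition           20 each
f6        helix/strand/coil state composition               3
f7/f8/f9  helix / strand / coil amino-acid composition      20 each
f4r..f9r  randomized controls of f4,f5,f7,f8,f9             20 each
f10       predefined physicochemical cluster composition    11
f12       codon usage (59 degenerately encoded codons)      59
f13       sp_length, protein_length, cai, pI                4
f15..f18  k-mer counts of the protein sequence, k=2..5      observed
f19..f22  k-mer counts of the signal peptide, k=2..5        observed
========  ================================================  ========

f11 (data-optimized cluster composition) is produced by pairing
:func:`cluster_feature_matrix` with a clustering from
:mod:`secprod.aa_clustering`; f14 (forward-selected features) lives in
:mod:`secprod.model_eval`.

Feature matrices are plain :class:`pandas.DataFrame` objects indexed by
record id with uniquely named columns, so matrices from different sets can
be concatenated into selection pools.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from . import representations
from .data_model import AMINO_ACIDS, ProteinRecord, StructuralAnnotation

#: All 64 codons, lexicographic over ACGT.
CODONS = tuple("".join(t) for t in itertools.product("ACGT", repeat=3))

#: codon -> amino acid for the 61 sense codons (standard genetic code).
CODON_TO_AA: Mapping[str, str] = dict(standard_dna_table.forward_table)

#: amino acid -> tuple of its codons.
CODON_FAMILIES: Mapping[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}

#: The 59 codons that non-uniquely encode an amino acid (all sense codons
#: except ATG and TGG, whose amino acids have a single codon).
DEGENERATE_CODONS = tuple(
    c
    for aa in AMINO_ACIDS
    for c in CODON_FAMILIES[aa]
    if len(CODON_FAMILIES[aa]) > 1
)


@dataclass(frozen=True)
class ClusterSet:
    """Ordered amino-acid cluster sets used for cluster-composition features.

    Learned clusterings are disjoint (an amino acid sits in at most one
    cluster and need not be in any); the predefined physicochemical clusters
    overlap by nature and set ``allow_overlap``.
    """

    clusters: tuple[frozenset, ...]
    names: tuple[str, ...] | None = None
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("ClusterSet needs at least one cluster")
        seen: set[str] = set()
        for cl in self.clusters:
            if not cl:
                raise ValueError("clusters must be non-empty")
            bad = set(cl) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"non-standard amino acid(s) {sorted(bad)}")
            if not self.allow_overlap and seen & cl:
                raise ValueError(
                    f"clusters overlap on {sorted(seen & cl)}; "
                    "set allow_overlap for predefined cluster tables"
                )
            seen |= cl
        if self.names is not None and len(self.names) != len(self.clusters):
            raise ValueError("names must match number of clusters")

    def labels(self) -> tuple[str, ...]:
        if self.names is not None:
            return self.names
        return tuple("".join(sorted(cl)) for cl in self.clusters)

    def covered(self) -> frozenset:
        return frozenset().union(*self.clusters)


#: The 11 predefined physicochemical amino-acid clusters (Taylor-style
#: groupings; cysteine excluded from the polar cluster because its state,
#: free vs disulfide-bonded, is unknown without structure).
TABLE1_CLUSTERS = ClusterSet(
    clusters=(
        frozenset("VCAGTPSDN"),  # small
        frozenset("SWNQTY"),  # polar uncharged
        frozenset("FYWH"),  # aromatic
        frozenset("DE"),  # acidic
        frozenset("HKRED"),  # charged
        frozenset("KRH"),  # basic
        frozenset("ILVMFYWHCATK"),  # hydrophobic
        frozenset("AGS"),  # tiny
        frozenset("AVLIMGFP"),  # nonpolar
        frozenset("ILV"),  # aliphatic
        frozenset("YWHKRDETSNQ"),  # polar
    ),
    names=(
        "small",
        "polar_uncharged",
        "aromatic",
        "acidic",
        "charged",
        "basic",
        "hydrophobic",
        "tiny",
        "nonpolar",
        "aliphatic",
        "polar",
    ),
    allow_overlap=True,
)


def composition(seq: Sequence, alphabet: Sequence[str]) -> np.ndarray:
    """Fraction of each alphabet symbol in ``seq`` (Σ = 1).

    ``seq`` may be a string or a sequence of tokens (e.g. codons).
    """
    if len(seq) == 0:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = Counter(seq)
    unknown = set(counts) - set(alphabet)
    if unknown:
        raise ValueError(f"symbol(s) outside alphabet: {sorted(unknown)}")
    n = len(seq)
    return np.array([counts[a] / n for a in alphabet], dtype=float)


def cluster_composition(seq: str, clusters: ClusterSet) -> np.ndarray:
    """Per-cluster summed amino-acid fractions of ``seq``."""
    comp = composition(seq, AMINO_ACIDS)
    by_aa = dict(zip(AMINO_ACIDS, comp))
    return np.array(
        [sum(by_aa[a] for a in cl) for cl in clusters.clusters], dtype=float
    )


def codon_usage(codon_seq: Sequence[str]) -> np.ndarray:
    """Relative synonymous usage for the 59 degenerately encoded codons.

    Each entry is the codon count divided by the count of the amino acid it
    encodes; codons of amino acids absent from the translation are 0, so for
    every amino acid present its family entries sum to 1.
    """
    if len(codon_seq) == 0:
        raise ValueError("empty codon sequence")
    tokens = [c.upper() for c in codon_seq]
    bad = set(tokens) - set(CODONS)
    if bad:
        raise ValueError(f"invalid codon(s): {sorted(bad)}")
    counts = Counter(tokens)
    aa_counts: Counter = Counter()
    for codon, cnt in counts.items():
        aa = CODON_TO_AA.get(codon)  # stops are skipped
        if aa is not None:
            aa_counts[aa] += cnt
    return np.array(
        [
            counts[c] / aa_counts[CODON_TO_AA[c]] if aa_counts[CODON_TO_AA[c]] else 0.0
            for c in DEGENERATE_CODONS
        ],
        dtype=float,
    )


def build_reference_index(
    orf_collection: Iterable[Sequence[str]],
) -> dict[str, float]:
    """Relative adaptiveness w for the 59 degenerate codons from reference ORFs.

    Within each synonymous family, ``w = count / max family count``. Codons
    with zero reference count are floored at 0.01 so geometric means stay
    finite; families entirely absent from the reference get neutral w = 1.
    """
    agg: Counter = Counter()
    n_seqs = 0
    for seq in orf_collection:
        agg.update(c.upper() for c in seq)
        n_seqs += 1
    if n_seqs == 0:
        raise ValueError("empty reference collection")
    w: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        fam = CODON_FAMILIES[aa]
        if len(fam) < 2:
            continue
        mx = max(agg[c] for c in fam)
        for c in fam:
            w[c] = 1.0 if mx == 0 else max(agg[c] / mx, 0.01)
    return w


def codon_adaptation_index(
    codon_seq: Sequence[str], reference: Mapping[str, float]
) -> float:
    """Geometric mean of relative adaptiveness over the degenerate codons.

    Stop codons and the single-codon families (ATG, TGG) are excluded, as
    usual for this index.
    """
    eligible = [reference[c.upper()] for c in codon_seq if c.upper() in reference]
    if not eligible:
        raise ValueError("no codons from multi-codon families in sequence")
    return float(math.exp(sum(math.log(v) for v in eligible) / len(eligible)))


# Bjellqvist pKa values: generic termini with residue-specific overrides,
# plus the seven ionizable side chains.
PKA_POSITIVE_SIDE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE_SIDE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PKA_CTERM_DEFAULT = 3.55
PKA_CTERM = {"D": 4.55, "E": 4.75}


def net_charge(protein_seq: str, pH: float) -> float:
    """Henderson–Hasselbalch net charge at ``pH`` (termini + side chains)."""
    if not protein_seq:
        raise ValueError("empty sequence")
    counts = Counter(protein_seq)

    def pos(pka: float, n: float = 1.0) -> float:
        return n / (1.0 + 10.0 ** (pH - pka))

    def neg(pka: float, n: float = 1.0) -> float:
        return -n / (1.0 + 10.0 ** (pka - pH))

    charge = pos(PKA_NTERM.get(protein_seq[0], PKA_NTERM_DEFAULT))
    charge += neg(PKA_CTERM.get(protein_seq[-1], PKA_CTERM_DEFAULT))
    for aa, pka in PKA_POSITIVE_SIDE.items():
        if counts[aa]:
            charge += pos(pka, counts[aa])
    for aa, pka in PKA_NEGATIVE_SIDE.items():
        if counts[aa]:
            charge += neg(pka, counts[aa])
    return charge


def isoelectric_point(protein_seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14]."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein_seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Counts of all overlapping length-``k`` windows of ``seq``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(seq):
        warnings.warn(
            f"k={k} exceeds sequence length {len(seq)}; returning empty counts",
            stacklevel=2,
        )
        return {}
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def spectrum_kernel_matrix(seqs: Sequence[str], k: int) -> np.ndarray:
    """Spectrum-kernel Gram matrix: inner products of k-mer count vectors."""
    for i, s in enumerate(seqs):
        if len(s) < k:
            raise ValueError(f"sequence {i} shorter than k={k}: {s!r}")
    maps = [kmer_counts(s, k) for s in seqs]
    n = len(seqs)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            a, b = maps[i], maps[j]
            if len(b) < len(a):
                a, b = b, a
            K[i, j] = K[j, i] = sum(cnt * b.get(kmer, 0) for kmer, cnt in a.items())
    return K


# --- feature-set assembly ----------------------------------------------------

_AA_COMPOSITION_SETS = {
    "f1": ("signal_peptide", "sp_comp"),
    "f2": ("mature", "comp"),
    "f4": ("buried", "buried_comp"),
    "f5": ("exposed", "exposed_comp"),
    "f7": ("helix", "helix_comp"),
    "f8": ("strand", "strand_comp"),
    "f9": ("coil", "coil_comp"),
    "f4r": ("buried_rand", "buried_rand_comp"),
    "f5r": ("exposed_rand", "exposed_rand_comp"),
    "f7r": ("helix_rand", "helix_rand_comp"),
    "f8r": ("strand_rand", "strand_rand_comp"),
    "f9r": ("coil_rand", "coil_rand_comp"),
}

_KMER_SETS = {
    "f15": ("protein", 2),
    "f16": ("protein", 3),
    "f17": ("protein", 4),
    "f18": ("protein", 5),
    "f19": ("signal_peptide", 2),
    "f20": ("signal_peptide", 3),
    "f21": ("signal_peptide", 4),
    "f22": ("signal_peptide", 5),
}

FEATURE_SETS = (
    ("f0", "f3", "f6", "f10", "f12", "f13")
    + tuple(_AA_COMPOSITION_SETS)
    + tuple(_KMER_SETS)
)

#: Default pool for univariate prefilter + forward selection: the
#: compositional sets plus the four scalar sequence-derived features
#: (64+20+20+2+3+11+4 = 124 columns when ORFs are available).
DEFAULT_SELECTION_SETS = ("f0", "f1", "f2", "f3", "f6", "f10", "f13")


def _composition_or_zero(seq, alphabet, rec_id: str, kind: str) -> np.ndarray:
    if len(seq) == 0:
        warnings.warn(
            f"record {rec_id!r}: empty {kind} subsequence; emitting zero row",
            stacklevel=3,
        )
        return np.zeros(len(alphabet))
    return composition(seq, alphabet)


def assemble_features(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, StructuralAnnotation],
    set_name: str,
    *,
    reference_index: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the named feature matrix over ``records``.

    ``reference_index`` supplies the relative-adaptiveness table for the
    codon adaptation index in f13; if omitted it is derived from the ORFs of
    ``records`` themselves. ``seed`` controls the randomized structural
    controls (f4r..f9r).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")

    def annot(rec: ProteinRecord) -> StructuralAnnotation:
        if rec.id not in annotations:
            raise KeyError(f"no structural annotation for record {rec.id!r}")
        return annotations[rec.id]

    if set_name == "f0":
        rows = [
            composition(representations.derive(r, None, "orf_codons"), CODONS)
            for r in records
        ]
        cols = [f"codon:{c}" for c in CODONS]
    elif set_name in _AA_COMPOSITION_SETS:
        kind, prefix = _AA_COMPOSITION_SETS[set_name]
        rows = [
            _composition_or_zero(
                representations.derive(r, annot(r), kind, seed), AMINO_ACIDS, r.id, kind
            )
            for r in records
        ]
        cols = [f"{prefix}:{a}" for a in AMINO_ACIDS]
    elif set_name == "f3":
        rows = [
            composition(representations.derive(r, annot(r), "acc_states"), "BE")
            for r in records
        ]
        cols = ["acc:B", "acc:E"]
    elif set_name == "f6":
        rows = [
            composition(representations.derive(r, annot(r), "ss_states"), "HEC")
            for r in records
        ]
        cols = ["ss:H", "ss:E", "ss:C"]
    elif set_name == "f10":
        rows = [
            cluster_composition(
                representations.derive(r, annot(r), "mature"), TABLE1_CLUSTERS
            )
            for r in records
        ]
        cols = [f"cluster:{name}" for name in TABLE1_CLUSTERS.labels()]
    elif set_name == "f12":
        rows = [
            codon_usage(representations.derive(r, None, "orf_codons"))
            for r in records
        ]
        cols = [f"usage:{c}" for c in DEGENERATE_CODONS]
    elif set_name == "f13":
        codon_seqs = {
            r.id: representations.derive(r, None, "orf_codons") for r in records
        }
        ref = reference_index or build_reference_index(codon_seqs.values())
        rows = [
            np.array(
                [
                    annot(r).cleavage_pos,
                    len(r.protein_seq),
                    codon_adaptation_index(codon_seqs[r.id], ref),
                    isoelectric_point(r.protein_seq),
                ]
            )
            for r in records
        ]
        cols = ["sp_length", "protein_length", "cai", "pI"]
    elif set_name in _KMER_SETS:
        source, k = _KMER_SETS[set_name]
        prefix = f"{k}mer" if source == "protein" else f"sp_{k}mer"
        maps = []
        for r in records:
            seq = (
                r.protein_seq
                if source == "protein"
                else representations.derive(r, annot(r), "signal_peptide")
            )
            maps.append(kmer_counts(seq, k))
        observed = sorted(set().union(*maps)) if maps else []
        rows = [
            np.array([m.get(kmer, 0) for kmer in observed], dtype=float) for m in maps
        ]
        cols = [f"{prefix}:{kmer}" for kmer in observed]
    else:
        raise ValueError(f"unknown feature set {set_name!r}")

    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(cols))),
                        index=pd.Index(ids, name="id"), columns=cols)


def cluster_feature_matrix(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, StructuralAnnotation],
    clusters: ClusterSet,
    representation: str = "mature",
) -> pd.DataFrame:
    """Cluster-composition feature matrix for an arbitrary ClusterSet (f11)."""
    ids = [r.id for r in records]
    rows = [
        cluster_composition(
            representations.derive(r, annotations.get(r.id), representation), clusters
        )
        for r in records
    ]
    cols = [f"cluster:{name}" for name in clusters.labels()]
    return pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"), columns=cols)


def selection_pool(
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, StructuralAnnotation],
    sets: Sequence[str] = DEFAULT_SELECTION_SETS,
    *,
    reference_index: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Concatenate feature sets into one pool for univariate selection."""
    parts = [
        assemble_features(
            records, annotations, s, reference_index=reference_index, seed=seed
        )
        for s in sets
    ]
    pool = pd.concat(parts, axis=1)
    if pool.columns.duplicated().any():
        dupes = pool.columns[pool.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names across sets: {dupes}")
    return pool


def ttest_prefilter(
    X: pd.DataFrame, y: Sequence[int], alpha: float = 0.05
) -> pd.DataFrame:
    """Welch two-sample t-test per column; keep p < alpha, sort by |t| desc.

    Constant columns get t = 0, p = 1 and are never selected. Returns a frame
    with columns ``feature``, ``t``, ``p``.
    """
    y = np.asarray(y)
    if not ((y == 1).any() and (y == -1).any()):
        raise ValueError("both classes must be present")
    pos = X.values[y == 1]
    neg = X.values[y == -1]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant columns trigger a precision warning and a nan result;
        # they are mapped to t=0, p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(pos, neg, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame({"feature": X.columns, "t": t, "p": p})
    table = table[table["p"] < alpha]
    return table.reindex(table["t"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
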