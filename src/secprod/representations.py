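"""Derived sequence representations of a protein.

A protein with an ORF and structural annotation yields ten representations:
the codon sequence (64-letter codon alphabet), the signal peptide and mature
amino-acid sequences, the solvent-accessibility state string (B/E), the
buried and exposed amino-acid subsequences, the secondary-structure state
string (H/E/C), and the helix, strand and coil amino-acid subsequences.

Each structural subsequence also has a randomized control of the same
length, drawn uniformly without replacement from the mature sequence. A
classifier that performs as well on the randomized control as on the real
subsequence derives its signal from subsequence *length*, not from which
residues are in the predicted structural state.
"""

from __future__ import annotations

import zlib

import numpy as np

from .data_model import ProteinRecord, StructuralAnnotation

#: Representation names accepted by :func:`derive`.
KINDS = (
    "orf_codons",
    "signal_peptide",
    "mature",
    "acc_states",
    "buried",
    "exposed",
    "ss_states",
    "helix",
    "strand",
    "coil",
    "buried_rand",
    "exposed_rand",
    "helix_rand",
    "strand_rand",
    "coil_rand",
)

_STATE_SOURCE = {
    "buried": ("acc_states", frozenset("B")),
    "exposed": ("acc_states", frozenset("E")),
    "helix": ("ss_states", frozenset("H")),
    "strand": ("ss_states", frozenset("E")),
    "coil": ("ss_states", frozenset("C")),
}

# Randomized subsequences are cached per (record id, kind, seed) so repeated
# feature assembly sees identical controls.
_RANDOM_CACHE: dict[tuple[str, str, int], str] = {}


def split_signal_peptide(protein_seq: str, cleavage_pos: int) -> tuple[str, str]:
    """Split a protein into (signal peptide, mature sequence).

    ``cleavage_pos`` is the 1-based signal-peptide length; both parts must be
    non-empty and concatenate back to the input.
    """
    if not 0 < cleavage_pos < len(protein_seq):
        raise ValueError(
            f"cleavage_pos {cleavage_pos} out of range for length-"
            f"{len(protein_seq)} sequence"
        )
    return protein_seq[:cleavage_pos], protein_seq[cleavage_pos:]


def to_codon_sequence(orf_seq: str) -> tuple[str, ...]:
    """Tokenize an ORF into consecutive non-overlapping codons.

    The stop codon is kept as a token; input is case-normalized. Length must
    be divisible by 3 and strictly ACGT.
    """
    orf = orf_seq.upper()
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} not divisible by 3")
    bad = set(orf) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT character(s) in ORF: {sorted(bad)}")
    return tuple(orf[i : i + 3] for i in range(0, len(orf), 3))


def state_subsequence(mature: str, states: str, keep: frozenset | set) -> str:
    """Residues of ``mature`` whose structural state is in ``keep``, in order."""
    if len(mature) != len(states):
        raise ValueError(
            f"sequence length {len(mature)} != state-string length {len(states)}"
        )
    return "".join(aa for aa, st in zip(mature, states) if st in keep)


def randomized_subsequence(full_seq: str, length: int, seed: int) -> str:
    """``length`` residues sampled without replacement from ``full_seq``.

    Deterministic in ``seed``; at ``length == len(full_seq)`` the result is a
    permutation of the input.
    """
    if not 0 <= length <= len(full_seq):
        raise ValueError(
            f"length {length} outside [0, {len(full_seq)}]"
        )
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(full_seq), size=length, replace=False)
    return "".join(full_seq[i] for i in idx)


def _variant_seed(record_id: str, kind: str, seed: int) -> int:
    # Stable per-(protein, representation) stream below 2**31.
    return (zlib.crc32(f"{record_id}:{kind}".encode()) ^ seed) & 0x7FFFFFFF


def derive(
    record: ProteinRecord,
    annot: StructuralAnnotation | None,
    kind: str,
    seed: int = 0,
):
    """Return the requested representation of ``record``.

    Codon representations return a tuple of codon tokens; all others return
    strings. Structural representations require ``annot``; randomized
    variants additionally take ``seed`` and are drawn from the mature
    sequence (the sequence the structural states are defined on).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown representation {kind!r}")
    if kind == "orf_codons":
        if record.orf_seq is None:
            raise ValueError(f"record {record.id!r} has no ORF sequence")
        return to_codon_sequence(record.orf_seq)
    if annot is None:
        raise ValueError(f"representation {kind!r} requires a structural annotation")
    annot.check_against(record)
    sp, mature = split_signal_peptide(record.protein_seq, annot.cleavage_pos)
    if kind == "signal_peptide":
        return sp
    if kind == "mature":
        return mature
    if kind == "acc_states":
        return annot.acc_states
    if kind == "ss_states":
        return annot.ss_states
    if kind in _STATE_SOURCE:
        attr, keep = _STATE_SOURCE[kind]
        return state_subsequence(mature, getattr(annot, attr), keep)
    # randomized structural controls
    base = kind.removesuffix("_rand")
    attr, keep = _STATE_SOURCE[base]
    length = len(state_subsequence(mature, getattr(annot, attr), keep))
    key = (record.id, kind, seed)
    if key not in _RANDOM_CACHE:
        _RANDOM_CACHE[key] = randomized_subsequence(
            mature, length, _variant_seed(record.id, kind, seed)
        )
    return _RANDOM_CACHE[key]
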