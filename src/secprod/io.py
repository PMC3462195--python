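"""Plain-text dataset I/O: FASTA sequences, labels TSV, annotations TSV."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .data_model import ProteinRecord, StructuralAnnotation


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, int]:
    """Labels TSV (columns id, label in {pos, neg}) -> {id: +1/-1}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = {"pos": 1, "neg": -1}
    bad = set(df["label"]) - set(mapping)
    if bad:
        raise ValueError(f"unknown label value(s): {sorted(bad)}")
    return {row.id: mapping[row.label] for row in df.itertuples()}


def write_labels(path: str | Path, labels: Mapping[str, int]) -> None:
    df = pd.DataFrame(
        {"id": list(labels), "label": ["pos" if v == 1 else "neg" for v in labels.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, StructuralAnnotation]:
    """Annotations TSV -> {id: StructuralAnnotation}.

    Columns: id, sp_flag, cleavage_pos, tm_flag, acc_states, ss_states.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "acc_states": str, "ss_states": str})
    out: dict[str, StructuralAnnotation] = {}
    for row in df.itertuples():
        out[row.id] = StructuralAnnotation(
            cleavage_pos=int(row.cleavage_pos),
            acc_states=str(row.acc_states),
            ss_states=str(row.ss_states),
            tm_flag=bool(row.tm_flag),
            sp_flag=bool(row.sp_flag),
        )
    return out


def write_annotations(
    path: str | Path, annotations: Mapping[str, StructuralAnnotation]
) -> None:
    df = pd.DataFrame(
        {
            "id": list(annotations),
            "sp_flag": [a.sp_flag for a in annotations.values()],
            "cleavage_pos": [a.cleavage_pos for a in annotations.values()],
            "tm_flag": [a.tm_flag for a in annotations.values()],
            "acc_states": [a.acc_states for a in annotations.values()],
            "ss_states": [a.ss_states for a in annotations.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_dataset(
    fasta: str | Path,
    orf_fasta: str | Path | None = None,
    labels: str | Path | None = None,
    annotations: str | Path | None = None,
    organism: str = "",
) -> tuple[list[ProteinRecord], dict[str, StructuralAnnotation]]:
    """Assemble records (and annotations) from the on-disk file set.

    Ids must match across files; ORFs and labels are optional per file but
    when a file is given every protein id must appear in it.
    """
    proteins = read_fasta(fasta)
    orfs = read_fasta(orf_fasta) if orf_fasta else {}
    label_map = read_labels(labels) if labels else {}
    annot_map = read_annotations(annotations) if annotations else {}
    records = []
    for rec_id, seq in proteins.items():
        if orfs and rec_id not in orfs:
            raise KeyError(f"no ORF for record {rec_id!r}")
        if label_map and rec_id not in label_map:
            raise KeyError(f"no label for record {rec_id!r}")
        records.append(
            ProteinRecord(
                id=rec_id,
                protein_seq=seq,
                orf_seq=orfs.get(rec_id),
                label=label_map.get(rec_id),
                organism=organism,
            )
        )
    return records, annot_map


def write_dataset(
    prefix: str | Path,
    records: Sequence[ProteinRecord],
    annotations: Mapping[str, StructuralAnnotation],
) -> dict[str, Path]:
    """Write <prefix>.protein.fasta/.orf.fasta/.labels.tsv/.annot.tsv."""
    prefix = Path(prefix)
    paths = {
        "protein": prefix.with_suffix(".protein.fasta"),
        "orf": prefix.with_suffix(".orf.fasta"),
        "labels": prefix.with_suffix(".labels.tsv"),
        "annot": prefix.with_suffix(".annot.tsv"),
    }
    write_fasta(paths["protein"], {r.id: r.protein_seq for r in records})
    orfs = {r.id: r.orf_seq for r in records if r.orf_seq}
    if orfs:
        write_fasta(paths["orf"], orfs)
    labels = {r.id: r.label for r in records if r.label is not None}
    if labels:
        write_labels(paths["labels"], labels)
    write_annotations(paths["annot"], annotations)
    return paths
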