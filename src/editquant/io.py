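"""File formats: FASTA/FASTQ via Biopython, headered TSVs via pandas.

All internal tables round-trip exactly through their TSV form; TSVs are
tolerant of CRLF line endings.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .align import AlignedRead
from .amplicon import AmpliconReference
from .calling import CLASSES, EditCall, OutcomeTable

ANNOT_COLUMNS = ["name", "protospacer_start", "strand", "pam"]


def read_references(fasta_path, annot_path) -> dict[str, AmpliconReference]:
    """Load amplicons from a FASTA plus an annotation TSV with columns
    name, protospacer_start, strand, pam."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"{fasta_path}: no FASTA records")
    annot = pd.read_csv(annot_path, sep="\t")
    missing = [c for c in ANNOT_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"{annot_path}: missing columns {missing}")
    refs = {}
    for i, row in annot.iterrows():
        name = str(row["name"])
        if name not in seqs:
            raise ValueError(f"{annot_path} line {i + 2}: no FASTA record named {name!r}")
        refs[name] = AmpliconReference(
            name=name,
            sequence=seqs[name],
            protospacer_start=int(row["protospacer_start"]),
            strand=str(row["strand"]),
            pam=str(row["pam"]),
        )
    return refs


def read_fastq(path) -> list:
    reads = list(SeqIO.parse(str(path), "fastq"))
    if not reads:
        raise ValueError(f"{path}: empty FASTQ input")
    return reads


def write_fastq(records, path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def alignments_to_frame(aligned: list[AlignedRead]) -> pd.DataFrame:
    rows = [
        {
            "read_id": a.read_id,
            "ref_start": a.ref_start,
            "cigar": a.cigar(),
            "score": a.score,
            "reverse_complemented": a.reverse_complemented,
        }
        for a in aligned
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "ref_start", "cigar", "score", "reverse_complemented"]
    )


def calls_to_frame(calls: list[EditCall]) -> pd.DataFrame:
    rows = [
        {
            "read_id": c.read_id,
            "class": c.klass,
            "indel_len": c.indel_len,
            "indel_start": c.indel_start,
            "substitutions": ";".join(c.substitutions),
            "reason": c.reason,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["read_id", "class", "indel_len", "indel_start", "substitutions", "reason"]
    )


def outcomes_to_frame(tables: list[OutcomeTable]) -> pd.DataFrame:
    return pd.DataFrame([t.as_row() for t in tables])


def allele_table(reads, calls: list[EditCall]) -> pd.DataFrame:
    """Allele-count table: one row per distinct read sequence with its count
    and called class."""
    by_id = {c.read_id: c.klass for c in calls}
    rows: dict[tuple[str, str], int] = {}
    for rec in reads:
        read_id, seq = (rec.id, str(rec.seq)) if hasattr(rec, "seq") else rec
        key = (seq, by_id.get(read_id, "unknown"))
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [{"sequence": s, "class": k, "count": n} for (s, k), n in rows.items()],
        columns=["sequence", "class", "count"],
    )
    return df.sort_values(["count", "sequence"], ascending=[False, True]).reset_index(drop=True)


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
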