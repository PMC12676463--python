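"""FASTA reading/writing wrappers (Biopython-backed)."""

from __future__ import annotations

from Bio import SeqIO

from .seq import wrap_fasta


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_records(records, path) -> None:
    """Write an iterable of Biopython SeqRecords as 60-column FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{wrap_fasta(str(rec.seq))}")
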