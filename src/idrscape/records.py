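"""Protein sequence records and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scales import AMINO_ACIDS

_CANONICAL = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical one-letter codes.

    Non-canonical letters (including X) are rejected rather than skipped:
    silently dropping residues would corrupt downstream composition
    statistics.
    """

    id: str
    sequence: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise ValueError(
                f"{self.id}: non-canonical letters {sorted(bad)}; "
                "only the 20 canonical amino acids are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(r.id, str(r.seq).upper(), r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)
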