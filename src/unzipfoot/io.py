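"""FASTA and report I/O."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .energy_model import HairpinSequence

__all__ = ["read_hairpin_fasta", "write_hairpin_fasta"]


def read_hairpin_fasta(path, loop: str = "TTTT") -> HairpinSequence:
    """Read the first record of a FASTA file as a hairpin stem.

    A ``loop=...`` token in the record description overrides `loop`.
    """
    record = next(SeqIO.parse(str(path), "fasta"))
    for token in record.description.split():
        if token.startswith("loop="):
            loop = token.split("=", 1)[1]
    return HairpinSequence(str(record.seq), loop)


def write_hairpin_fasta(seq: HairpinSequence, path, name: str = "hairpin") -> None:
    record = SeqRecord(Seq(seq.stem), id=name, description=f"loop={seq.loop}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write([record], str(path), "fasta")
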