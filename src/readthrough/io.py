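"""FASTA and tab-separated I/O helpers shared across the package.

All coordinates written by this package are 0-based, half-open; table writers
emit a ``# coordinates: 0-based half-open`` header comment so downstream
consumers never have to guess.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COORD_NOTE = "# coordinates: 0-based half-open\n"


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs; ids cut at first whitespace."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[Tuple[str, str]], width: int = 60) -> None:
    seq_records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_table(path) -> pd.DataFrame:
    """Read a headered TSV, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})


def write_table(path, frame: pd.DataFrame, coord_note: bool = False) -> None:
    with open(path, "w") as fh:
        if coord_note:
            fh.write(COORD_NOTE)
        frame.to_csv(fh, sep="\t", index=False)
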