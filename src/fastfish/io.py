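"""Plain-text I/O: FASTA oligo sets, TSV tables, TIFF image stacks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import OligoRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_candidates",
    "read_length_dwell",
    "write_stack",
    "read_stack",
]


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def write_candidates(path, pairs: list[tuple[OligoRecord, OligoRecord]]) -> None:
    """Ranked candidate table: target, probe and the target's scores."""
    rows = [
        {
            "target": t.sequence,
            "probe": p.sequence,
            "gc": t.gc_fraction,
            "g_count": t.g_count,
            "complexity": t.lz_complexity,
            "fold_energy": t.fold_energy,
        }
        for t, p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_length_dwell(path) -> list[tuple[float, float]]:
    """(template length nt, peak dwell s) pairs from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return list(zip(df[cols[0]].astype(float), df[cols[1]].astype(float)))


def write_stack(path, stack: np.ndarray) -> None:
    """Write a frames x height x width array as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
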