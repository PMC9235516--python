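"""FASTA and TSV plumbing."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sketch import KmerSequence, MinimizerSketch, decode_kmer

logger = logging.getLogger("sketchbias")

__all__ = ["read_fasta", "read_fasta_record", "write_fasta", "write_tsv", "sketch_table"]


def read_fasta(path) -> dict[str, str]:
    """All records as {id: upper-cased sequence}.  Lowercase bases are folded."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("record %s: folding lowercase bases to uppercase", rec.id)
        records[rec.id] = seq.upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_fasta_record(path, record_id: Optional[str] = None, k: int = 16
                      ) -> KmerSequence:
    """One record k-merized; the first record unless an id is given.

    Ambiguity codes (N etc.) are rejected for sketching.
    """
    records = read_fasta(path)
    if record_id is None:
        seq = next(iter(records.values()))
    else:
        try:
            seq = records[record_id]
        except KeyError:
            raise ValueError(f"record {record_id!r} not found in {path}") from None
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(
            f"sequence contains non-ACGT characters {sorted(bad)}; "
            "sketching requires unambiguous nucleotides"
        )
    return KmerSequence.from_string(seq, k)


def write_fasta(sequences: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences]
    SeqIO.write(recs, str(path), "fasta")


def write_tsv(frame, path) -> None:
    frame.to_csv(Path(path), sep="\t", index=False)


def sketch_table(ks: KmerSequence, sketch: MinimizerSketch, values):
    """Sketch as a table with columns position, kmer, hash_value."""
    import pandas as pd

    pos = sketch.positions
    return pd.DataFrame(
        {
            "position": pos,
            "kmer": [decode_kmer(ks.codes[p], ks.k) for p in pos],
            "hash_value": [values[p] for p in pos],
        }
    )
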