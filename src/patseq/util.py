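"""Small shared helpers: sequence manipulation and FASTA I/O."""

from __future__ import annotations

from typing import Dict, Iterable

from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file into a {name: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def as_seq(s: str) -> Seq:
    return Seq(s)


def max_base_run(seq: str, base: str) -> int:
    """Length of the longest run of `base` in `seq`."""
    best = cur = 0
    for ch in seq:
        if ch == base:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best
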