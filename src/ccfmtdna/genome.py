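"""Genome containers and low-level DNA sequence utilities.

The mitochondrial genome is a circle: a window "centered" at any of its L
positions is well defined by wrapping across the origin, which is why the
:class:`CircularGenome` container carries an explicit ``circular`` flag.
Nuclear genomes (or any linear contig) use the same container with
``circular=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN"

# uint8 encoding: A=0 C=1 G=2 T=3 N=4; anything else is invalid.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i
_DECODE_LUT = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, N=4)."""
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() == 255:
        bad = chr(int(np.frombuffer(seq.encode(), np.uint8)[arr == 255][0]))
        raise ValueError(f"invalid base {bad!r}; alphabet is {ALPHABET}")
    return arr


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return bytes(_DECODE_LUT[np.asarray(arr, dtype=np.uint8)]).decode("ascii")


@dataclass(frozen=True)
class CircularGenome:
    """A DNA sequence with a name and a circularity flag.

    Parameters
    ----------
    sequence:
        Upper- or lower-case DNA over the alphabet ACGTN.
    name:
        Contig label used in alignment records and FASTA headers.
    circular:
        True for the mitochondrial circle, False for linear contigs.
    """

    sequence: str
    name: str = "chrM"
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("genome must contain at least one base")
        encode(self.sequence)  # validates the alphabet
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def window(self, center: int, width: int) -> str:
        """Window of odd ``width`` whose central nucleotide sits at ``center``.

        On a circular genome the window wraps across the origin; on a linear
        genome the window must fit entirely within the sequence.
        """
        if width < 1 or width % 2 == 0:
            raise ValueError("window width must be a positive odd integer")
        L = len(self.sequence)
        if L < width:
            raise ValueError(f"genome of length {L} shorter than window {width}")
        half = width // 2
        if self.circular:
            start = (center - half) % L
            stop = start + width
            if stop <= L:
                return self.sequence[start:stop]
            return self.sequence[start:] + self.sequence[: stop - L]
        if center - half < 0 or center + half >= L:
            raise ValueError(
                f"window centered at {center} does not fit in linear genome of length {L}"
            )
        return self.sequence[center - half : center + half + 1]


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    """Write genomes to FASTA; circularity is recorded in the description."""
    records = [
        SeqRecord(
            Seq(g.sequence),
            id=g.name,
            description="circular" if g.circular else "linear",
        )
        for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, circular_names: Sequence[str] = ()) -> list[CircularGenome]:
    """Read genomes from FASTA.

    A contig is flagged circular if its name is in ``circular_names`` or its
    description contains the word "circular" (as written by
    :func:`write_fasta`).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circ = rec.id in circular_names or "circular" in rec.description.split()
        out.append(CircularGenome(str(rec.seq), name=rec.id, circular=circ))
    return out
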