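"""cfDNA fragment records, length computation, and size distributions.

A cfDNA fragment is observed as a paired-end read; its length is the distance
(+1) between the first and the last aligned base of the pair.  Records whose
primary alignment is nuclear are removed before any mitochondrial analysis so
that NUMT-derived reads cannot masquerade as mtDNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 30


@dataclass
class FragmentRecord:
    """One sequenced cfDNA fragment (a resolved paired-end read).

    ``first_aligned``/``last_aligned`` are 0-based inclusive reference
    coordinates of the outermost aligned bases of the pair.  On a circular
    contig ``last_aligned`` may exceed the contig length minus one; consumers
    interpret positions modulo the contig length.  ``seq``/``quals`` carry the
    base calls across the fragment span when known (synthetic fragments and
    SAM pairs with pure-match alignments).
    """

    qname: str
    reference: str
    first_aligned: int
    last_aligned: int
    mapq: int = 60
    primary: bool = True
    strand: str = "+"
    seq: str | None = None
    quals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.last_aligned < self.first_aligned:
            raise ValueError("last_aligned must be >= first_aligned")
        if self.mapq < 0:
            raise ValueError("mapq must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def fragment_length(record: FragmentRecord) -> int:
    """Fragment length in bp: last_aligned - first_aligned + 1."""
    return record.last_aligned - record.first_aligned + 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["qname", "reference", "first_aligned", "last_aligned",
                "mapq", "primary", "strand", "seq", "quals"]


def write_fragments_tsv(records: Iterable[FragmentRecord], path: str | Path) -> None:
    """Serialize fragment records as a plain TSV (qualities as phred+33)."""
    rows = []
    for r in records:
        rows.append({
            "qname": r.qname, "reference": r.reference,
            "first_aligned": r.first_aligned, "last_aligned": r.last_aligned,
            "mapq": r.mapq, "primary": int(r.primary), "strand": r.strand,
            "seq": r.seq if r.seq is not None else "",
            "quals": "".join(chr(q + 33) for q in r.quals) if r.quals is not None else "",
        })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_sam(records: Iterable[FragmentRecord], path: str | Path,
              reference_lengths: dict[str, int], read_length: int = 100) -> int:
    """Write fragments as a minimal text SAM of proper read pairs.

    Each fragment becomes two mates with pure-match CIGARs whose outermost
    aligned bases reproduce the fragment span.  Mates are ``read_length``
    long, stretched to half the fragment when necessary so the pair always
    tiles the whole span (fragment sequence and qualities survive a round
    trip through :func:`read_alignments`).  Fragments that wrap a circular
    origin have no pure-match linear representation and are skipped with a
    logged count (the return value).
    """
    records = list(records)
    skipped = 0
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in reference_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            ref_len = reference_lengths[r.reference]
            if r.last_aligned >= ref_len:
                skipped += 1
                continue
            flen = fragment_length(r)
            rl = max(min(read_length, flen), (flen + 1) // 2)
            seq = r.seq if r.seq is not None else "*"
            qual = "".join(chr(q + 33) for q in r.quals) if r.quals is not None else "*"
            mate1 = (r.first_aligned, seq[:rl] if seq != "*" else "*",
                     qual[:rl] if qual != "*" else "*")
            mate2 = (r.last_aligned - rl + 1, seq[flen - rl:] if seq != "*" else "*",
                     qual[flen - rl:] if qual != "*" else "*")
            if r.strand == "+":
                flags = (0x1 | 0x2 | 0x20 | 0x40, 0x1 | 0x2 | 0x10 | 0x80)
            else:
                flags = (0x1 | 0x2 | 0x10 | 0x40, 0x1 | 0x2 | 0x20 | 0x80)
            for (pos, s, q), flag, mpos, tlen in (
                (mate1, flags[0], mate2[0], flen),
                (mate2, flags[1], mate1[0], -flen),
            ):
                fh.write(
                    f"{r.qname}\t{flag}\t{r.reference}\t{pos + 1}\t{r.mapq}\t"
                    f"{rl}M\t=\t{mpos + 1}\t{tlen}\t{s}\t{q}\n"
                )
    if skipped:
        logger.info("write_sam: skipped %d origin-wrapping fragments", skipped)
    return skipped


def _read_tsv(path: str | Path, min_mapq: int) -> list[FragmentRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"seq": str, "quals": str})
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            if int(row.mapq) < min_mapq:
                continue
            quals = (np.frombuffer(str(row.quals).encode(), np.uint8) - 33
                     if row.quals else None)
            records.append(FragmentRecord(
                qname=str(row.qname), reference=str(row.reference),
                first_aligned=int(row.first_aligned), last_aligned=int(row.last_aligned),
                mapq=int(row.mapq), primary=bool(int(row.primary)),
                strand=str(row.strand),
                seq=str(row.seq) if row.seq else None, quals=quals,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed record at data line {i + 1} of {path}: {exc}") from exc
    return records


def _read_sam(path: str | Path, min_mapq: int) -> list[FragmentRecord]:
    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            by_name.setdefault(aln.query_name, []).append(aln)
    records, dropped = [], 0
    for qname, alns in by_name.items():
        if len(alns) != 2 or alns[0].reference_name != alns[1].reference_name:
            dropped += len(alns)
            continue
        a, b = sorted(alns, key=lambda x: x.reference_start)
        first = a.reference_start
        last = max(a.reference_end, b.reference_end) - 1
        seq = quals = None
        if a.query_sequence and b.query_sequence:
            flen = last - first + 1
            sarr = np.full(flen, ord("N"), np.uint8)
            qarr = np.zeros(flen, np.uint8)
            for m in (b, a):  # a second so mate1 wins in overlaps
                off = m.reference_start - first
                s = np.frombuffer(m.query_sequence.encode(), np.uint8)
                sarr[off:off + s.size] = s
                if m.query_qualities is not None:
                    qarr[off:off + s.size] = np.asarray(m.query_qualities, np.uint8)
            seq, quals = bytes(sarr).decode(), qarr
        mate1 = a if a.is_read1 else b
        records.append(FragmentRecord(
            qname=qname, reference=a.reference_name, first_aligned=first,
            last_aligned=last, mapq=min(a.mapping_quality, b.mapping_quality),
            primary=True, strand="-" if mate1.is_reverse else "+",
            seq=seq, quals=quals,
        ))
    if dropped:
        logger.info("read_alignments: dropped %d unpaired/discordant reads", dropped)
    records.sort(key=lambda r: (r.reference, r.first_aligned, r.qname))
    return records


def read_alignments(path: str | Path, min_mapq: int = DEFAULT_MIN_MAPQ) -> list[FragmentRecord]:
    """Read fragment records from minimal SAM or from the TSV dialect.

    Reads below ``min_mapq`` are excluded before pairing; reads left without a
    mate are dropped with a logged count.  Format is chosen by extension
    (``.tsv`` vs anything else = SAM).
    """
    path = Path(path)
    if path.suffix.lower() == ".tsv":
        return _read_tsv(path, min_mapq)
    return _read_sam(path, min_mapq)


# ---------------------------------------------------------------------------
# mitochondrial partitioning
# ---------------------------------------------------------------------------

def filter_mt(records: Sequence[FragmentRecord], mt_reference: str = "chrM",
              known_references: Sequence[str] | None = None) -> list[FragmentRecord]:
    """Keep fragments whose *primary* alignment is on the mitochondrial contig.

    Secondary/supplementary placements never qualify, so reads whose primary
    home is nuclear are removed even if they also align to mtDNA (the NUMT
    guard).  If ``known_references`` is given, any other contig label raises.
    """
    if known_references is not None:
        known = set(known_references) | {mt_reference}
        for r in records:
            if r.reference not in known:
                raise ValueError(f"unknown contig {r.reference!r} in fragment {r.qname}")
    return [r for r in records if r.primary and r.reference == mt_reference]


def mt_yield(records: Sequence[FragmentRecord], mt_reference: str = "chrM") -> float:
    """Fraction of fragments with a primary mitochondrial alignment."""
    if not records:
        raise ValueError("mt_yield of an empty record set is undefined")
    n_mt = sum(1 for r in records if r.primary and r.reference == mt_reference)
    return n_mt / len(records)


# ---------------------------------------------------------------------------
# size distribution
# ---------------------------------------------------------------------------

class SizeDistribution:
    """Empirical fragment-size distribution.

    ``fraction_below`` is strict (< t, mirroring "less than 100 bp");
    ``fraction_in`` is closed on both ends ([lo, hi]).
    """

    def __init__(self, lengths: Iterable[int], bin_edges: np.ndarray | None = None):
        arr = np.sort(np.asarray(list(lengths), dtype=float))
        if arr.size == 0:
            raise ValueError("size distribution of an empty length set is undefined")
        if np.any(arr < 1):
            raise ValueError("fragment lengths must be >= 1")
        self.lengths = arr
        if bin_edges is None:
            bin_edges = np.arange(int(arr.min()), int(arr.max()) + 2) - 0.5
        self.bin_edges = np.asarray(bin_edges, dtype=float)
        self.counts, _ = np.histogram(arr, bins=self.bin_edges)

    @property
    def n(self) -> int:
        return self.lengths.size

    def cdf(self, x: float) -> float:
        """Empirical CDF: P(length <= x)."""
        return np.searchsorted(self.lengths, x, side="right") / self.n

    def fraction_below(self, t: float) -> float:
        """P(length < t), strict."""
        return np.searchsorted(self.lengths, t, side="left") / self.n

    def fraction_at_or_above(self, t: float) -> float:
        return 1.0 - self.fraction_below(t)

    def fraction_in(self, lo: float, hi: float) -> float:
        """P(lo <= length <= hi), closed interval."""
        right = np.searchsorted(self.lengths, hi, side="right")
        left = np.searchsorted(self.lengths, lo, side="left")
        return (right - left) / self.n

    def to_frame(self) -> pd.DataFrame:
        """Histogram + CDF table suitable for CSV export."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({
            "length": centers,
            "count": self.counts,
            "cdf": np.cumsum(self.counts) / self.n,
        })


def size_distribution(lengths: Iterable[int]) -> SizeDistribution:
    """Build a :class:`SizeDistribution` from a multiset of fragment lengths."""
    return SizeDistribution(lengths)
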