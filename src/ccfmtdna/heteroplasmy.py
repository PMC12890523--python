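"""Stranded pileups and low-frequency heteroplasmy calling.

Heteroplasmy — the coexistence of more than one mtDNA genotype in a sample —
is detected from per-site, per-strand allele counts.  A site is called only
when it clears four criteria together:

* sequencing coverage strictly greater than 400 quality-passing bases,
* minor allele frequency (top non-reference base / coverage) >= 1%,
* per-strand minor allele frequency >= 0.6% on *both* strands, and
* no significant allele-frequency difference between strands (two-sided
  Fisher exact test on the alt/ref x plus/minus table, retained when
  p >= alpha = 0.05).

Base calls below the base-quality threshold (Q20) and reads below the mapping
quality threshold (Q30) never enter the pileup; coverage counts
quality-passing bases only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .fragmentomics import FragmentRecord
from .genome import CircularGenome, encode

DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_BASEQ = 20
DEFAULT_MIN_COVERAGE = 400
DEFAULT_MIN_MAF = 0.01
DEFAULT_MIN_STRAND_MAF = 0.006
DEFAULT_ALPHA = 0.05

_BASES = "ACGT"
_STRANDS = ("+", "-")


@dataclass
class StrandedPileupSite:
    """Quality-passing allele counts at one mt position.

    ``counts`` is a (2, 4) array indexed [strand (+=0, -=1), base (ACGT)].
    """

    position: int
    ref_base: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 4):
            raise ValueError("counts must be a (2 strands, 4 bases) array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.ref_base not in _BASES:
            raise ValueError(f"ref_base must be one of {_BASES}")

    @property
    def coverage(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class HeteroplasmySite:
    """A passing heteroplasmic SNP with its allele-fraction evidence."""

    position: int
    ref_base: str
    alt_base: str
    maf: float
    maf_plus: float
    maf_minus: float
    strand_p: float
    coverage: int


@dataclass(frozen=True)
class Rejection:
    """Why a pileup site failed calling (first failed criterion)."""

    position: int
    reason: str


@dataclass
class TissueSnpSet:
    """The heteroplasmy call set of one sample (plasma or a tissue)."""

    tissue: str
    sites: dict[tuple[int, str], HeteroplasmySite] = field(default_factory=dict)

    @classmethod
    def from_sites(cls, tissue: str, sites: Iterable[HeteroplasmySite]) -> "TissueSnpSet":
        out = cls(tissue)
        for s in sorted(sites, key=lambda x: (x.position, x.alt_base)):
            key = (s.position, s.alt_base)
            if key in out.sites:
                raise ValueError(f"duplicate site {key} in tissue {tissue!r}")
            out.sites[key] = s
        return out

    def keys(self) -> set[tuple[int, str]]:
        return set(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self.sites

    def __iter__(self) -> Iterator[HeteroplasmySite]:
        return iter(self.sites.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"tissue": self.tissue, "position": s.position, "ref": s.ref_base,
             "alt": s.alt_base, "maf": s.maf, "maf_plus": s.maf_plus,
             "maf_minus": s.maf_minus, "strand_p": s.strand_p,
             "coverage": s.coverage}
            for s in self
        ], columns=["tissue", "position", "ref", "alt", "maf", "maf_plus",
                    "maf_minus", "strand_p", "coverage"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TissueSnpSet":
        df = pd.read_csv(path)
        tissue = str(df["tissue"].iloc[0]) if len(df) else "unknown"
        return cls.from_sites(tissue, (
            HeteroplasmySite(int(r.position), str(r.ref), str(r.alt),
                             float(r.maf), float(r.maf_plus), float(r.maf_minus),
                             float(r.strand_p), int(r.coverage))
            for r in df.itertuples(index=False)
        ))

    def to_vcf(self, path: str | Path, contig: str = "chrM",
               contig_length: int | None = None) -> None:
        """Minimal SNP-only VCF (POS is 1-based on output)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            if contig_length is not None:
                fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
            for k, d in (("MAF", "Minor allele fraction"),
                         ("MAF_PLUS", "Plus-strand alt fraction"),
                         ("MAF_MINUS", "Minus-strand alt fraction"),
                         ("STRAND_P", "Fisher strand-balance p-value"),
                         ("DP", "Quality-passing coverage")):
                typ = "Integer" if k == "DP" else "Float"
                fh.write(f'##INFO=<ID={k},Number=1,Type={typ},Description="{d}">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for s in self:
                info = (f"MAF={s.maf:.6g};MAF_PLUS={s.maf_plus:.6g};"
                        f"MAF_MINUS={s.maf_minus:.6g};STRAND_P={s.strand_p:.6g};"
                        f"DP={s.coverage}")
                fh.write(f"{contig}\t{s.position + 1}\t.\t{s.ref_base}\t"
                         f"{s.alt_base}\t.\tPASS\t{info}\n")


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class Pileup:
    """Array-backed stranded pileup over the covered mt positions."""

    def __init__(self, positions: np.ndarray, ref_bases: str,
                 counts: np.ndarray):
        self.positions = np.asarray(positions, dtype=np.int64)
        self.ref_bases = ref_bases
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (self.positions.size, 2, 4):
            raise ValueError("counts must have shape (n_sites, 2, 4)")

    def __len__(self) -> int:
        return self.positions.size

    def __iter__(self) -> Iterator[StrandedPileupSite]:
        for i in range(len(self)):
            yield StrandedPileupSite(int(self.positions[i]), self.ref_bases[i],
                                     self.counts[i])

    def to_frame(self) -> pd.DataFrame:
        cols = {"position": self.positions, "ref": list(self.ref_bases)}
        for si, strand in enumerate(("plus", "minus")):
            for bi, base in enumerate(_BASES):
                cols[f"{base}_{strand}"] = self.counts[:, si, bi]
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pileup":
        df = pd.read_csv(path, sep="\t")
        counts = np.zeros((len(df), 2, 4), dtype=np.int64)
        for si, strand in enumerate(("plus", "minus")):
            for bi, base in enumerate(_BASES):
                counts[:, si, bi] = df[f"{base}_{strand}"].to_numpy()
        return cls(df["position"].to_numpy(), "".join(df["ref"]), counts)


def build_pileup(records: Sequence[FragmentRecord], reference: CircularGenome,
                 min_mapq: int = DEFAULT_MIN_MAPQ,
                 min_baseq: int = DEFAULT_MIN_BASEQ) -> Pileup:
    """Per-position, per-strand base counts from mt fragment records.

    Each fragment contributes one call per covered position (mate overlap is
    already merged in the record).  Calls below ``min_baseq``, records below
    ``min_mapq``, and N calls are excluded; positions with no passing calls
    are omitted.  Positions wrap modulo the reference length on circular
    contigs.
    """
    L = len(reference)
    counts = np.zeros((L, 2, 4), dtype=np.int64)
    for r in records:
        if r.mapq < min_mapq or r.seq is None:
            continue
        arr = encode(r.seq)
        flen = arr.size
        if r.quals is not None:
            ok = (np.asarray(r.quals) >= min_baseq) & (arr < 4)
        else:
            ok = arr < 4
        pos = r.first_aligned + np.arange(flen)
        if reference.circular:
            pos = pos % L
        elif r.last_aligned >= L:
            raise ValueError(f"fragment {r.qname} extends past linear contig end")
        si = 0 if r.strand == "+" else 1
        np.add.at(counts, (pos[ok], si, arr[ok]), 1)
    covered = counts.sum(axis=(1, 2)) > 0
    idx = np.flatnonzero(covered)
    refs = "".join(reference.sequence[i] for i in idx)
    return Pileup(idx, refs, counts[idx])


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def strand_equality_test(alt_plus: int, ref_plus: int,
                         alt_minus: int, ref_minus: int) -> float:
    """Two-sided Fisher exact p-value on the [alt, ref] x [plus, minus] table."""
    for v in (alt_plus, ref_plus, alt_minus, ref_minus):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if alt_plus + ref_plus == 0 or alt_minus + ref_minus == 0:
        raise ValueError("strand with no observations: test undefined")
    return float(fisher_exact([[alt_plus, ref_plus],
                               [alt_minus, ref_minus]], alternative="two-sided")[1])


def call_heteroplasmy(site: StrandedPileupSite,
                      min_coverage: int = DEFAULT_MIN_COVERAGE,
                      min_maf: float = DEFAULT_MIN_MAF,
                      min_strand_maf: float = DEFAULT_MIN_STRAND_MAF,
                      alpha: float = DEFAULT_ALPHA) -> HeteroplasmySite | Rejection:
    """Apply the four heteroplasmy criteria to one pileup site.

    The evaluated alternate is the most abundant non-reference base (ties
    broken toward the alphabetically first base).  Returns the passing
    :class:`HeteroplasmySite`, or a :class:`Rejection` naming the first
    failed criterion (``coverage``, ``maf``, ``per-strand maf``,
    ``strand balance``).
    """
    cov = site.coverage
    if cov <= min_coverage:  # strictly greater than required
        return Rejection(site.position, "coverage")
    ref_idx = _BASES.index(site.ref_base)
    totals = site.counts.sum(axis=0).astype(float)
    totals[ref_idx] = -1.0
    alt_idx = int(np.argmax(totals))
    alt_total = int(site.counts[:, alt_idx].sum())
    maf = alt_total / cov
    if maf < min_maf:
        return Rejection(site.position, "maf")
    strand_cov = site.counts.sum(axis=1)
    strand_maf = [
        (site.counts[s, alt_idx] / strand_cov[s]) if strand_cov[s] > 0 else 0.0
        for s in (0, 1)
    ]
    if min(strand_maf) < min_strand_maf:
        return Rejection(site.position, "per-strand maf")
    try:
        p = strand_equality_test(
            int(site.counts[0, alt_idx]), int(site.counts[0, ref_idx]),
            int(site.counts[1, alt_idx]), int(site.counts[1, ref_idx]),
        )
    except ValueError:
        return Rejection(site.position, "strand balance")
    if p < alpha:
        return Rejection(site.position, "strand balance")
    return HeteroplasmySite(
        position=site.position, ref_base=site.ref_base, alt_base=_BASES[alt_idx],
        maf=maf, maf_plus=float(strand_maf[0]), maf_minus=float(strand_maf[1]),
        strand_p=p, coverage=cov,
    )


def call_all(pileup: Iterable[StrandedPileupSite], tissue: str = "plasma",
             min_coverage: int = DEFAULT_MIN_COVERAGE,
             min_maf: float = DEFAULT_MIN_MAF,
             min_strand_maf: float = DEFAULT_MIN_STRAND_MAF,
             alpha: float = DEFAULT_ALPHA) -> TissueSnpSet:
    """Call every site of a pileup; passing SNPs sorted by position."""
    passing = []
    for site in pileup:
        res = call_heteroplasmy(site, min_coverage=min_coverage, min_maf=min_maf,
                                min_strand_maf=min_strand_maf, alpha=alpha)
        if isinstance(res, HeteroplasmySite):
            passing.append(res)
    return TissueSnpSet.from_sites(tissue, passing)
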