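"""NUMT-aware target scanning by minimum Hamming distance.

Nuclear-mitochondrial segments (NUMTs) are nuclear copies of mitochondrial
sequence; a PCR probe landing on a region with a near-identical nuclear copy
will count nuclear template as mtDNA.  This module slides an odd-width window
(default 101 bp, centre nucleotide = position) around the circular
mitochondrial genome and records, for every position, the minimum number of
mismatches between that window — or its reverse complement — and every
ungapped placement along the nuclear genome.  High-minimum-distance stretches
are safe ddPCR target regions.

The scan is exact (no heuristic seeding): every nuclear offset on both
strands is evaluated.  Any comparison involving N counts as a mismatch, which
is the conservative choice for primer design.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .genome import CircularGenome, encode, reverse_complement

DEFAULT_WINDOW = 101


@dataclass(frozen=True)
class FragmentWindow:
    """An odd-length window of the mt genome, addressed by its centre base."""

    center: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) % 2 == 0:
            raise ValueError("fragment windows must have odd length")


@dataclass(frozen=True)
class TargetRegion:
    """Half-open [start, end) run of positions safe for ddPCR targeting."""

    start: int
    end: int
    min_profile_value: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HammingProfile:
    """Per-position minimum Hamming distance of mt windows vs a nuclear genome.

    ``positions[i]`` is the mt centre coordinate of ``d_min[i]``.  For a
    circular genome there is one entry per position (length L); for a linear
    genome only full windows exist (length L - W + 1).
    """

    d_min: np.ndarray
    window: int
    positions: np.ndarray
    nuclear_name: str = "nuclear"
    circular: bool = True

    def __post_init__(self) -> None:
        self.d_min = np.asarray(self.d_min, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.d_min.shape != self.positions.shape:
            raise ValueError("d_min and positions must have equal length")
        if self.d_min.size and (self.d_min.min() < 0 or self.d_min.max() > self.window):
            raise ValueError("profile values must lie in [0, window]")

    def __len__(self) -> int:
        return self.d_min.size

    def value_at(self, position: int) -> int:
        idx = np.searchsorted(self.positions, position)
        if idx >= self.positions.size or self.positions[idx] != position:
            raise KeyError(f"no profile entry at position {position}")
        return int(self.d_min[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "d_min": self.d_min})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fragmentization
# ---------------------------------------------------------------------------

def fragmentize(genome: CircularGenome, window: int = DEFAULT_WINDOW) -> list[FragmentWindow]:
    """All windows of the genome, one per admissible centre position.

    A circular genome of length L yields exactly L windows (wrapping across
    the origin); consecutive windows overlap by window - 1 bases.  A linear
    genome yields L - W + 1 windows.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    L = len(genome)
    if L < window:
        raise ValueError(f"genome of length {L} shorter than window {window}")
    half = window // 2
    if genome.circular:
        doubled = genome.sequence + genome.sequence[: window - 1]
        return [
            FragmentWindow(c, doubled[(c - half) % L : (c - half) % L + window])
            for c in range(L)
        ]
    return [
        FragmentWindow(c, genome.sequence[c - half : c + half + 1])
        for c in range(half, L - half)
    ]


# ---------------------------------------------------------------------------
# exact Hamming scans
# ---------------------------------------------------------------------------

def _min_one_window(w_enc: np.ndarray, nuc_enc: np.ndarray,
                    chunk: int = 1 << 19) -> int:
    """Minimum mismatches of one window against all offsets of one strand."""
    W = w_enc.size
    N = nuc_enc.size
    w_valid = w_enc < 4
    best = W
    for off in range(0, N - W + 1, chunk):
        block = nuc_enc[off : min(off + chunk + W - 1, N)]
        view = sliding_window_view(block, W)
        matches = ((view == w_enc) & w_valid & (view < 4)).sum(axis=1)
        best = min(best, int(W - matches.max()))
        if best == 0:
            break
    return best


def _profile_one_strand(ext_enc: np.ndarray, nuc_enc: np.ndarray, W: int) -> np.ndarray:
    """Min distances for every window start of ``ext_enc`` vs one nuclear strand.

    Runs along diagonals of the (window start, nuclear offset) grid: on a
    fixed diagonal the per-base equality indicator is a 1-D array and the
    W-base match count is a sliding-window sum, so the whole scan costs
    O((M + N) * min(M, N)) vectorised byte operations.
    """
    M, N = ext_enc.size, nuc_enc.size
    n_starts = M - W + 1
    best = np.full(n_starts, W, dtype=np.int64)
    ext_valid = ext_enc < 4
    nuc_valid = nuc_enc < 4
    for d in range(-(n_starts - 1), N - W + 1):
        p0 = max(0, -d)
        p1 = min(M, N - d)
        if p1 - p0 < W:
            continue
        eq = ((ext_enc[p0:p1] == nuc_enc[p0 + d : p1 + d])
              & ext_valid[p0:p1] & nuc_valid[p0 + d : p1 + d])
        c = np.cumsum(eq, dtype=np.int64)
        matches = c[W - 1 :].copy()
        matches[1:] -= c[:-W]
        seg = best[p0 : p0 + matches.size]
        np.minimum(seg, W - matches, out=seg)
    return best


def min_hamming(window: FragmentWindow | str, nuclear: CircularGenome | str) -> int:
    """Minimum Hamming distance of a window (or its reverse complement)
    against every ungapped placement in the nuclear genome."""
    wseq = window.sequence if isinstance(window, FragmentWindow) else window
    nseq = nuclear.sequence if isinstance(nuclear, CircularGenome) else nuclear
    if len(nseq) < len(wseq):
        raise ValueError("nuclear genome shorter than the window")
    nuc_enc = encode(nseq)
    fwd = _min_one_window(encode(wseq), nuc_enc)
    if fwd == 0:
        return 0
    rev = _min_one_window(encode(reverse_complement(wseq)), nuc_enc)
    return min(fwd, rev)


def numt_profile(mt: CircularGenome, nuclear: CircularGenome | str,
                 window: int = DEFAULT_WINDOW) -> HammingProfile:
    """Minimum Hamming distance at every mt position against both nuclear strands."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    L = len(mt)
    if L < window:
        raise ValueError("mt genome shorter than the window")
    if isinstance(nuclear, CircularGenome):
        nseq, nname = nuclear.sequence, nuclear.name
    else:
        nseq, nname = nuclear, "nuclear"
    if len(nseq) < window:
        raise ValueError("nuclear genome shorter than the window")
    half = window // 2
    if mt.circular:
        ext = encode(mt.sequence + mt.sequence[: window - 1])
    else:
        ext = encode(mt.sequence)
    nuc_enc = encode(nseq)
    rc_enc = encode(reverse_complement(nseq))
    best = np.minimum(
        _profile_one_strand(ext, nuc_enc, window),
        _profile_one_strand(ext, rc_enc, window),
    )
    if mt.circular:
        centers = np.arange(L)
        d_min = best[(centers - half) % L]
    else:
        centers = np.arange(half, L - half)
        d_min = best
    return HammingProfile(d_min=d_min, window=window, positions=centers,
                          nuclear_name=nname, circular=mt.circular)


# ---------------------------------------------------------------------------
# target-region selection
# ---------------------------------------------------------------------------

def select_target_regions(profile: HammingProfile, min_distance: int,
                          min_length: int) -> list[TargetRegion]:
    """Maximal runs of positions with d_min >= min_distance, at least
    min_length long, as half-open regions in mt centre coordinates.

    On a circular profile a run touching both ends of the array is merged
    across the origin and reported with ``end > L`` (coordinates mod L).
    """
    if min_distance < 1 or min_length < 1:
        raise ValueError("min_distance and min_length must be >= 1")
    d = profile.d_min
    pos = profile.positions
    mask = d >= min_distance
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    runs = list(zip(starts, ends))  # index runs, half-open
    L = d.size
    wrapped = None
    if profile.circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L:
        (s0, e0), (s1, e1) = runs[0], runs[-1]
        runs = runs[1:-1]
        wrapped = TargetRegion(
            start=int(pos[s1]), end=int(pos[e0 - 1]) + 1 + L,
            min_profile_value=int(min(d[s1:e1].min(), d[s0:e0].min())),
        )
    regions = [
        TargetRegion(start=int(pos[s]), end=int(pos[e - 1]) + 1,
                     min_profile_value=int(d[s:e].min()))
        for s, e in runs
    ]
    if wrapped is not None:
        regions.append(wrapped)
    regions = [r for r in regions if r.length >= min_length]
    regions.sort(key=lambda r: r.start)
    return regions


def regions_to_bed(regions: Sequence[TargetRegion], path: str | Path,
                   contig: str = "chrM") -> None:
    """Write target regions as a BED file (0-based half-open, like the API)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{contig}\t{r.start}\t{r.end}\tdmin{r.min_profile_value}\n")
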