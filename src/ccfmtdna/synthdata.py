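"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the cfDNA analysis can be exercised without any sequencing
download: this module builds (i) a circular mitochondrial genome plus a
nuclear genome with NUMT copies planted at exact mismatch counts, (ii)
paired-end cfDNA fragments with a bimodal size distribution, planted
tissue-specific heteroplasmies at chosen allele fractions, and uniform
sequencing error, (iii) droplet assays with Poisson occupancy, and (iv)
two-group metabolite matrices with planted log2 effects, lognormal noise and
missing-at-random entries.

All generators are bit-reproducible under a fixed seed.  Generated base
qualities are a constant Q37 so quality filters are exercised by explicit
low-quality injection in tests rather than by noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .ddpcr_quant import DEFAULT_DROPLET_VOLUME, DropletAssay
from .fragmentomics import FragmentRecord
from .genome import ALPHABET, CircularGenome, decode, encode, reverse_complement
from .metabolomics import MetaboliteMatrix

DEFAULT_WINDOW = 101
DEFAULT_BASE_QUALITY = 37


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NumtPlan:
    """A nuclear copy of one mt window, planted at an exact Hamming distance.

    ``insert_position`` is the 0-based nuclear coordinate of the copy's first
    base; ``mt_window_center`` addresses the source window on the circle;
    ``n_mismatches`` substitutions are applied to the copy; ``revcomp``
    plants the reverse complement instead.
    """

    insert_position: int
    mt_window_center: int
    n_mismatches: int
    revcomp: bool = False

    def __post_init__(self) -> None:
        if self.insert_position < 0 or self.n_mismatches < 0:
            raise ValueError("insert_position and n_mismatches must be non-negative")


@dataclass(frozen=True)
class HeteroplasmyPlan:
    """Ground truth for one planted heteroplasmic SNP in one tissue."""

    tissue: str
    position: int
    ref_base: str
    alt_base: str
    allele_fraction: float

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ValueError("ref and alt must be ACGT bases")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError("allele_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class FragmentSizeModel:
    """Truncated-normal mixture of cfDNA fragment lengths (bp).

    The default two components (modes near 100 and 160-170 bp) reproduce the
    bimodal plasma cfDNA size profile, with roughly 15% of fragments below
    100 bp and roughly 40% below 150 bp.
    """

    means: tuple[float, ...] = (95.0, 170.0)
    sds: tuple[float, ...] = (20.0, 30.0)
    weights: tuple[float, ...] = (0.22, 0.78)
    min_len: int = 30
    max_len: int = 500

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise ValueError("means, sds, weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if self.min_len < 1 or self.max_len <= self.min_len:
            raise ValueError("need 1 <= min_len < max_len")
        if any(s <= 0 for s in self.sds):
            raise ValueError("component sds must be positive")

    def _components(self):
        for mu, sd in zip(self.means, self.sds):
            a = (self.min_len - mu) / sd
            b = (self.max_len - mu) / sd
            yield truncnorm(a, b, loc=mu, scale=sd)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample n integer fragment lengths in [min_len, max_len]."""
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        out = np.empty(n, dtype=float)
        for i, dist in enumerate(self._components()):
            m = comp == i
            if m.any():
                out[m] = dist.rvs(size=int(m.sum()), random_state=rng)
        return np.clip(np.rint(out).astype(int), self.min_len, self.max_len)

    def cdf(self, x) -> np.ndarray | float:
        """Mixture CDF of the (continuous) truncated-normal model."""
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for w, dist in zip(self.weights, self._components()):
            total = total + w * dist.cdf(x)
        return total if total.shape else float(total)


DEFAULT_SIZE_MODEL = FragmentSizeModel()


# ---------------------------------------------------------------------------
# genomes with planted NUMTs
# ---------------------------------------------------------------------------

def make_genomes(mt_length: int, nuc_length: int,
                 numts: Sequence[NumtPlan] = (), seed: int = 0,
                 window: int = DEFAULT_WINDOW) -> tuple[CircularGenome, CircularGenome]:
    """Random circular mt genome plus a linear nuclear genome with NUMT copies.

    Background bases are i.i.d. uniform over ACGT.  Each plan places the
    stated mt window (reverse-complemented if requested) into the nuclear
    genome with exactly ``n_mismatches`` substitutions at positions sampled
    without replacement, each to a uniformly chosen different base.
    Overlapping inserts are rejected.
    """
    if mt_length < window:
        raise ValueError(f"mt_length must be >= window ({window})")
    rng = np.random.default_rng(seed)
    mt = CircularGenome(decode(rng.integers(0, 4, mt_length, dtype=np.uint8).astype(np.uint8)),
                        name="chrM", circular=True)
    nuc_arr = rng.integers(0, 4, nuc_length, dtype=np.uint8).astype(np.uint8)
    occupied: list[tuple[int, int]] = []
    for plan in numts:
        if plan.n_mismatches > window:
            raise ValueError("n_mismatches cannot exceed the window length")
        if plan.insert_position + window > nuc_length:
            raise ValueError(
                f"planted window at {plan.insert_position} does not fit in "
                f"nuclear genome of length {nuc_length}")
        lo, hi = plan.insert_position, plan.insert_position + window
        for (a, b) in occupied:
            if lo < b and a < hi:
                raise ValueError(f"planted insert [{lo}, {hi}) overlaps [{a}, {b})")
        occupied.append((lo, hi))
        wseq = mt.window(plan.mt_window_center, window)
        if plan.revcomp:
            wseq = reverse_complement(wseq)
        copy = encode(wseq)
        if plan.n_mismatches:
            idx = rng.choice(window, size=plan.n_mismatches, replace=False)
            shift = rng.integers(1, 4, size=plan.n_mismatches).astype(np.uint8)
            copy[idx] = (copy[idx] + shift) % 4
        nuc_arr[lo:hi] = copy
    nuclear = CircularGenome(decode(nuc_arr), name="nuclear", circular=False)
    return mt, nuclear


# ---------------------------------------------------------------------------
# cfDNA fragments
# ---------------------------------------------------------------------------

def make_cfdna_fragments(mt_genome: CircularGenome,
                         nuclear_genome: CircularGenome | None,
                         n_fragments: int,
                         size_model: FragmentSizeModel = DEFAULT_SIZE_MODEL,
                         mt_fraction: float = 1.0,
                         plans: Sequence[HeteroplasmyPlan] = (),
                         error_rate: float = 0.001,
                         seed: int = 0,
                         base_quality: int = DEFAULT_BASE_QUALITY,
                         qname_prefix: str = "frag") -> list[FragmentRecord]:
    """Simulate aligned paired-end cfDNA fragments for one sample.

    Mitochondrial fragments (probability ``mt_fraction``) start uniformly on
    the circle with lengths from ``size_model``; at each planted position a
    covering fragment carries the alternate base with probability
    ``allele_fraction`` (a molecule-level draw, made before sequencing
    error).  Sequencing error substitutes each base independently with
    probability ``error_rate`` to a uniformly chosen different base.  Strands
    are assigned independently with probability 1/2.  Nuclear fragments are
    drawn uniformly from the (linear) nuclear genome and keep their nuclear
    primary alignment label.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    if not 0.0 <= mt_fraction <= 1.0:
        raise ValueError("mt_fraction must lie in [0, 1]")
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must lie in [0, 0.25)")
    if mt_fraction < 1.0 and nuclear_genome is None:
        raise ValueError("nuclear genome required when mt_fraction < 1")
    L = len(mt_genome)
    if size_model.max_len > L:
        raise ValueError("size model max_len exceeds the mt genome length")
    for plan in plans:
        if mt_genome.sequence[plan.position] != plan.ref_base:
            raise ValueError(
                f"plan at {plan.position} states ref {plan.ref_base} but the "
                f"genome has {mt_genome.sequence[plan.position]}")

    rng = np.random.default_rng(seed)
    lengths = size_model.sample(n_fragments, rng)
    is_mt = rng.random(n_fragments) < mt_fraction
    strands = np.where(rng.random(n_fragments) < 0.5, "+", "-")
    mt_enc2 = np.concatenate([encode(mt_genome.sequence)] * 2)
    nuc_enc = encode(nuclear_genome.sequence) if nuclear_genome is not None else None
    plan_pos = np.array([p.position for p in plans], dtype=int)
    plan_alt = np.array([encode(p.alt_base)[0] for p in plans], dtype=np.uint8)
    plan_af = np.array([p.allele_fraction for p in plans], dtype=float)

    records: list[FragmentRecord] = []
    for i in range(n_fragments):
        flen = int(lengths[i])
        if is_mt[i]:
            start = int(rng.integers(0, L))
            arr = mt_enc2[start : start + flen].copy()
            if plan_pos.size:
                offsets = (plan_pos - start) % L
                covered = np.flatnonzero(offsets < flen)
                for j in covered:
                    if rng.random() < plan_af[j]:
                        arr[offsets[j]] = plan_alt[j]
            ref_name = mt_genome.name
        else:
            nmax = nuc_enc.size - flen
            if nmax < 0:
                raise ValueError("nuclear genome shorter than a sampled fragment")
            start = int(rng.integers(0, nmax + 1))
            arr = nuc_enc[start : start + flen].copy()
            ref_name = nuclear_genome.name
        if error_rate > 0:
            err = rng.random(flen) < error_rate
            n_err = int(err.sum())
            if n_err:
                arr[err] = (arr[err] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
        records.append(FragmentRecord(
            qname=f"{qname_prefix}{i:07d}", reference=ref_name,
            first_aligned=start, last_aligned=start + flen - 1,
            mapq=60, primary=True, strand=str(strands[i]),
            seq=decode(arr), quals=np.full(flen, base_quality, dtype=np.uint8),
        ))
    return records


# ---------------------------------------------------------------------------
# droplet assays
# ---------------------------------------------------------------------------

def make_droplet_assay(true_conc: float, n_droplets: int,
                       droplet_volume: float = DEFAULT_DROPLET_VOLUME,
                       seed: int = 0) -> DropletAssay:
    """Simulate one ddPCR well at a reaction-scale concentration (copies/uL).

    Each droplet is positive independently with probability
    1 - exp(-true_conc * droplet_volume).  The returned assay carries
    ``dilution=1`` because the generating concentration is reaction-scale.
    """
    if true_conc < 0:
        raise ValueError("true_conc must be non-negative")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be positive")
    rng = np.random.default_rng(seed)
    p = 1.0 - np.exp(-true_conc * droplet_volume)
    positives = int(rng.binomial(n_droplets, p))
    return DropletAssay(positives=positives, total=n_droplets,
                        droplet_volume=droplet_volume, dilution=1.0)


# ---------------------------------------------------------------------------
# metabolite matrices
# ---------------------------------------------------------------------------

def make_metabolite_matrix(n_per_group: int, n_metabolites: int,
                           n_affected: int, effect_log2fc: float,
                           missing_rate: float = 0.0, noise_sd: float = 0.5,
                           seed: int = 0,
                           group_labels: tuple[str, str] = ("sham", "clp"),
                           ) -> tuple[MetaboliteMatrix, list[str]]:
    """Two-group lognormal metabolite matrix with planted effects.

    The first ``n_affected`` metabolites are shifted by ``effect_log2fc``
    (log2 units) in the second group; per-entry noise is N(0, noise_sd) on
    the log2 scale around a metabolite baseline drawn from N(17, 1.5); each
    entry is missing independently with probability ``missing_rate``.
    Returns the matrix and the names of the affected metabolites.
    """
    if n_per_group < 2:
        raise ValueError("each group needs at least two samples")
    if not 0 <= n_affected <= n_metabolites:
        raise ValueError("n_affected must lie in [0, n_metabolites]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    baseline = rng.normal(17.0, 1.5, size=n_metabolites)
    log2x = baseline + rng.normal(0.0, noise_sd, size=(n, n_metabolites))
    log2x[n_per_group:, :n_affected] += effect_log2fc
    X = 2.0 ** log2x
    if missing_rate > 0:
        X[rng.random(X.shape) < missing_rate] = np.nan
    names = [f"met_{j + 1:04d}" for j in range(n_metabolites)]
    samples = ([f"{group_labels[0]}_{i + 1:02d}" for i in range(n_per_group)]
               + [f"{group_labels[1]}_{i + 1:02d}" for i in range(n_per_group)])
    groups = pd.Series([group_labels[0]] * n_per_group
                       + [group_labels[1]] * n_per_group, index=samples,
                       name="group")
    data = pd.DataFrame(X, index=samples, columns=names)
    return MetaboliteMatrix(data=data, groups=groups), names[:n_affected]
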