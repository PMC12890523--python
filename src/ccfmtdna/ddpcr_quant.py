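"""Droplet digital PCR quantification.

A ddPCR reaction partitions the sample into ~20,000 nanolitre-scale droplets;
template molecules distribute over droplets approximately as a Poisson
process, so the fraction of PCR-positive droplets p determines the mean
occupancy lambda = -ln(1 - p) copies per droplet.  Dividing by the droplet
volume gives copies/uL in the reaction, and multiplying by the dilution
factor (20 for the plasma assays modelled here) gives copies/uL in the
original sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

#: Nominal droplet volume (uL) of the QX-class droplet readers.
DEFAULT_DROPLET_VOLUME = 0.00085

#: Default plasma-to-reaction dilution factor.
DEFAULT_DILUTION = 20.0


@dataclass(frozen=True)
class DropletAssay:
    """Counts of positive droplets out of the total read for one well.

    ``droplet_volume`` is in uL; ``dilution`` is the factor converting
    reaction-scale concentration to sample-scale concentration.
    """

    positives: int
    total: int
    droplet_volume: float = DEFAULT_DROPLET_VOLUME
    dilution: float = DEFAULT_DILUTION

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("total droplet count must be >= 1")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must lie in [0, total]")
        if self.droplet_volume <= 0:
            raise ValueError("droplet volume must be positive")
        if self.dilution <= 0:
            raise ValueError("dilution factor must be positive")

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.total


def copies_per_droplet(assay: DropletAssay, poisson: bool = True) -> float:
    """Mean template copies per droplet.

    With ``poisson=True`` (the default, and the model consistent with
    absolute quantification) this is lambda = -ln(1 - p); with
    ``poisson=False`` the raw positive fraction is returned instead.
    A saturated assay (all droplets positive) has no finite estimate.
    """
    p = assay.positive_fraction
    if assay.positives == assay.total:
        raise ValueError(
            "assay is saturated (all droplets positive); concentration is unbounded"
        )
    return -math.log1p(-p) if poisson else p


def quantify(assay: DropletAssay, poisson: bool = True) -> float:
    """Target concentration in copies/uL of the original sample.

    concentration = lambda / droplet_volume * dilution.
    """
    lam = copies_per_droplet(assay, poisson=poisson)
    return lam / assay.droplet_volume * assay.dilution


def recover_concentration(assay: DropletAssay, poisson: bool = True) -> float:
    """Reaction-scale concentration estimate (copies/uL in the reaction).

    This is :func:`quantify` without the dilution factor; it is the quantity
    directly comparable to the generating concentration of a simulated assay.
    """
    return quantify(replace(assay, dilution=1.0), poisson=poisson)


def quantify_table(table: pd.DataFrame, poisson: bool = True,
                   droplet_volume: float = DEFAULT_DROPLET_VOLUME,
                   dilution: float = DEFAULT_DILUTION) -> pd.DataFrame:
    """Quantify a CSV-style table with columns ``sample, positives, total``."""
    out = []
    for row in table.itertuples(index=False):
        assay = DropletAssay(int(row.positives), int(row.total),
                             droplet_volume=droplet_volume, dilution=dilution)
        out.append({"sample": row.sample, "copies_per_ul": quantify(assay, poisson=poisson)})
    return pd.DataFrame(out)
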