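"""Tissue-of-origin inference for plasma heteroplasmy sites.

Each plasma SNP (position, alternate allele) is looked up in the per-tissue
call sets from the same animal.  A plasma SNP found in exactly one tissue is
the strongest evidence for that tissue as the source of the circulating
fragment; matches to several tissues are ambiguous; unmatched SNPs may arise
in circulation or from unsampled tissues.  Allele fractions are not compared
— a match is presence of the identical (position, alt) pair on both sides,
with both sides having passed the same calling criteria.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .heteroplasmy import TissueSnpSet

CATEGORIES = ("unique", "multiple", "unmatched")


@dataclass(frozen=True)
class OriginClassification:
    """Inferred origin of one plasma SNP."""

    site: tuple[int, str]
    category: str
    matched_tissues: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.matched_tissues)
        expected = "unmatched" if n == 0 else ("unique" if n == 1 else "multiple")
        if self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with {n} matched tissues"
            )


@dataclass
class OriginReport:
    """Per-animal summary of plasma SNP origin classifications."""

    animal_id: str
    classifications: list[OriginClassification] = field(default_factory=list)
    tissue_counts: dict[str, int] = field(default_factory=dict)

    @property
    def summary(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cl in self.classifications:
            out[cl.category] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"animal": self.animal_id, "position": cl.site[0], "alt": cl.site[1],
             "category": cl.category, "matched_tissues": ";".join(cl.matched_tissues)}
            for cl in self.classifications
        ], columns=["animal", "position", "alt", "category", "matched_tissues"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "animal": self.animal_id,
            "summary": self.summary,
            "tissue_snp_counts": self.tissue_counts,
            "sites": [
                {"position": cl.site[0], "alt": cl.site[1],
                 "category": cl.category, "matched_tissues": list(cl.matched_tissues)}
                for cl in self.classifications
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _check_unique_labels(tissue_sets: Sequence[TissueSnpSet]) -> None:
    labels = [t.tissue for t in tissue_sets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate tissue labels in {labels}")


def match_site(plasma_site: tuple[int, str],
               tissue_sets: Sequence[TissueSnpSet]) -> OriginClassification:
    """Classify one plasma SNP against the tissue call sets.

    The match key is the identical (position, alternate base) pair; category
    follows the number of matching tissues (0 unmatched, 1 unique, >=2
    multiple).
    """
    _check_unique_labels(tissue_sets)
    matched = tuple(t.tissue for t in tissue_sets if plasma_site in t)
    if len(matched) == 0:
        category = "unmatched"
    elif len(matched) == 1:
        category = "unique"
    else:
        category = "multiple"
    return OriginClassification(site=plasma_site, category=category,
                                matched_tissues=matched)


def tissue_snp_counts(tissue_sets: Sequence[TissueSnpSet]) -> dict[str, int]:
    """Number of passing SNPs per tissue (zero-count tissues retained)."""
    _check_unique_labels(tissue_sets)
    return {t.tissue: len(t) for t in tissue_sets}


def origin_report(animal_id: str, plasma: TissueSnpSet,
                  tissue_sets: Sequence[TissueSnpSet]) -> OriginReport:
    """Classify every plasma SNP of one animal and summarise the counts."""
    _check_unique_labels(tissue_sets)
    if any(t.tissue == plasma.tissue for t in tissue_sets):
        raise ValueError("tissue sets must exclude plasma itself")
    classifications = [
        match_site(key, tissue_sets)
        for key in sorted(plasma.keys())
    ]
    return OriginReport(animal_id=animal_id, classifications=classifications,
                        tissue_counts=tissue_snp_counts(tissue_sets))
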