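"""Clade presence scores and pennate/raphid/benthic signatures.

For every query gene, the fraction of species in a clade with a homologous
hit defines a clade score in [0, 1]. Three signatures contrast paired
clades as log2 ratios of scores:

    pennate signature = log2(pennate score / centric score)
    raphid  signature = log2(raphid score / araphid score)
    benthic signature = log2(benthic score / planktonic score)

A zero denominator with a positive numerator yields +inf (a gene absent
from the whole contrasting clade is maximal, not missing, evidence); a
zero numerator with positive denominator yields -inf; 0/0 is undefined
(NaN). High-signature calls require signature >= 3 (two infinities
included) plus a validation rule: genomic family support for the pennate
and raphid axes, and hits in at least two benthic species for the benthic
axis, because transcriptome absence alone cannot prove gene absence.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CENSUS",
    "AXES",
    "HomologHitTable",
    "clade_scores",
    "signature_values",
    "call_high_signature",
    "robustness_control",
]

#: species counts per clade in the reference transcriptome panel
DEFAULT_CENSUS = {
    "pennate": 32,
    "centric": 56,
    "raphid": 18,
    "araphid": 14,
    "benthic": 8,
    "planktonic": 73,
}

#: signature axis -> (numerator clade, denominator clade)
AXES = {
    "pennate": ("pennate", "centric"),
    "raphid": ("raphid", "araphid"),
    "benthic": ("benthic", "planktonic"),
}

HIGH_SIGNATURE_THRESHOLD = 3.0
MIN_BENTHIC_SPECIES = 2


@dataclasses.dataclass
class HomologHitTable:
    """Binary gene x species hit indicators with per-species clade labels.

    ``species_clades`` is indexed by species with columns ``symmetry``
    (pennate/centric), ``raphe`` (raphid/araphid/unlabeled) and ``habitat``
    (benthic/planktonic/unlabeled). ``census`` overrides the per-clade
    species totals; by default they are counted from the labels.
    """

    hits: pd.DataFrame
    species_clades: pd.DataFrame
    census: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        missing = set(self.hits.columns) - set(self.species_clades.index)
        if missing:
            raise ValueError(f"species without clade labels: {sorted(missing)}")

    def clade_members(self, clade: str) -> list[str]:
        m = self.species_clades.isin([clade]).any(axis=1)
        return [s for s in self.hits.columns if m.get(s, False)]

    def clade_census(self) -> dict[str, int]:
        if self.census is not None:
            return dict(self.census)
        return {c: len(self.clade_members(c)) for c in DEFAULT_CENSUS}


def clade_scores(table: HomologHitTable) -> pd.DataFrame:
    """Per-gene clade scores: hit-species count / clade census."""
    census = table.clade_census()
    out = {}
    for clade in AXES_FLAT():
        total = census.get(clade, 0)
        if total <= 0:
            raise ValueError(f"empty census for clade {clade!r}")
        members = [s for s in table.clade_members(clade) if s in table.hits.columns]
        counts = table.hits[members].sum(axis=1) if members else pd.Series(
            0, index=table.hits.index
        )
        out[f"score_{clade}"] = counts / total
        out[f"hits_{clade}"] = counts.astype(int)
    return pd.DataFrame(out, index=table.hits.index)


def AXES_FLAT() -> list[str]:
    return [c for pair in AXES.values() for c in pair]


def signature_values(scores: pd.DataFrame) -> pd.DataFrame:
    """Attach log2-ratio signatures to a clade-score table."""
    out = scores.copy()
    for axis, (num, den) in AXES.items():
        a = scores[f"score_{num}"].to_numpy(dtype=float)
        b = scores[f"score_{den}"].to_numpy(dtype=float)
        sig = np.full(len(scores), np.nan)
        both = (a > 0) & (b > 0)
        sig[both] = np.log2(a[both] / b[both])
        sig[(a > 0) & (b == 0)] = np.inf
        sig[(a == 0) & (b > 0)] = -np.inf
        out[f"signature_{axis}"] = sig
    return out


def call_high_signature(
    table: pd.DataFrame,
    family_clade_support: Mapping[str, bool] | pd.Series | None = None,
    benthic_species_hits: Mapping[str, int] | pd.Series | None = None,
    threshold: float = HIGH_SIGNATURE_THRESHOLD,
    min_benthic_species: int = MIN_BENTHIC_SPECIES,
) -> pd.DataFrame:
    """Flag genes with validated high signatures, with reason codes.

    ``family_clade_support`` (pennate/raphid axes) records whether the
    diatom homologs of the gene's family are confined to the claimed
    clade; it defaults to False when not provided for a gene.
    ``benthic_species_hits`` defaults to the ``hits_benthic`` column of the
    score table.
    """
    support = pd.Series(family_clade_support if family_clade_support is not None else {},
                        dtype="boolean").reindex(table.index).fillna(False)
    if benthic_species_hits is None:
        if "hits_benthic" not in table.columns:
            raise ValueError("benthic_species_hits required when score table "
                             "lacks a hits_benthic column")
        benthic_hits = table["hits_benthic"]
    else:
        benthic_hits = pd.Series(dict(benthic_species_hits)).reindex(table.index).fillna(0)

    out = pd.DataFrame(index=table.index)
    for axis in AXES:
        sig = table[f"signature_{axis}"]
        above = sig >= threshold  # +inf passes, NaN fails
        if axis == "benthic":
            valid = benthic_hits >= min_benthic_species
            reason_fail = "insufficient_benthic_species"
        else:
            valid = support.astype(bool)
            reason_fail = "no_family_support"
        flag = above.fillna(False) & valid
        reasons = np.where(
            flag, "flagged",
            np.where(above.fillna(False), reason_fail, "signature_below_threshold"),
        )
        out[f"high_{axis}"] = flag
        out[f"reason_{axis}"] = reasons
    return out


def robustness_control(
    strict: pd.DataFrame,
    relaxed: pd.DataFrame,
    threshold: float = HIGH_SIGNATURE_THRESHOLD,
) -> dict[str, float]:
    """Concordance of high-signature calls between two homolog-hit cutoffs.

    Both arguments are signature tables (from :func:`signature_values`)
    over the same gene universe. For every axis, among genes whose strict
    signature passes the threshold, the fraction whose relaxed signature is
    still positive is returned (NaN when no gene passes).
    """
    if set(strict.index) != set(relaxed.index):
        raise ValueError("strict and relaxed tables cover different genes")
    relaxed = relaxed.reindex(strict.index)
    out = {}
    for axis in AXES:
        s = strict[f"signature_{axis}"]
        r = relaxed[f"signature_{axis}"]
        flagged = s >= threshold
        flagged = flagged.fillna(False)
        if flagged.sum() == 0:
            out[axis] = float("nan")
        else:
            out[axis] = float((r[flagged] > 0).mean())
    return out
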