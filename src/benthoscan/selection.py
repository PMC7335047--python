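"""Per-gene nucleotide diversity at synonymous and nonsynonymous sites.

The estimator is the classic frequency-based pi: for a biallelic SNP with
alternate-allele frequency p among n called chromosomes, the per-site
expected heterozygosity is

    h = n / (n - 1) * 2 p (1 - p)

(the n/(n-1) factor is the unbiased sample-size correction; it makes h
exactly equal to the average proportion of pairs of chromosomes that differ
at the site). Summing h over synonymous SNPs of a gene and dividing by the
gene's synonymous site total L_S gives pi_S; nonsynonymous likewise.
Multi-allelic sites contribute n/(n-1) * (1 - sum_i p_i^2) summed over all
alleles including the reference.

Site totals use unweighted Nei-Gojobori fractional counting under the
standard nuclear code: each codon position contributes s/3 synonymous and
(3 - s)/3 nonsynonymous sites, where s is the number of the three possible
single-base changes that preserve the amino acid. Changes creating a stop
codon count as nonsynonymous, which keeps L_N + L_S equal to the callable
CDS length.
"""

from __future__ import annotations

import dataclasses
import functools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

__all__ = [
    "CdsFrameError",
    "count_sites",
    "count_sites_set",
    "pi_per_gene",
    "summarize_pi",
    "compare_groups",
    "flag_positive_candidates",
    "codon_synonymous_fractions",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_BASES = "ACGT"


class CdsFrameError(ValueError):
    """CDS not a clean reading frame (length, internal stop, alphabet)."""


def _translate(codon: str) -> str | None:
    """Amino acid for a codon, None for stop codons."""
    return _TABLE.forward_table.get(codon)


@functools.lru_cache(maxsize=None)
def codon_synonymous_fractions(codon: str) -> tuple[float, float, float]:
    """Fraction of synonymous single-base changes at each codon position."""
    aa = _translate(codon)
    if aa is None:
        raise CdsFrameError(f"stop codon {codon} inside CDS")
    fractions = []
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt_aa = _translate(codon[:i] + b + codon[i + 1:])
            # stop-introducing changes count as nonsynonymous
            if alt_aa is not None and alt_aa == aa:
                syn += 1
        fractions.append(syn / 3)
    return tuple(fractions)


def validate_cds(cds: str) -> str:
    cds = str(cds).upper()
    if len(cds) % 3 != 0:
        raise CdsFrameError(f"CDS length {len(cds)} not divisible by 3")
    if set(cds) - set(_BASES):
        raise CdsFrameError(f"non-ACGT characters in CDS: {set(cds) - set(_BASES)}")
    for i in range(0, len(cds), 3):
        if _translate(cds[i:i + 3]) is None:
            raise CdsFrameError(f"internal stop codon at CDS position {i + 1}")
    return cds


@dataclasses.dataclass(frozen=True)
class SiteCounts:
    l_n: float  # nonsynonymous sites (fractional)
    l_s: float  # synonymous sites (fractional)

    @property
    def total(self) -> float:
        return self.l_n + self.l_s


def count_sites(cds: str, callable_mask: Sequence[bool] | None = None) -> SiteCounts:
    """Nei-Gojobori site counts over the callable positions of one CDS."""
    cds = validate_cds(cds)
    if callable_mask is None:
        mask = np.ones(len(cds), dtype=bool)
    else:
        mask = np.asarray(callable_mask, dtype=bool)
        if mask.shape != (len(cds),):
            raise ValueError("callable_mask length must equal CDS length")
    l_s = 0.0
    for i in range(0, len(cds), 3):
        fr = codon_synonymous_fractions(cds[i:i + 3])
        for j in range(3):
            if mask[i + j]:
                l_s += fr[j]
    l_total = float(mask.sum())
    return SiteCounts(l_n=l_total - l_s, l_s=l_s)


def count_sites_set(
    cds_set: Mapping[str, str],
    masks: Mapping[str, Sequence[bool]] | None = None,
) -> pd.DataFrame:
    """Site counts for a set of genes; DataFrame indexed by gene."""
    rows = {}
    for gene, cds in cds_set.items():
        mask = None if masks is None else masks.get(gene)
        sc = count_sites(cds, mask)
        rows[gene] = dict(l_n=sc.l_n, l_s=sc.l_s)
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# pi estimation
# ---------------------------------------------------------------------------

_EFFECTS = {"synonymous", "nonsynonymous"}


@dataclasses.dataclass
class SelectionResult:
    per_gene: pd.DataFrame  # pi_n, pi_s, ratio (NaN when pi_s == 0)
    summary: dict


def _site_heterozygosity(sub: pd.DataFrame) -> float:
    """Unbiased expected heterozygosity of one site (rows = alternate alleles)."""
    n = int(sub["n_chrom"].iloc[0])
    if (sub["n_chrom"] != n).any():
        raise ValueError("inconsistent chromosome count at one site")
    p_alt = sub["alt_count"].to_numpy(dtype=float) / n
    if (p_alt <= 0).any() or p_alt.sum() >= 1:
        raise ValueError("allele counts must satisfy 0 < count and sum < n")
    p_all = np.append(p_alt, 1 - p_alt.sum())
    return n / (n - 1) * (1 - np.sum(p_all**2))


def pi_per_gene(variants: pd.DataFrame, sites: pd.DataFrame) -> SelectionResult:
    """Estimate pi_N and pi_S per gene from an annotated variant table.

    ``variants`` needs columns gene, pos, effect, alt_count, n_chrom (one
    row per alternate allele); ``sites`` is indexed by gene with columns
    l_n, l_s. Every gene in ``sites`` is reported, with pi = 0 when it has
    no variants.
    """
    if len(variants):
        bad = set(variants["effect"]) - _EFFECTS
        if bad:
            raise ValueError(f"unknown effect classes: {bad}")
        orphan = set(variants["gene"]) - set(sites.index)
        if orphan:
            raise ValueError(f"variants for genes without site counts: {sorted(orphan)}")

    h_sum = pd.DataFrame(0.0, index=sites.index, columns=["synonymous", "nonsynonymous"])
    if len(variants):
        for (gene, pos, effect), sub in variants.groupby(["gene", "pos", "effect"]):
            h_sum.loc[gene, effect] += _site_heterozygosity(sub)

    with np.errstate(divide="ignore", invalid="ignore"):
        pi_s = np.where(sites["l_s"] > 0, h_sum["synonymous"] / sites["l_s"], 0.0)
        pi_n = np.where(sites["l_n"] > 0, h_sum["nonsynonymous"] / sites["l_n"], 0.0)
    per_gene = pd.DataFrame({"pi_n": pi_n, "pi_s": pi_s}, index=sites.index)
    per_gene["ratio"] = per_gene["pi_n"] / per_gene["pi_s"].where(per_gene["pi_s"] > 0)
    return SelectionResult(per_gene, summarize_pi(per_gene))


def summarize_pi(per_gene: pd.DataFrame) -> dict:
    """Genome-wide averages; headline ratio is the ratio of mean pi values."""
    mean_n = float(per_gene["pi_n"].mean())
    mean_s = float(per_gene["pi_s"].mean())
    defined = per_gene["ratio"].dropna()
    return {
        "mean_pi_n": mean_n,
        "mean_pi_s": mean_s,
        "ratio_of_means": mean_n / mean_s if mean_s > 0 else float("nan"),
        "mean_of_ratios": float(defined.mean()) if len(defined) else float("nan"),
        "n_genes": int(len(per_gene)),
        "n_genes_with_ratio": int(len(defined)),
    }


def compare_groups(
    result: SelectionResult, groupings: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Compare median pi_N/pi_S between gene groups.

    ``groupings`` maps a grouping name (e.g. "age_class") to a gene->label
    mapping. For every pair of labels within a grouping, a two-sided
    Wilcoxon rank-sum test is run on the defined per-gene ratios. Groups
    with fewer than two defined ratios are skipped with a warning.
    """
    ratios = result.per_gene["ratio"].dropna()
    records = []
    for name, mapping in groupings.items():
        labels = pd.Series(dict(mapping))
        groups = {}
        for label in sorted(set(labels)):
            members = ratios.reindex(labels.index[labels == label]).dropna()
            if len(members) < 2:
                warnings.warn(
                    f"grouping {name!r}: group {label!r} has "
                    f"{len(members)} genes with defined ratio; skipped"
                )
                continue
            groups[label] = members
        for a, b in zip(*np.triu_indices(len(groups), k=1)):
            la, lb = list(groups)[a], list(groups)[b]
            stat = stats.mannwhitneyu(groups[la], groups[lb], alternative="two-sided")
            records.append(
                dict(
                    grouping=name, group_a=la, group_b=lb,
                    n_a=len(groups[la]), n_b=len(groups[lb]),
                    median_a=float(groups[la].median()),
                    median_b=float(groups[lb].median()),
                    p_value=float(stat.pvalue),
                )
            )
    return pd.DataFrame.from_records(
        records,
        columns=["grouping", "group_a", "group_b", "n_a", "n_b",
                 "median_a", "median_b", "p_value"],
    )


def flag_positive_candidates(
    result: SelectionResult,
    de_calls: pd.DataFrame,
    universe: Sequence[str] | None = None,
    ratio_cutoff: float = 1.0,
    min_hits: int = 2,
    q_cutoff: float = 0.05,
) -> tuple[set[str], pd.DataFrame]:
    """Test whether high pi_N/pi_S genes concentrate in upregulated sets.

    Candidates are genes with a defined ratio >= ``ratio_cutoff``; each
    condition's upregulated gene set (from ``de_calls`` with columns gene,
    condition, direction) is tested for enrichment of candidates by the
    upper-tail hypergeometric test with BH correction.
    """
    from .enrichment import hypergeom_enrichment

    ratios = result.per_gene["ratio"].dropna()
    candidates = set(ratios.index[ratios >= ratio_cutoff])
    if universe is None:
        universe = list(ratios.index)
    if not candidates:
        return candidates, pd.DataFrame()
    up = de_calls[de_calls["direction"] == "up"]
    annotations = {
        cond: set(sub["gene"]) for cond, sub in up.groupby("condition")
    }
    table = hypergeom_enrichment(
        candidates, annotations, universe, min_hits=min_hits, q_cutoff=q_cutoff
    )
    return candidates, table
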