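"""Expression-atlas filters, hypergeometric family enrichment, pleiotropy
classification and expression divergence on family gene trees.

Filters follow the atlas conventions: a gene is *expressed* when it reaches
TPM >= 2 in at least one sample, and *retained* for differential-expression
work when it exceeds 1 count per million in at least three samples.
Enrichment of a gene set in an annotation (family) uses the upper-tail
hypergeometric probability P(X >= k) with Benjamini-Hochberg control over
all annotations tested in one run; a call additionally requires at least
two overlapping genes. A family is *pleiotropic* when it is enriched in
upregulated genes in seven or more conditions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "compute_tpm",
    "apply_expression_filters",
    "hypergeom_enrichment",
    "classify_pleiotropic",
    "expression_divergence",
    "divergence_by_family_size",
]

TPM_EXPRESSED = 2.0
CPM_RETAINED = 1.0
MIN_RETAINED_SAMPLES = 3
ENRICHMENT_Q = 0.05
ENRICHMENT_MIN_HITS = 2
PLEIOTROPY_MIN_CONDITIONS = 7
SPECIFIC_MAX_CONDITIONS = 2
DIVERGENCE_R_CUTOFF = 0.5
MIN_FAMILY_SIZE_FOR_DIVERGENCE = 4


@dataclasses.dataclass
class ExpressionMatrix:
    counts: pd.DataFrame            # genes x samples, raw counts
    tpm: pd.DataFrame               # genes x samples
    sample_condition: pd.Series     # sample -> condition
    gene_length: pd.Series | None = None
    expressed: pd.Series | None = None
    retained: pd.Series | None = None

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_condition))


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and gene lengths (bp)."""
    rate = counts.div(lengths, axis=0) * 1e3  # reads per kilobase
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.div(counts.sum(axis=0), axis=1) * 1e6


def apply_expression_filters(
    expr: ExpressionMatrix,
    tpm_min: float = TPM_EXPRESSED,
    cpm_min: float = CPM_RETAINED,
    min_samples: int = MIN_RETAINED_SAMPLES,
) -> ExpressionMatrix:
    """Attach expressed (TPM >= 2 anywhere) and retained (CPM > 1 in >= 3
    samples) flags."""
    expressed = (expr.tpm >= tpm_min).any(axis=1)
    retained = (cpm(expr.counts) > cpm_min).sum(axis=1) >= min_samples
    return dataclasses.replace(
        expr, expressed=expressed.rename("expressed"),
        retained=retained.rename("retained"),
    )


def hypergeom_enrichment(
    target: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_hits: int = ENRICHMENT_MIN_HITS,
    q_cutoff: float = ENRICHMENT_Q,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``target`` in each annotation.

    All gene sets are intersected with the universe. The p-value for an
    annotation of size K with overlap k is P(X >= k) where X is
    hypergeometric(M=|universe|, K, N=|target|); q-values are BH over all
    annotations in the call. ``enriched`` requires q < q_cutoff and
    k >= min_hits.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    target = set(target) & universe
    records = []
    for label in sorted(annotations):
        ann = set(annotations[label]) & universe
        k = len(ann & target)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(ann), len(target)))
        records.append(dict(label=label, overlap=k, annotation_size=len(ann),
                            target_size=len(target), universe_size=len(universe),
                            p_value=p))
    table = pd.DataFrame.from_records(
        records, columns=["label", "overlap", "annotation_size", "target_size",
                          "universe_size", "p_value"],
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["enriched"] = (table["q_value"] < q_cutoff) & (table["overlap"] >= min_hits)
    else:
        table["q_value"] = pd.Series(dtype=float)
        table["enriched"] = pd.Series(dtype=bool)
    return table


def classify_pleiotropic(
    enrichments: pd.DataFrame,
    min_conditions: int = PLEIOTROPY_MIN_CONDITIONS,
    max_specific: int = SPECIFIC_MAX_CONDITIONS,
    related_groups: Mapping[str, str] | None = None,
) -> pd.Series:
    """Classify families by the breadth of their upregulation enrichment.

    ``enrichments`` is tidy with columns family, condition, enriched. A
    family enriched in >= ``min_conditions`` conditions is *pleiotropic*;
    enriched in >= 1 but spanning at most ``max_specific`` related
    condition groups is *condition-specific*; anything else is *neither*.
    ``related_groups`` maps conditions to group labels (identity when not
    given).
    """
    hit = enrichments[enrichments["enriched"]]
    n_conditions = hit.groupby("family")["condition"].nunique()
    if related_groups is None:
        n_groups = n_conditions
    else:
        grouped = hit.assign(
            group=[related_groups.get(c, c) for c in hit["condition"]]
        )
        n_groups = grouped.groupby("family")["group"].nunique()
    classes = {}
    for family in sorted(set(enrichments["family"])):
        nc = int(n_conditions.get(family, 0))
        ng = int(n_groups.get(family, 0))
        if nc >= min_conditions:
            classes[family] = "pleiotropic"
        elif 1 <= ng <= max_specific:
            classes[family] = "condition-specific"
        else:
            classes[family] = "neither"
    return pd.Series(classes, name="class")


# ---------------------------------------------------------------------------
# expression divergence on family gene trees
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DivergenceProfile:
    per_node: pd.DataFrame  # node label, r, divergent
    percent_divergent: float  # NaN when no node evaluable / family too small
    n_evaluable: int
    family_size: int


def _condition_profile(
    genes: Sequence[str], expr: ExpressionMatrix, pseudocount: float
) -> np.ndarray | None:
    present = [g for g in genes if g in expr.tpm.index]
    if not present:
        return None
    logtpm = np.log2(expr.tpm.loc[present] + pseudocount)
    by_cond = logtpm.T.groupby(expr.sample_condition).mean()  # condition x gene
    return by_cond.mean(axis=1).to_numpy()


def expression_divergence(
    tree: dendropy.Tree | str,
    expr: ExpressionMatrix,
    r_cutoff: float = DIVERGENCE_R_CUTOFF,
    pseudocount: float = 1.0,
    min_family_size: int = MIN_FAMILY_SIZE_FOR_DIVERGENCE,
) -> DivergenceProfile:
    """Fraction of a family tree's internal nodes with diverged expression.

    For every internal node whose two child clades each contain at least
    one gene with expression data, the Pearson correlation between the two
    child-clade mean log2(TPM + pseudocount) condition profiles is
    computed; the node is *divergent* when r < ``r_cutoff``. Families with
    fewer than ``min_family_size`` genes are not evaluated (NaN percent).
    Profiles with zero variance give an undefined correlation and count as
    non-divergent.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", rooting="force-rooted")
    if not tree.is_rooted:
        raise ValueError("expression divergence requires a rooted family tree")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    family_size = len(leaves)
    records = []
    if family_size >= min_family_size:
        for idx, node in enumerate(tree.preorder_internal_node_iter()):
            children = node.child_nodes()
            if len(children) != 2:
                continue
            profiles = []
            for child in children:
                genes = [l.taxon.label for l in child.leaf_iter()]
                profiles.append(_condition_profile(genes, expr, pseudocount))
            if any(p is None for p in profiles):
                continue
            a, b = profiles
            if np.std(a) == 0 or np.std(b) == 0:
                r = float("nan")
                divergent = False
            else:
                r = float(stats.pearsonr(a, b).statistic)
                divergent = r < r_cutoff
            records.append(dict(node=f"n{idx}", r=r, divergent=divergent))
    per_node = pd.DataFrame.from_records(records, columns=["node", "r", "divergent"])
    n_eval = len(per_node)
    pct = 100 * per_node["divergent"].mean() if n_eval else float("nan")
    return DivergenceProfile(per_node, float(pct), n_eval, family_size)


def divergence_by_family_size(
    profiles: Mapping[str, DivergenceProfile], size_threshold: int
) -> dict:
    """Two-sided Wilcoxon rank-sum of divergence percentage, large vs small
    families (split at ``size_threshold`` members, inclusive for large)."""
    large, small = [], []
    for prof in profiles.values():
        if np.isnan(prof.percent_divergent):
            continue
        (large if prof.family_size >= size_threshold else small).append(
            prof.percent_divergent
        )
    if len(large) < 2 or len(small) < 2:
        return {"p_value": float("nan"), "median_large": float("nan"),
                "median_small": float("nan"), "n_large": len(large),
                "n_small": len(small)}
    res = stats.mannwhitneyu(large, small, alternative="two-sided")
    return {
        "p_value": float(res.pvalue),
        "median_large": float(np.median(large)),
        "median_small": float(np.median(small)),
        "n_large": len(large),
        "n_small": len(small),
    }
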