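"""Pan-genome presence/absence analysis across resequenced strains.

Presence of a reference (or de novo) gene in a strain is called from the
horizontal coverage of its exons by that strain's reads: a gene is absent
when less than 5% of its exonic bases are covered. Genes present in all
strains are *core*; genes present in at least 95% of strains but not all
are *softcore*; the rest of the non-core genes are plain *dispensable*.
Following the arithmetic used for the headline percentages, softcore genes
are reported as a labelled subset of the dispensable fraction, so the core
share of the pan genome ranges between ``core`` and ``core + softcore``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PresenceAbsenceMatrix",
    "PanClassification",
    "call_presence",
    "classify_pan_genes",
    "summarize_pan_counts",
    "accumulation_curves",
    "dedup_de_novo_genes",
    "cluster_strains",
    "absence_percentage",
]

PRESENCE_THRESHOLD = 0.05
SOFTCORE_FRACTION = 0.95


@dataclasses.dataclass
class PresenceAbsenceMatrix:
    coverage: pd.DataFrame        # genes x strains, fractions in [0, 1]
    presence: pd.DataFrame        # genes x strains, boolean
    clades: pd.Series | None = None   # strain -> clade label
    reference: str | None = None      # reference strain column, if any

    @property
    def strains(self) -> list[str]:
        return list(self.coverage.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.coverage.index)


def call_presence(
    coverage: pd.DataFrame,
    threshold: float = PRESENCE_THRESHOLD,
    clades: pd.Series | None = None,
    reference: str | None = None,
) -> PresenceAbsenceMatrix:
    """Threshold horizontal coverage into presence calls (present ⇔ >= 5%)."""
    values = coverage.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"coverage outside [0, 1] at gene {coverage.index[i]!r}, "
            f"strain {coverage.columns[j]!r}: {values[i, j]}"
        )
    presence = coverage >= threshold
    return PresenceAbsenceMatrix(coverage, presence, clades, reference)


def _softcore_min_strains(n_strains: int, fraction: float) -> int:
    # ceiling with a guard against float artefacts (0.95 * 60 != 57.0 exactly)
    return math.ceil(fraction * n_strains - 1e-9)


@dataclasses.dataclass
class PanClassification:
    classes: pd.Series  # gene -> {core, softcore, dispensable}
    summary: dict


def summarize_pan_counts(n_core: int, n_dispensable: int, n_softcore: int) -> dict:
    """Headline pan-genome arithmetic from class counts.

    ``n_dispensable`` is the full non-core fraction, of which ``n_softcore``
    genes are the softcore subset. Percentages follow the reporting
    convention: whole percents for core/dispensable and the core+softcore
    upper bound, one decimal for softcore.
    """
    pan = n_core + n_dispensable
    if n_softcore > n_dispensable:
        raise ValueError("softcore is a subset of the dispensable fraction")
    return {
        "pan_size": pan,
        "core_size": n_core,
        "dispensable_size": n_dispensable,
        "softcore_size": n_softcore,
        "core_pct": round(100 * n_core / pan),
        "dispensable_pct": round(100 * n_dispensable / pan),
        "softcore_pct": round(100 * n_softcore / pan, 1),
        "core_softcore_pct": round(100 * (n_core + n_softcore) / pan),
    }


def classify_pan_genes(
    pa: PresenceAbsenceMatrix, softcore_fraction: float = SOFTCORE_FRACTION
) -> PanClassification:
    """Partition pan genes into core / softcore / plain dispensable."""
    n = len(pa.strains)
    if n < 2:
        raise ValueError("pan-genome classification needs >= 2 strains")
    counts = pa.presence.sum(axis=1)
    min_soft = _softcore_min_strains(n, softcore_fraction)
    classes = pd.Series("dispensable", index=pa.presence.index, name="class")
    classes[counts >= min_soft] = "softcore"
    classes[counts == n] = "core"
    n_core = int((classes == "core").sum())
    n_soft = int((classes == "softcore").sum())
    n_disp = len(classes) - n_core  # softcore counts inside dispensable
    summary = summarize_pan_counts(n_core, n_disp, n_soft)
    summary["n_strains"] = n
    summary["softcore_min_strains"] = min_soft
    return PanClassification(classes, summary)


@dataclasses.dataclass
class AccumulationCurve:
    pan_traj: np.ndarray   # (n_permutations, n_strains) pan sizes
    core_traj: np.ndarray  # (n_permutations, n_strains) core sizes
    summary: pd.DataFrame  # per k: pan/core mean and sd
    seed: int


def accumulation_curves(
    pa: PresenceAbsenceMatrix, n_permutations: int = 100, seed: int = 0
) -> AccumulationCurve:
    """Pan and core genome size as strains are added in random orders."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if len(pa.strains) < 2:
        raise ValueError("accumulation needs >= 2 strains")
    rng = np.random.default_rng(seed)
    presence = pa.presence.to_numpy(dtype=bool)
    n_genes, n_strains = presence.shape
    pan = np.empty((n_permutations, n_strains), dtype=int)
    core = np.empty((n_permutations, n_strains), dtype=int)
    for p in range(n_permutations):
        order = rng.permutation(n_strains)
        acc_union = np.zeros(n_genes, dtype=bool)
        acc_inter = np.ones(n_genes, dtype=bool)
        for k, s in enumerate(order):
            acc_union |= presence[:, s]
            acc_inter &= presence[:, s]
            pan[p, k] = acc_union.sum()
            core[p, k] = acc_inter.sum()
    summary = pd.DataFrame(
        {
            "k": np.arange(1, n_strains + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_sd": pan.std(axis=0, ddof=0),
            "core_mean": core.mean(axis=0),
            "core_sd": core.std(axis=0, ddof=0),
        }
    ).set_index("k")
    return AccumulationCurve(pan, core, summary, seed)


def dedup_de_novo_genes(
    identities: pd.DataFrame | Iterable[tuple[str, str, float]],
    lengths: Mapping[str, float],
    threshold: float = 0.95,
) -> dict[str, list[str]]:
    """Greedy length-first clustering of de novo genes at >= 95% identity.

    Genes are visited in decreasing length order (ties broken by
    identifier); each gene joins the first existing cluster whose
    representative it matches at >= ``threshold`` identity, otherwise it
    founds its own cluster. Representatives are therefore always the
    longest member. Returns representative -> ordered member list
    (representative first).
    """
    if isinstance(identities, pd.DataFrame):
        rows = identities.itertuples(index=False)
    else:
        rows = identities
    ident: dict[frozenset, float] = {}
    genes: set[str] = set()
    for a, b, v in rows:
        if not 0 <= v <= 1:
            raise ValueError(f"identity outside [0, 1] for pair ({a}, {b}): {v}")
        ident[frozenset((a, b))] = float(v)
        genes.update((a, b))
    genes.update(lengths.keys())
    missing = [g for g in sorted(genes) if g not in lengths]
    if missing:
        raise ValueError(f"genes without length: {missing}")
    order = sorted(genes, key=lambda g: (-lengths[g], g))
    clusters: dict[str, list[str]] = {}
    for g in order:
        for rep in clusters:
            if ident.get(frozenset((rep, g)), 0.0) >= threshold:
                clusters[rep].append(g)
                break
        else:
            clusters[g] = [g]
    return clusters


def cluster_strains(
    pa: PresenceAbsenceMatrix, method: str = "average", metric: str = "euclidean"
):
    """Hierarchically cluster strains on their gene-coverage profiles.

    Returns ``(linkage, leaf_order)`` where ``leaf_order`` is the strain
    list in dendrogram order; strains with correlated gene loss (same
    clade) end up adjacent.
    """
    profiles = pa.coverage.to_numpy(dtype=float).T
    link = hierarchy.linkage(pdist(profiles, metric=metric), method=method)
    order = hierarchy.leaves_list(link)
    return link, [pa.strains[i] for i in order]


def absence_percentage(n_absent: int, n_total: int) -> float:
    """Percent of genes absent in >= 1 strain, to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100 * n_absent / n_total, 2)
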