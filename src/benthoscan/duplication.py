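"""Tandem, block (segmental) and dispersed duplicate classification.

Definitions, all operating on gene order (ranks) and family co-membership:

* A *tandem array* is a maximal set of same-family genes on one scaffold
  chained transitively through pairs at most ``tandem_gap`` ranks apart.
* A *collinear block* is a chain of at least ``min_anchors`` anchor pairs.
  An anchor pair is a pair of same-family genes on a (possibly identical)
  scaffold pair; consecutive anchors in a chain are separated by at most
  ``gap_size`` genes on both scaffolds and run in a consistent direction
  (same or inverted). Tandem arrays are collapsed to their lowest-rank
  member before anchors are enumerated so a single array cannot fabricate
  a block on its own. Chains closer than ``cluster_gap`` on both axes of
  the same scaffold pair are merged into one block.
* A multi-copy gene in no array and no block is a *dispersed* duplicate;
  genes whose family has a single member (or no family) are *single*.

Precedence for classification is tandem > block > dispersed.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import pandas as pd

from .catalog import GeneCatalog

__all__ = [
    "TandemArray",
    "CollinearBlock",
    "find_tandem_arrays",
    "find_collinear_blocks",
    "classify_duplicates",
]

DEFAULT_TANDEM_GAP = 15
DEFAULT_GAP_SIZE = 15
DEFAULT_CLUSTER_GAP = 15
DEFAULT_MIN_ANCHORS = 3


@dataclasses.dataclass(frozen=True)
class TandemArray:
    array_id: str
    scaffold: str
    family: str
    genes: tuple[str, ...]  # ordered by rank


@dataclasses.dataclass(frozen=True)
class CollinearBlock:
    block_id: str
    scaffold_a: str
    scaffold_b: str
    #: ordered (gene_on_a, gene_on_b) pairs, sorted by rank on scaffold_a
    anchors: tuple[tuple[str, str], ...]
    orientation: str  # "same" | "inverted"

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.anchors for g in pair}


def find_tandem_arrays(
    catalog: GeneCatalog, tandem_gap: int = DEFAULT_TANDEM_GAP
) -> list[TandemArray]:
    """Maximal same-scaffold, same-family rank runs with gaps <= tandem_gap."""
    if tandem_gap < 1:
        raise ValueError("tandem_gap must be >= 1")
    genes = catalog.genes.dropna(subset=["family"])
    arrays: list[TandemArray] = []
    for (scaffold, family), sub in genes.groupby(["scaffold", "family"], sort=False):
        sub = sub.sort_values("rank")
        run: list[tuple[int, str]] = []
        rows = list(zip(sub["rank"], sub["gene_id"])) + [(None, None)]
        for rank, gid in rows:
            if run and (rank is None or rank - run[-1][0] > tandem_gap):
                if len(run) >= 2:
                    arrays.append(
                        TandemArray("", scaffold, family,
                                    tuple(g for _, g in run))
                    )
                run = []
            if rank is not None:
                run.append((rank, gid))
    # deterministic ids: order by scaffold then first-member rank
    rank_of = dict(zip(catalog.genes["gene_id"], catalog.genes["rank"]))
    arrays.sort(key=lambda a: (a.scaffold, rank_of[a.genes[0]]))
    return [
        dataclasses.replace(a, array_id=f"T{i:04d}")
        for i, a in enumerate(arrays, 1)
    ]


# ---------------------------------------------------------------------------
# collinear blocks
# ---------------------------------------------------------------------------

def _anchor_pairs(catalog: GeneCatalog, arrays: Sequence[TandemArray]):
    """Enumerate anchor pairs per ordered scaffold pair, tandems collapsed.

    Returns {(scaffold_a, scaffold_b): [(rank_a, rank_b, gene_a, gene_b)]}
    with scaffold_a <= scaffold_b; for the self pair rank_a < rank_b.
    """
    rank_of = dict(zip(catalog.genes["gene_id"], catalog.genes["rank"]))
    in_array: dict[str, TandemArray] = {}
    for arr in arrays:
        for g in arr.genes:
            in_array[g] = arr
    # representatives: lowest-rank member of each array, all non-array genes
    reps = catalog.genes.dropna(subset=["family"]).copy()
    keep = []
    for row in reps.itertuples():
        arr = in_array.get(row.gene_id)
        keep.append(arr is None or arr.genes[0] == row.gene_id)
    reps = reps[keep]

    pairs: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for family, sub in reps.groupby("family", sort=False):
        members = list(sub.itertuples())
        for m1, m2 in itertools.combinations(members, 2):
            a, b = m1, m2
            if (a.scaffold, a.rank) > (b.scaffold, b.rank):
                a, b = b, a
            key = (a.scaffold, b.scaffold)
            pairs.setdefault(key, []).append(
                (a.rank, b.rank, a.gene_id, b.gene_id)
            )
    return pairs


def _maximal_chains(anchors, gap_size: int):
    """All maximal valid chains over one scaffold pair's anchors.

    A chain is a sequence of anchors strictly increasing on axis A with
    consecutive steps <= gap_size on both axes, axis B strictly monotone
    (increasing = "same", decreasing = "inverted"). Maximality is by anchor
    subset: chains contained in a longer valid chain are dropped.
    """
    anchors = sorted(set(anchors))
    n = len(anchors)
    chains: list[tuple[tuple, str]] = []
    for direction, name in ((1, "same"), (-1, "inverted")):
        def step_ok(u, v):
            da = v[0] - u[0]
            db = (v[1] - u[1]) * direction
            return 0 < da <= gap_size and 0 < db <= gap_size

        succ = [[j for j in range(n) if step_ok(anchors[i], anchors[j])]
                for i in range(n)]
        has_pred = [False] * n
        for i in range(n):
            for j in succ[i]:
                has_pred[j] = True

        def extend(path):
            last = path[-1]
            nxt = succ[last]
            if not nxt:
                chains.append((tuple(anchors[i] for i in path), name))
                return
            for j in nxt:
                extend(path + [j])

        for i in range(n):
            if not has_pred[i]:
                extend([i])
    # drop single-anchor "chains" and subset-dominated chains
    chains = [c for c in chains if len(c[0]) >= 2]
    sets = [frozenset(c[0]) for c in chains]
    keep = []
    for i, (chain, name) in enumerate(chains):
        dominated = any(
            i != j and sets[i] < sets[j] for j in range(len(chains))
        ) or any(
            i != j and sets[i] == sets[j] and j < i for j in range(len(chains))
        )
        if not dominated:
            keep.append((chain, name))
    return keep


def _merge_chains(chains, cluster_gap: int):
    """Merge same-orientation chains closer than cluster_gap on both axes."""
    def interval_dist(lo1, hi1, lo2, hi2):
        if hi1 < lo2:
            return lo2 - hi1
        if hi2 < lo1:
            return lo1 - hi2
        return 0

    chains = [list(c) for c in chains]
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(chains)), 2):
            (ai, ni), (aj, nj) = (chains[i][0], chains[i][1]), (chains[j][0], chains[j][1])
            if ni != nj:
                continue
            a_lo1, a_hi1 = min(x[0] for x in ai), max(x[0] for x in ai)
            a_lo2, a_hi2 = min(x[0] for x in aj), max(x[0] for x in aj)
            b_lo1, b_hi1 = min(x[1] for x in ai), max(x[1] for x in ai)
            b_lo2, b_hi2 = min(x[1] for x in aj), max(x[1] for x in aj)
            if (interval_dist(a_lo1, a_hi1, a_lo2, a_hi2) < cluster_gap
                    and interval_dist(b_lo1, b_hi1, b_lo2, b_hi2) < cluster_gap):
                union = tuple(sorted(set(ai) | set(aj)))
                chains[i] = [union, ni]
                del chains[j]
                merged = True
                break
    # deduplicate identical anchor sets that may arise after merging
    seen = set()
    out = []
    for anchors, name in chains:
        key = (frozenset(anchors), name)
        if key not in seen:
            seen.add(key)
            out.append((tuple(sorted(anchors)), name))
    return out


def find_collinear_blocks(
    catalog: GeneCatalog,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    gap_size: int = DEFAULT_GAP_SIZE,
    cluster_gap: int = DEFAULT_CLUSTER_GAP,
    arrays: Sequence[TandemArray] | None = None,
) -> list[CollinearBlock]:
    """Detect collinear blocks; ``arrays`` defaults to find_tandem_arrays."""
    if min_anchors < 2:
        raise ValueError("min_anchors must be >= 2")
    if arrays is None:
        arrays = find_tandem_arrays(catalog)
    blocks: list[CollinearBlock] = []
    for (sa, sb), anchors in sorted(_anchor_pairs(catalog, arrays).items()):
        raw = _maximal_chains(anchors, gap_size)
        raw = [c for c in raw if len(c[0]) >= min_anchors]
        for anchor_tuples, orientation in _merge_chains(raw, cluster_gap):
            pairs = tuple((ga, gb) for _, _, ga, gb in anchor_tuples)
            blocks.append(CollinearBlock("", sa, sb, pairs, orientation))
    blocks.sort(key=lambda b: (b.scaffold_a, b.scaffold_b, b.anchors))
    return [
        dataclasses.replace(b, block_id=f"B{i:04d}")
        for i, b in enumerate(blocks, 1)
    ]


def classify_duplicates(
    catalog: GeneCatalog,
    arrays: Sequence[TandemArray],
    blocks: Sequence[CollinearBlock],
) -> pd.DataFrame:
    """Assign every gene a duplicate type (single/tandem/block/dispersed).

    A gene in a tandem array is tandem even when it also anchors a block;
    block membership extends to every member of a collapsed array whose
    representative anchors the block only through that representative's own
    call, i.e. classification is per gene, not per array.
    """
    fam_sizes = catalog.family_sizes()
    in_array: dict[str, str] = {}
    for arr in arrays:
        for g in arr.genes:
            in_array[g] = arr.array_id
    in_blocks: dict[str, list[str]] = {}
    for blk in blocks:
        for g in blk.genes:
            in_blocks.setdefault(g, []).append(blk.block_id)

    records = []
    for row in catalog.genes.itertuples():
        fam = row.family
        multi = (not pd.isna(fam)) and fam_sizes.get(fam, 0) >= 2
        if not multi:
            dtype = "single"
        elif row.gene_id in in_array:
            dtype = "tandem"
        elif row.gene_id in in_blocks:
            dtype = "block"
        else:
            dtype = "dispersed"
        records.append(
            dict(
                gene_id=row.gene_id,
                type=dtype,
                array_id=in_array.get(row.gene_id),
                block_ids=",".join(in_blocks.get(row.gene_id, [])) or None,
            )
        )
    return pd.DataFrame.from_records(records).set_index("gene_id")
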