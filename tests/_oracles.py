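"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use the dumbest correct algorithm (pairwise graphs,
exhaustive subset enumeration, explicit haplotype pair counting, direct
combinatorial sums) and share no code with the package's detectors.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


# --- tandem arrays: transitive closure over a pairwise proximity graph ----

def oracle_tandem_arrays(genes, tandem_gap):
    """genes: iterable of (gene_id, scaffold, rank, family). Returns a set of
    frozensets of gene ids (arrays of >= 2 members)."""
    genes = [g for g in genes if g[3] is not None]
    adj = {g[0]: set() for g in genes}
    for a, b in itertools.combinations(genes, 2):
        if (a[1] == b[1] and a[3] == b[3]
                and abs(a[2] - b[2]) <= tandem_gap):
            adj[a[0]].add(b[0])
            adj[b[0]].add(a[0])
    seen, arrays = set(), set()
    for g in adj:
        if g in seen:
            continue
        stack, comp = [g], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        if len(comp) >= 2:
            arrays.add(frozenset(comp))
    return arrays


# --- collinear blocks: exhaustive subset enumeration ----------------------

def _valid_chain(subset, gap_size):
    """A subset of (rank_a, rank_b, gene_a, gene_b) anchors is a valid chain
    when, sorted on axis A, steps are <= gap_size on both axes, axis A is
    strictly increasing and axis B strictly monotone. Returns orientation
    or None."""
    chain = sorted(subset)
    directions = set()
    for u, v in itertools.pairwise(chain):
        da = v[0] - u[0]
        db = v[1] - u[1]
        if da <= 0 or da > gap_size or db == 0 or abs(db) > gap_size:
            return None
        directions.add(1 if db > 0 else -1)
    if len(directions) > 1:
        return None
    return "same" if directions == {1} else "inverted"


def oracle_collinear_blocks(genes, min_anchors, gap_size, cluster_gap,
                            tandem_gap, max_anchors_per_pair=18):
    """Exhaustive block detection. genes as in oracle_tandem_arrays.
    Returns a set of (scaffold_a, scaffold_b, frozenset(anchor gene pairs),
    orientation)."""
    arrays = oracle_tandem_arrays(genes, tandem_gap)
    rank = {g[0]: g[2] for g in genes}
    drop = set()
    for arr in arrays:
        rep = min(arr, key=lambda g: rank[g])
        drop |= arr - {rep}
    reps = [g for g in genes if g[3] is not None and g[0] not in drop]

    anchors_by_pair = {}
    by_family = {}
    for g in reps:
        by_family.setdefault(g[3], []).append(g)
    for members in by_family.values():
        for a, b in itertools.combinations(members, 2):
            if (a[1], a[2]) > (b[1], b[2]):
                a, b = b, a
            anchors_by_pair.setdefault((a[1], b[1]), set()).add(
                (a[2], b[2], a[0], b[0])
            )

    blocks = set()
    for (sa, sb), anchors in anchors_by_pair.items():
        anchors = sorted(anchors)
        if len(anchors) > max_anchors_per_pair:
            raise RuntimeError(
                f"oracle intractable: {len(anchors)} anchors on ({sa},{sb})"
            )
        valid = []
        for size in range(2, len(anchors) + 1):
            for subset in itertools.combinations(anchors, size):
                orientation = _valid_chain(subset, gap_size)
                if orientation is not None:
                    valid.append((frozenset(subset), orientation))
        maximal = [
            (s, o) for s, o in valid
            if not any(s < s2 for s2, _ in valid)
        ]
        chains = [(s, o) for s, o in set(maximal) if len(s) >= min_anchors]
        # merge same-orientation chains closer than cluster_gap on both axes
        def dist(lo1, hi1, lo2, hi2):
            if hi1 < lo2:
                return lo2 - hi1
            if hi2 < lo1:
                return lo1 - hi2
            return 0

        merged = True
        while merged:
            merged = False
            for i, j in itertools.combinations(range(len(chains)), 2):
                (si, oi), (sj, oj) = chains[i], chains[j]
                if oi != oj:
                    continue
                a1 = [x[0] for x in si]; b1 = [x[1] for x in si]
                a2 = [x[0] for x in sj]; b2 = [x[1] for x in sj]
                if (dist(min(a1), max(a1), min(a2), max(a2)) < cluster_gap
                        and dist(min(b1), max(b1), min(b2), max(b2)) < cluster_gap):
                    chains[i] = (si | sj, oi)
                    del chains[j]
                    merged = True
                    break
        for s, o in set(chains):
            pairs = frozenset((ga, gb) for _, _, ga, gb in s)
            blocks.add((sa, sb, pairs, o))
    return blocks


# --- expansion z-scores: direct summation ---------------------------------

def oracle_expansion(counts, focal_index, variance_cutoff=2.0, z_cutoff=3.0,
                     sd_floor=1.0):
    """counts: 1-D sequence of included-species copy counts. Returns
    (z, variance, expanded) computed by direct summation."""
    counts = [float(c) for c in counts]
    n = len(counts)
    mean_all = sum(counts) / n
    variance = sum((c - mean_all) ** 2 for c in counts) / n
    others = [c for i, c in enumerate(counts) if i != focal_index]
    m = sum(others) / len(others)
    sd = (sum((c - m) ** 2 for c in others) / len(others)) ** 0.5
    z = (counts[focal_index] - m) / max(sd, sd_floor)
    return z, variance, (variance > variance_cutoff and z > z_cutoff)


# --- hypergeometric tail: exact enumeration / combinatorial sum -----------

def oracle_hypergeom_upper(M, K, N, k):
    """P(X >= k) for overlap of a size-N draw with a size-K annotation in a
    size-M universe, by direct combinatorial summation."""
    total = comb(M, N)
    return sum(comb(K, x) * comb(M - K, N - x)
               for x in range(k, min(K, N) + 1)) / total


def oracle_hypergeom_enumerate(universe, annotation, target_size, k):
    """Same tail probability by literally enumerating all draws (|U| small)."""
    universe = sorted(universe)
    annotation = set(annotation)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, target_size):
        total += 1
        if len(annotation & set(draw)) >= k:
            hits += 1
    return hits / total


# --- pi: average pairwise haplotype differences ---------------------------

def oracle_pi_from_haplotypes(haplotypes, site_classes, l_n, l_s):
    """haplotypes: (n, L) array of alleles; site_classes: length-L array of
    "synonymous"/"nonsynonymous"/None. Returns (pi_n, pi_s) as mean
    per-pair difference counts over all C(n, 2) pairs divided by the class
    site totals."""
    H = np.asarray(haplotypes)
    n = H.shape[0]
    diff_n = diff_s = 0.0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        pairs += 1
        neq = H[i] != H[j]
        for pos in np.flatnonzero(neq):
            if site_classes[pos] == "synonymous":
                diff_s += 1
            elif site_classes[pos] == "nonsynonymous":
                diff_n += 1
    return diff_n / pairs / l_n, diff_s / pairs / l_s


# --- Nei-Gojobori site counts: enumerate all 9 changes per codon ----------

_CODE = {}


def _aa(codon):
    from Bio.Seq import Seq
    if codon not in _CODE:
        _CODE[codon] = str(Seq(codon).translate())
    return _CODE[codon]


def oracle_site_counts(cds):
    """(l_n, l_s) by brute-force enumeration of all single-base changes."""
    l_s = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = _aa(codon)
        for j in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[j]:
                    continue
                alt = codon[:j] + b + codon[j + 1:]
                if _aa(alt) != "*" and _aa(alt) == aa:
                    syn += 1
            l_s += syn / 3
    return len(cds) - l_s, l_s
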