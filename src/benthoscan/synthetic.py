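"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator draws from a single named :class:`numpy.random.Generator`
seeded explicitly — no global random state — and returns, next to the data
container, a :class:`SyntheticTruth` recording exactly what was planted so
recovery can be asserted.

What the generators emulate (and their fixed, documented defaults):

* gene catalogs with planted tandem arrays and collinear blocks on
  scaffolds of ordered gene models;
* a multi-species family copy-number matrix whose background counts are
  ``1 + Poisson(0.5)`` per family/species, with planted focal-species
  expansions;
* a strain presence/absence structure with clade-correlated gene loss and
  coverage noise (present genes 0.8-1.0, absent < 0.05);
* coding SNPs dosed to target synonymous/nonsynonymous diversity with
  allele frequencies from a Beta(1, 3) folded to the minor allele;
* clade-structured homolog presence with per-group presence probabilities;
* a condition-structured expression atlas with negative-binomial counts
  (gamma-Poisson, dispersion 0.1) and planted upregulation.

Gene CDS lengths default to 300-3000 nt in multiples of three so the
selection estimator sees valid codon framing.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import math
from dataclasses import field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .enrichment import ExpressionMatrix, compute_tpm
from .pangenome import PresenceAbsenceMatrix, call_presence, _softcore_min_strains
from .selection import CdsFrameError, codon_synonymous_fractions, validate_cds, _TABLE
from .signature import DEFAULT_CENSUS, HomologHitTable

__all__ = [
    "SyntheticTruth",
    "generate_gene_catalog",
    "generate_copy_matrix",
    "generate_strain_matrix",
    "generate_cds_set",
    "generate_variants",
    "generate_hit_table",
    "generate_expression",
]


@dataclasses.dataclass
class SyntheticTruth:
    expanded_family_ids: set[str] = field(default_factory=set)
    tandem_arrays: list[set[str]] = field(default_factory=list)
    block_pairs: list[list[tuple[str, str]]] = field(default_factory=list)
    gene_class: dict[str, str] = field(default_factory=dict)
    per_gene_pi: dict[str, tuple[float, float]] = field(default_factory=dict)
    clade_membership: dict[str, str] = field(default_factory=dict)
    de_truth: dict[tuple[str, str], str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene catalogs with planted tandem arrays and collinear blocks
# ---------------------------------------------------------------------------

def _draw_exons(rng: np.random.Generator, cursor: int) -> tuple[tuple, int]:
    n_exons = int(rng.integers(1, 4))
    cds_len = 3 * int(rng.integers(100, 1001))
    cuts = sorted(rng.choice(np.arange(1, cds_len // 3), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    pieces = np.diff([0, *[3 * c for c in cuts], cds_len])
    start = cursor + int(rng.integers(100, 1001))
    exons = []
    for piece in pieces:
        exons.append((start, start + int(piece) - 1))
        start = exons[-1][1] + int(rng.integers(50, 301)) + 1
    return tuple(exons), exons[-1][1]


def generate_gene_catalog(
    n_scaffolds: int,
    genes_per_scaffold: int,
    n_families: int,
    tandem_rate: float,
    block_rate: float,
    seed: int,
    tandem_gap: int = 15,
    gap_size: int = 15,
) -> tuple[GeneCatalog, SyntheticTruth]:
    """Ordered gene models with planted tandem arrays and collinear blocks.

    ``tandem_rate``/``block_rate`` are target fractions of genes belonging
    to planted arrays / planted block anchors. Background genes draw
    family labels from a pool of ``n_families`` labels; planted structures
    use dedicated fresh labels. The emitted catalog is scrubbed so that it
    contains *only* the planted structure: background label collisions that
    would form unplanned arrays or blocks are reassigned to singleton
    families.
    """
    if min(n_scaffolds, genes_per_scaffold, n_families) < 1:
        raise ValueError("counts must be >= 1")
    for name, rate in (("tandem_rate", tandem_rate), ("block_rate", block_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")

    rng = np.random.default_rng(seed)
    scaffolds = [f"scf{j:02d}" for j in range(n_scaffolds)]
    gene_id = {
        (s, r): f"g{j:02d}_{r:03d}"
        for j, s in enumerate(scaffolds)
        for r in range(genes_per_scaffold)
    }
    family = {key: None for key in gene_id}
    free = {s: list(range(genes_per_scaffold)) for s in scaffolds}
    truth = SyntheticTruth()
    total = n_scaffolds * genes_per_scaffold

    # --- plant tandem arrays ---------------------------------------------
    target_tandem = round(tandem_rate * total)
    planted = 0
    t_idx = 0
    while planted < target_tandem:
        s = scaffolds[int(rng.integers(n_scaffolds))]
        size = min(2 + int(rng.poisson(1.0)), len(free[s]))
        if size < 2:
            continue
        i = int(rng.integers(0, len(free[s]) - size + 1))
        ranks = free[s][i:i + size]
        if any(b - a > tandem_gap for a, b in itertools.pairwise(ranks)):
            continue
        fam = f"FT{t_idx:03d}"
        t_idx += 1
        for r in ranks:
            family[(s, r)] = fam
        free[s] = [r for r in free[s] if r not in set(ranks)]
        truth.tandem_arrays.append({gene_id[(s, r)] for r in ranks})
        planted += size

    # --- plant collinear blocks ------------------------------------------
    def take_run(s: str, size: int, forbid: set[int] | None = None) -> list[int] | None:
        ok = [r for r in free[s] if forbid is None
              or all(abs(r - f) > tandem_gap for f in forbid)]
        for start in rng.permutation(max(len(ok) - size + 1, 0)):
            ranks = ok[start:start + size]
            if all(b - a <= gap_size for a, b in itertools.pairwise(ranks)):
                return ranks
        return None

    target_block = round(block_rate * total)
    planted = 0
    b_idx = 0
    attempts = 0
    while planted < target_block and attempts < 50:
        attempts += 1
        size = 3 + int(rng.poisson(1.0))
        if n_scaffolds >= 2:
            sa, sb = rng.choice(n_scaffolds, size=2, replace=False)
            sa, sb = scaffolds[int(sa)], scaffolds[int(sb)]
            run_a = take_run(sa, size)
            if run_a is None:
                continue
            run_b = take_run(sb, size)
        else:
            sa = sb = scaffolds[0]
            run_a = take_run(sa, size)
            if run_a is None:
                continue
            run_b = take_run(sb, size, forbid=set(run_a))
        if run_b is None:
            continue
        inverted = bool(rng.random() < 0.5)
        partner = list(reversed(run_b)) if inverted else run_b
        pairs = []
        for ra, rb in zip(run_a, partner):
            fam = f"FB{b_idx:03d}"
            b_idx += 1
            family[(sa, ra)] = fam
            family[(sb, rb)] = fam
            pairs.append((gene_id[(sa, ra)], gene_id[(sb, rb)]))
        free[sa] = [r for r in free[sa] if r not in set(run_a)]
        free[sb] = [r for r in free[sb] if r not in set(run_b)]
        truth.block_pairs.append(pairs)
        planted += 2 * size

    # --- background labels, then scrub unplanned structure ----------------
    pool = [f"F{j:04d}" for j in range(n_families)]
    for s in scaffolds:
        for r in free[s]:
            family[(s, r)] = pool[int(rng.integers(n_families))]

    def build() -> GeneCatalog:
        records = []
        for j, s in enumerate(scaffolds):
            cursor = 0
            for r in range(genes_per_scaffold):
                exons, cursor = _draw_exons(np.random.default_rng(seed * 1000003 + j * 1009 + r), cursor)
                records.append(dict(
                    gene_id=gene_id[(s, r)], scaffold=s, rank=r,
                    strand="+" if rng.random() < 0.5 else "-",
                    family=family[(s, r)], exons=exons,
                ))
        return GeneCatalog(pd.DataFrame.from_records(records))

    from .duplication import find_collinear_blocks, find_tandem_arrays

    planted_genes = set().union(*truth.tandem_arrays) if truth.tandem_arrays else set()
    for pairs in truth.block_pairs:
        planted_genes.update(g for p in pairs for g in p)
    singleton = itertools.count()
    catalog = build()
    for _ in range(30):
        dirty = set()
        arrays = find_tandem_arrays(catalog, tandem_gap)
        for arr in arrays:
            genes = set(arr.genes)
            if genes not in truth.tandem_arrays:
                dirty.update(genes - planted_genes)
        for blk in find_collinear_blocks(catalog, gap_size=gap_size, arrays=arrays):
            planted_sets = [set(itertools.chain.from_iterable(p)) for p in truth.block_pairs]
            if not any(blk.genes <= ps for ps in planted_sets):
                dirty.update(blk.genes - planted_genes)
        if not dirty:
            break
        for g in sorted(dirty):
            key = next(k for k, v in gene_id.items() if v == g)
            family[key] = f"FS{next(singleton):04d}"
        catalog = build()
    return catalog, truth


# ---------------------------------------------------------------------------
# copy-number matrices with planted expansions
# ---------------------------------------------------------------------------

def generate_copy_matrix(
    n_species: int,
    n_families: int,
    expansion_fraction: float,
    expansion_multiplier: float,
    seed: int,
    focal: str | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Families x species copy counts with planted focal-species expansions.

    Background counts are ``1 + Poisson(0.5)``; a planted family has its
    focal count multiplied by ``expansion_multiplier`` (rounded up). The
    focal species is the first column unless named.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3 (Z score undefined otherwise)")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0 <= expansion_fraction <= 1:
        raise ValueError("expansion_fraction must be in [0, 1]")
    if expansion_multiplier < 3:
        raise ValueError("expansion_multiplier must be >= 3")
    rng = np.random.default_rng(seed)
    species = [f"species_{i:02d}" for i in range(n_species)]
    if focal is None:
        focal = species[0]
    elif focal not in species:
        species[0] = focal
    families = [f"F{i:04d}" for i in range(n_families)]
    counts = 1 + rng.poisson(0.5, size=(n_families, n_species))
    matrix = pd.DataFrame(counts, index=families, columns=species)
    truth = SyntheticTruth()
    n_planted = round(expansion_fraction * n_families)
    if n_planted:
        chosen = rng.choice(n_families, size=n_planted, replace=False)
        for i in chosen:
            matrix.iloc[i, matrix.columns.get_loc(focal)] = math.ceil(
                matrix.iloc[i, matrix.columns.get_loc(focal)] * expansion_multiplier
            )
            truth.expanded_family_ids.add(families[i])
    return matrix, truth


# ---------------------------------------------------------------------------
# strain presence/absence with clade-correlated loss
# ---------------------------------------------------------------------------

def generate_strain_matrix(
    n_strains: int,
    n_genes: int,
    core_fraction: float,
    softcore_fraction: float,
    clade_sizes: Sequence[int],
    seed: int,
) -> tuple[PresenceAbsenceMatrix, SyntheticTruth]:
    """Coverage matrix over strains with planted core/softcore/dispensable.

    Strain 0 is the reference (coverage 1.0 for every gene). Core genes
    are covered 0.8-1.0 in all strains; softcore genes are absent
    (coverage < 0.05) in a number of strains small enough to stay at or
    above the 95% presence bound; plain dispensable genes are absent in a
    clade-correlated subset large enough to fall below it.
    """
    if n_strains < 2 or n_genes < 1:
        raise ValueError("need >= 2 strains and >= 1 gene")
    if core_fraction < 0 or softcore_fraction < 0 or core_fraction + softcore_fraction > 1:
        raise ValueError("class fractions must be >= 0 and sum to <= 1")
    if sum(clade_sizes) != n_strains:
        raise ValueError(
            f"clade_sizes sums to {sum(clade_sizes)}, expected {n_strains}"
        )
    rng = np.random.default_rng(seed)
    strains = [f"strain_{i:02d}" for i in range(n_strains)]
    reference = strains[0]
    clades = {}
    labels = [f"clade_{chr(65 + i)}" for i in range(len(clade_sizes))]
    pos = 0
    for label, size in zip(labels, clade_sizes):
        for s in strains[pos:pos + size]:
            clades[s] = label
        pos += size

    n_core = round(core_fraction * n_genes)
    n_soft = round(softcore_fraction * n_genes)
    min_soft_present = _softcore_min_strains(n_strains, 0.95)
    max_soft_absent = n_strains - min_soft_present
    if n_soft and max_soft_absent < 1:
        raise ValueError(
            f"softcore band empty at {n_strains} strains (95% bound = all)"
        )
    genes = [f"g{i:04d}" for i in range(n_genes)]
    coverage = rng.uniform(0.8, 1.0, size=(n_genes, n_strains))
    truth = SyntheticTruth(clade_membership=dict(clades))
    non_ref = np.arange(1, n_strains)
    clade_of = np.array([clades[s] for s in strains])
    for i, g in enumerate(genes):
        if i < n_core:
            truth.gene_class[g] = "core"
        elif i < n_core + n_soft:
            truth.gene_class[g] = "softcore"
            a = int(rng.integers(1, max_soft_absent + 1))
            absent = rng.choice(non_ref, size=a, replace=False)
            coverage[i, absent] = rng.uniform(0.0, 0.0499, size=a)
        else:
            truth.gene_class[g] = "dispensable"
            min_absent = max_soft_absent + 1
            order = rng.permutation(len(labels))
            for li in order:
                members = np.array(
                    [j for j in non_ref if clade_of[j] == labels[li]]
                )
                if len(members) >= min_absent:
                    break
            else:
                members = non_ref
            a = int(rng.integers(min_absent, len(members) + 1))
            absent = rng.choice(members, size=a, replace=False)
            coverage[i, absent] = rng.uniform(0.0, 0.0499, size=a)
    coverage[:, 0] = 1.0  # reference strain carries every reference gene
    df = pd.DataFrame(coverage, index=genes, columns=strains)
    pa = call_presence(df, clades=pd.Series(clades), reference=reference)
    return pa, truth


# ---------------------------------------------------------------------------
# coding sequences and dosed variants
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(_TABLE.forward_table)


def generate_cds_set(
    n_genes: int, seed: int, min_codons: int = 100, max_codons: int = 1000
) -> dict[str, str]:
    """Random stop-free CDS sequences, lengths 300-3000 nt (multiples of 3)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_genes):
        n_codons = int(rng.integers(min_codons, max_codons + 1))
        idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        out[f"g{i:04d}"] = "".join(_SENSE_CODONS[j] for j in idx)
    return out


@functools.lru_cache(maxsize=None)
def _expected_site_heterozygosity(n_chromosomes: int) -> float:
    """Mean unbiased heterozygosity of one planted SNP under the default
    allele-frequency model (Beta(1, 3) folded to the minor allele, rounded
    to counts). Monte Carlo with a fixed internal stream."""
    rng = np.random.default_rng(987654321)
    p = rng.beta(1.0, 3.0, size=200_000)
    p = np.minimum(p, 1 - p)
    a = np.clip(np.rint(p * n_chromosomes), 1, n_chromosomes - 1)
    pe = a / n_chromosomes
    h = n_chromosomes / (n_chromosomes - 1) * 2 * pe * (1 - pe)
    return float(h.mean())


def _position_alternates(codon: str, i: int) -> tuple[list[str], list[str]]:
    """(synonymous alts, nonsynonymous alts) for position i of a codon."""
    aa = _TABLE.forward_table[codon]
    syn, non = [], []
    for b in "ACGT":
        if b == codon[i]:
            continue
        alt_aa = _TABLE.forward_table.get(codon[:i] + b + codon[i + 1:])
        (syn if alt_aa == aa else non).append(b)
    return syn, non


def generate_variants(
    cds_set: Mapping[str, str],
    n_chromosomes: int,
    target_pi_s: float,
    target_pi_n: float,
    seed: int,
) -> pd.DataFrame:
    """Coding SNPs dosed so the estimator recovers the target diversities.

    A position carries a synonymous SNP with probability proportional to
    its fractional synonymous site content (and likewise nonsynonymous),
    scaled so that the expected per-gene pi_S / pi_N under the
    frequency-based estimator equal the targets. Allele frequencies are
    Beta(1, 3) folded to the minor allele.
    """
    if n_chromosomes < 2:
        raise ValueError("pi needs >= 2 chromosomes")
    if target_pi_s < 0 or target_pi_n < 0:
        raise ValueError("target diversities must be >= 0")
    rng = np.random.default_rng(seed)
    h_bar = _expected_site_heterozygosity(n_chromosomes)
    lam_s = target_pi_s / h_bar
    lam_n = target_pi_n / h_bar
    if lam_s > 1 or lam_n > 1:
        raise ValueError("target diversity too high for per-site dosing")
    rows = []
    for gene in sorted(cds_set):
        cds = validate_cds(cds_set[gene])
        for c0 in range(0, len(cds), 3):
            codon = cds[c0:c0 + 3]
            fr = codon_synonymous_fractions(codon)
            for i in range(3):
                p_syn = lam_s * fr[i]
                p_non = lam_n * (1 - fr[i])
                u = rng.random()
                if u < p_syn:
                    effect = "synonymous"
                    alts = _position_alternates(codon, i)[0]
                elif u < p_syn + p_non:
                    effect = "nonsynonymous"
                    alts = _position_alternates(codon, i)[1]
                else:
                    continue
                if not alts:
                    continue
                alt = alts[int(rng.integers(len(alts)))]
                p = rng.beta(1.0, 3.0)
                p = min(p, 1 - p)
                a = int(np.clip(round(p * n_chromosomes), 1, n_chromosomes - 1))
                rows.append(dict(
                    gene=gene, pos=c0 + i + 1, ref=codon[i], alt=alt,
                    effect=effect, alt_count=a, n_chrom=n_chromosomes,
                ))
    return pd.DataFrame.from_records(
        rows, columns=["gene", "pos", "ref", "alt", "effect", "alt_count", "n_chrom"]
    )


# ---------------------------------------------------------------------------
# clade-structured homolog hit tables
# ---------------------------------------------------------------------------

_PROB_PRIORITY = ["benthic", "planktonic", "raphid", "araphid", "pennate",
                  "centric", "default"]


def _build_species_panel(census: Mapping[str, int]) -> pd.DataFrame:
    n_raphid = census["raphid"]
    n_araphid = census["araphid"]
    n_pennate = census["pennate"]
    n_centric = census["centric"]
    if n_raphid + n_araphid > n_pennate:
        raise ValueError("raphid + araphid cannot exceed pennate census")
    rows = []
    for i in range(n_pennate):
        raphe = ("raphid" if i < n_raphid
                 else "araphid" if i < n_raphid + n_araphid else "unlabeled")
        rows.append(dict(symmetry="pennate", raphe=raphe))
    for _ in range(n_centric):
        rows.append(dict(symmetry="centric", raphe="unlabeled"))
    n_total = len(rows)
    n_benthic, n_plankt = census["benthic"], census["planktonic"]
    if n_benthic + n_plankt > n_total:
        raise ValueError("benthic + planktonic cannot exceed total species")
    # benthic species sit among the raphid pennates; planktonic fill from
    # the end of the panel (centrics first), the remainder stays unlabeled
    habitat = ["unlabeled"] * n_total
    for i in range(n_benthic):
        habitat[i] = "benthic"
    j = n_total - 1
    placed = 0
    while placed < n_plankt:
        if habitat[j] == "unlabeled":
            habitat[j] = "planktonic"
            placed += 1
        j -= 1
    df = pd.DataFrame(rows)
    df["habitat"] = habitat
    df.index = [f"sp{i:03d}" for i in range(n_total)]
    return df


def generate_hit_table(
    n_genes: int,
    clade_census: Mapping[str, int] | None = None,
    presence_probs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    group_sizes: Mapping[str, int] | None = None,
) -> tuple[HomologHitTable, pd.Series]:
    """Binary homolog hits per gene x species with clade-structured presence.

    ``presence_probs`` maps gene-group -> {clade or "default": probability};
    a species takes the probability of its most specific labelled clade
    (benthic/planktonic before raphid/araphid before pennate/centric),
    falling back to the group's "default" entry (0.5 when absent). Genes
    are split across groups evenly unless ``group_sizes`` says otherwise.
    Returns the hit table and the gene -> group assignment.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    census = dict(DEFAULT_CENSUS if clade_census is None else clade_census)
    if presence_probs is None:
        presence_probs = {"background": {"default": 0.5}}
    for group, probs in presence_probs.items():
        for clade, p in probs.items():
            if not 0 <= p <= 1:
                raise ValueError(
                    f"presence probability for ({group}, {clade}) outside "
                    f"[0, 1]: {p}"
                )
    panel = _build_species_panel(census)
    groups = sorted(presence_probs)
    if group_sizes is None:
        base = n_genes // len(groups)
        sizes = {g: base for g in groups}
        sizes[groups[-1]] += n_genes - base * len(groups)
    else:
        sizes = dict(group_sizes)
        if sum(sizes.values()) != n_genes:
            raise ValueError("group_sizes must sum to n_genes")
    gene_group = {}
    i = 0
    for g in groups:
        for _ in range(sizes[g]):
            gene_group[f"g{i:04d}"] = g
            i += 1

    rng = np.random.default_rng(seed)
    labels = {
        sp: {row.symmetry, row.raphe, row.habitat}
        for sp, row in panel.iterrows()
    }
    prob_matrix = np.empty((n_genes, len(panel)))
    genes = sorted(gene_group)
    for gi, gene in enumerate(genes):
        probs = presence_probs[gene_group[gene]]
        for si, sp in enumerate(panel.index):
            p = probs.get("default", 0.5)
            for clade in _PROB_PRIORITY[:-1]:
                if clade in labels[sp] and clade in probs:
                    p = probs[clade]
                    break
            prob_matrix[gi, si] = p
    hits = pd.DataFrame(
        rng.random(prob_matrix.shape) < prob_matrix,
        index=genes, columns=panel.index,
    )
    table = HomologHitTable(hits, panel, census=census)
    return table, pd.Series(gene_group, name="group")


# ---------------------------------------------------------------------------
# condition-structured expression with planted upregulation
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int,
    condition_design: Mapping[str, int],
    planted_up: Mapping[tuple[str, str], float],
    seed: int,
    genes_per_family: int = 8,
    dispersion: float = 0.1,
    background_de_rate: float = 0.0,
    lfc_call_threshold: float = 1.0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Expression atlas with planted family-level upregulation.

    Counts are gamma-Poisson (negative binomial, dispersion 0.1) around
    per-gene log-normal baselines; planted (family, condition) effects are
    log2 fold changes applied to every member gene. The differential-call
    table is produced by thresholding the *true* effects at
    |log2 FC| > 1 — no model fitting — with a nominal adjusted p-value.
    Genes belong to families of ``genes_per_family`` consecutive genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for cond, reps in condition_design.items():
        if reps < 1:
            raise ValueError(f"condition {cond!r} has replicate count {reps}")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    families = {g: f"F{i // genes_per_family:03d}" for i, g in enumerate(genes)}
    lengths = pd.Series(3 * rng.integers(100, 1001, size=n_genes), index=genes)
    baseline = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)

    truth = SyntheticTruth()
    lfc = pd.DataFrame(0.0, index=genes, columns=sorted(condition_design))
    for (family, cond), effect in planted_up.items():
        members = [g for g in genes if families[g] == family]
        if not members:
            raise ValueError(f"planted family {family!r} has no genes")
        if cond not in lfc.columns:
            raise ValueError(f"planted condition {cond!r} not in design")
        lfc.loc[members, cond] = effect
        direction = "up" if effect > 0 else "down"
        for g in members:
            truth.de_truth[(g, cond)] = direction
    if background_de_rate > 0:
        mask = rng.random(lfc.shape) < background_de_rate
        signs = np.where(rng.random(lfc.shape) < 0.5, 1.0, -1.0)
        lfc = lfc.where(~(mask & (lfc == 0.0)), 1.5 * signs)

    samples, sample_cond = [], {}
    for cond in sorted(condition_design):
        for r in range(condition_design[cond]):
            name = f"{cond}_r{r + 1}"
            samples.append(name)
            sample_cond[name] = cond
    means = np.empty((n_genes, len(samples)))
    for si, sample in enumerate(samples):
        means[:, si] = baseline * 2.0 ** lfc[sample_cond[sample]].to_numpy()
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, means * dispersion)
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=samples)
    tpm = compute_tpm(counts, lengths)
    expr = ExpressionMatrix(counts, tpm, pd.Series(sample_cond), lengths)

    call_rows = []
    for cond in lfc.columns:
        called = lfc.index[lfc[cond].abs() > lfc_call_threshold]
        for g in called:
            call_rows.append(dict(
                gene=g, condition=cond,
                direction="up" if lfc.loc[g, cond] > 0 else "down",
                log2fc=float(lfc.loc[g, cond]), adj_p=1e-4,
            ))
    de_calls = pd.DataFrame.from_records(
        call_rows, columns=["gene", "condition", "direction", "log2fc", "adj_p"]
    )
    truth.gene_class = {}  # unused here
    return expr, de_calls, truth
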