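"""Gene-family expansion detection and phylostratification.

Expansion calling works on a families x species copy-number matrix. For a
focal species the copy count is standardised against the *other* included
species (leave-one-out): with the focal count inside the mean/sd, a single
species outlier can never exceed a Z of sqrt(n - 1) under a population sd,
so the conventional ``Z > 3`` criterion would be unreachable for
species-specific expansions in a ~9-species panel. A family is called
expanded in the focal species when the population variance of the full
included profile exceeds 2 and the leave-one-out Z exceeds 3; the sd in the
denominator is floored at one copy so that flat backgrounds (sd = 0) do not
produce infinite scores.

Phylostratification assigns each family the most recent taxonomy stratum
that still covers every species carrying at least one copy.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "detect_expansions",
    "assign_age_classes",
    "gene_ages",
    "read_copy_matrix",
    "read_taxonomy_tsv",
]

#: sd floor, in copies, used when the non-focal species have zero spread
SD_FLOOR = 1.0


def detect_expansions(
    matrix: pd.DataFrame,
    focal: str,
    excluded: Iterable[str] = (),
    variance_cutoff: float = 2.0,
    z_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Call families expanded in ``focal``.

    Parameters
    ----------
    matrix
        Families (rows) x species (columns) non-negative integer copy counts.
        A missing species/family combination must be encoded as 0.
    focal
        Species whose expansions are called.
    excluded
        Species dropped from the comparison altogether (e.g. an allodiploid
        whose doubled counts would distort the profile).

    Returns
    -------
    DataFrame indexed by family with columns ``z``, ``variance``,
    ``expanded``.
    """
    excluded = set(excluded)
    if focal in excluded:
        raise ValueError(f"focal species {focal!r} cannot be excluded")
    if focal not in matrix.columns:
        raise ValueError(f"focal species {focal!r} absent from matrix")
    include = [s for s in matrix.columns if s not in excluded]
    if len(include) < 3:
        raise ValueError(
            f"need >= 3 included species for a Z score, got {len(include)}"
        )
    if (matrix[include] < 0).any().any():
        raise ValueError("copy counts must be non-negative")

    sub = matrix[include].astype(float)
    variance = sub.var(axis=1, ddof=0)  # population variance, focal included
    others = sub.drop(columns=[focal])
    mean_o = others.mean(axis=1)
    sd_o = others.std(axis=1, ddof=0)
    z = (sub[focal] - mean_o) / np.maximum(sd_o, SD_FLOOR)
    expanded = (variance > variance_cutoff) & (z > z_cutoff)
    return pd.DataFrame({"z": z, "variance": variance, "expanded": expanded})


def assign_age_classes(
    matrix: pd.DataFrame,
    taxonomy: Mapping[str, Sequence[str]],
) -> pd.Series:
    """Assign each family the deepest taxonomy stratum covering all carriers.

    ``taxonomy`` maps every species to its root-to-leaf lineage path, e.g.
    ``["Eukaryota", "Stramenopiles", "Bacillariophyta", "Seminavis_robusta"]``.
    The family age class is the last element of the longest common prefix of
    the lineages of species with count >= 1; a family present in exactly one
    species therefore gets that species' own (leaf) stratum, i.e. is
    species-specific.
    """
    missing = [s for s in matrix.columns if s not in taxonomy]
    if missing:
        raise ValueError(f"species without taxonomy mapping: {missing}")
    ages = {}
    for family, row in matrix.iterrows():
        carriers = [s for s in matrix.columns if row[s] >= 1]
        if not carriers:
            ages[family] = pd.NA
            continue
        paths = [list(taxonomy[s]) for s in carriers]
        prefix = paths[0]
        for p in paths[1:]:
            n = 0
            while n < min(len(prefix), len(p)) and prefix[n] == p[n]:
                n += 1
            prefix = prefix[:n]
        if not prefix:
            raise ValueError(
                f"family {family}: species lineages share no root stratum"
            )
        ages[family] = prefix[-1]
    return pd.Series(ages, name="age_class")


def gene_ages(gene_families: Mapping[str, str], family_ages: pd.Series) -> pd.Series:
    """Propagate family age classes to genes (gene -> age class)."""
    return pd.Series(
        {g: family_ages.get(f, pd.NA) for g, f in gene_families.items()},
        name="age_class",
    )


def read_copy_matrix(path) -> pd.DataFrame:
    """Read a families-by-species copy-number TSV (first column = family)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_taxonomy_tsv(path) -> dict[str, list[str]]:
    """Read species taxonomy as TSV: species <tab> semicolon-joined lineage."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species", "lineage"])
    return {r.species: r.lineage.split(";") for r in df.itertuples()}
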