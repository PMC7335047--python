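"""Ordered gene models with family assignments.

The :class:`GeneCatalog` is the shared substrate for duplicate typing and
collinearity detection: genes live on scaffolds at dense 0-based integer
ranks (their position in the scaffold's gene order), carry a strand, an
optional gene-family label, and 1-based inclusive exon spans following the
GFF3 convention.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["GeneCatalog", "read_family_tsv"]

_COLUMNS = ["gene_id", "scaffold", "rank", "strand", "family", "exons"]


@dataclasses.dataclass
class GeneCatalog:
    """Per-gene records: identifier, scaffold, rank, strand, family, exons.

    ``genes`` is a DataFrame with columns ``gene_id``, ``scaffold``,
    ``rank``, ``strand``, ``family`` (may be NA for genes without a family)
    and ``exons`` (tuple of ``(start, end)`` 1-based inclusive spans,
    sorted and non-overlapping).
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        self.genes = self.genes.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene identifier: {dup}")
        for scaffold, sub in g.groupby("scaffold", sort=False):
            ranks = sorted(sub["rank"])
            if ranks != list(range(len(ranks))):
                raise ValueError(
                    f"ranks on scaffold {scaffold} are not dense 0-based: {ranks}"
                )
        bad_strand = set(g["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValueError(f"invalid strand values: {bad_strand}")
        for gene_id, exons in zip(g["gene_id"], g["exons"]):
            prev_end = 0
            for start, end in exons:
                if start <= prev_end or end < start:
                    raise ValueError(
                        f"gene {gene_id}: exon spans must be sorted, "
                        f"non-overlapping, 1-based: {exons}"
                    )
                prev_end = end

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    @property
    def scaffolds(self) -> list[str]:
        return list(dict.fromkeys(self.genes["scaffold"]))

    def family_of(self) -> pd.Series:
        """gene_id -> family (NA preserved)."""
        return self.genes.set_index("gene_id")["family"]

    def family_sizes(self) -> pd.Series:
        """Member count per family, genes without a family excluded."""
        return self.genes["family"].dropna().value_counts()

    def scaffold_genes(self, scaffold: str) -> pd.DataFrame:
        sub = self.genes[self.genes["scaffold"] == scaffold]
        return sub.sort_values("rank").reset_index(drop=True)

    # -- GFF3 round trip ---------------------------------------------------

    def to_gff3(self, path) -> None:
        """Write gene/mRNA/exon/CDS features (CDS identical to exons)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.genes.sort_values(["scaffold", "rank"]).itertuples():
                start = row.exons[0][0]
                end = row.exons[-1][1]
                gid = row.gene_id
                attrs = f"ID={gid}"
                if not pd.isna(row.family):
                    attrs += f";family={row.family}"
                fh.write(
                    f"{row.scaffold}\tbenthoscan\tgene\t{start}\t{end}\t.\t"
                    f"{row.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{row.scaffold}\tbenthoscan\tmRNA\t{start}\t{end}\t.\t"
                    f"{row.strand}\t.\tID={gid}.1;Parent={gid}\n"
                )
                for i, (s, e) in enumerate(row.exons, 1):
                    fh.write(
                        f"{row.scaffold}\tbenthoscan\texon\t{s}\t{e}\t.\t"
                        f"{row.strand}\t.\tID={gid}.1.exon{i};Parent={gid}.1\n"
                    )
                    fh.write(
                        f"{row.scaffold}\tbenthoscan\tCDS\t{s}\t{e}\t.\t"
                        f"{row.strand}\t0\tID={gid}.1.cds;Parent={gid}.1\n"
                    )

    @classmethod
    def from_gff3(cls, path, families: Mapping[str, str] | None = None) -> "GeneCatalog":
        """Build a catalog from a GFF3 file, ranking genes by start per scaffold.

        ``families`` maps gene identifiers to family labels; genes absent
        from the mapping get no family.
        """
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        records = []
        for gene in db.features_of_type("gene"):
            gid = gene.attributes.get("ID", [gene.id])[0]
            exons = sorted(
                (f.start, f.end)
                for f in db.children(gene, featuretype="exon")
            )
            if not exons:
                exons = [(gene.start, gene.end)]
            fam = None
            if families is not None:
                fam = families.get(gid)
            elif "family" in gene.attributes:
                fam = gene.attributes["family"][0]
            records.append(
                dict(gene_id=gid, scaffold=gene.seqid, rank=-1,
                     strand=gene.strand, family=fam, exons=tuple(exons))
            )
        df = pd.DataFrame.from_records(records)
        df["start"] = [ex[0][0] for ex in df["exons"]]
        df = df.sort_values(["scaffold", "start"]).drop(columns="start")
        df["rank"] = df.groupby("scaffold").cumcount()
        return cls(df.reset_index(drop=True))


def read_family_tsv(path) -> dict[str, str]:
    """Read a two-column gene->family TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "family"],
                     dtype=str, comment="#")
    if df["gene"].iloc[0] == "gene":  # tolerate a header line
        df = df.iloc[1:]
    return dict(zip(df["gene"], df["family"]))
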