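"""Readers and writers for the text formats the pipeline consumes.

TSV tables go through pandas; FASTA through Biopython; GFF3 writing lives
on :class:`~benthoscan.catalog.GeneCatalog`. Variant tables travel either
as a simplified TSV (gene, pos, ref, alt, effect, alt_count, n_chrom) or
as a minimal VCF dialect whose INFO field carries ``EFF`` (effect class
against the spliced CDS), ``AC`` and ``AN``; the CHROM column holds the
gene identifier and POS the 1-based position within the spliced CDS.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_variants_tsv",
    "read_variants_tsv",
]

_VARIANT_COLUMNS = ["gene", "pos", "ref", "alt", "effect", "alt_count", "n_chrom"]


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants[_VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    return df[_VARIANT_COLUMNS]


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=EFF,Number=1,Type=String,'
                 'Description="Coding effect class">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,'
                 'Description="Alternate allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,'
                 'Description="Called chromosome count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in variants.itertuples():
            info = f"EFF={row.effect};AC={row.alt_count};AN={row.n_chrom}"
            fh.write(f"{row.gene}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n")


def read_variants_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            rows.append(dict(
                gene=chrom, pos=int(pos), ref=ref, alt=alt,
                effect=fields["EFF"], alt_count=int(fields["AC"]),
                n_chrom=int(fields["AN"]),
            ))
    return pd.DataFrame.from_records(rows, columns=_VARIANT_COLUMNS)
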