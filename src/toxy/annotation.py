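"""Genome annotation containers: chromosomes, genes and TE intervals.

All coordinates are 0-based half-open internally.  BED output keeps that
convention; GFF3 output converts to the standard's 1-based closed
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

CHROM_CLASSES = ("autosome", "X", "Y")

GENE_COLUMNS = ["name", "chrom", "start", "end", "strand", "tss", "zygotic"]
TE_COLUMNS = ["chrom", "start", "end", "family", "strand"]


def empty_genes() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        GENE_COLUMNS, [str, str, int, int, str, int, bool])})


def empty_tes() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TE_COLUMNS, [str, int, int, str, str])})


@dataclass
class ChromosomeMap:
    """Feature -> chromosome assignment plus chromosome -> class labels."""

    feature_chrom: Mapping[str, str]
    chrom_class: Mapping[str, str]

    def feature_class_of(self, feature: str) -> str | None:
        chrom = self.feature_chrom.get(feature)
        if chrom is None:
            return None
        return self.chrom_class[chrom]

    def autosomal_features(self, features) -> list[str]:
        return [f for f in features if self.feature_class_of(f) == "autosome"]


@dataclass
class GenomeAnnotation:
    """Chromosome table, gene intervals and TE insertion intervals.

    ``chromosomes``: columns name, length, chrom_class.
    ``genes``: columns name, chrom, start, end, strand, tss, zygotic.
    ``tes``: columns chrom, start, end, family, strand.
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=empty_genes)
    tes: pd.DataFrame = field(default_factory=empty_tes)

    def __post_init__(self) -> None:
        self.chromosomes = self.chromosomes.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)
        self.tes = self.tes.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        bad = set(self.chromosomes["chrom_class"]) - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes: {sorted(bad)}")
        if (self.chromosomes["length"] <= 0).any():
            raise ValueError("chromosome lengths must be positive")
        lengths = self.chrom_lengths()
        for df, label in ((self.genes, "gene"), (self.tes, "TE")):
            if len(df) == 0:
                continue
            if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
                raise ValueError(f"{label} intervals must satisfy 0 <= start < end")
            limit = df["chrom"].map(lengths)
            if limit.isna().any():
                missing = sorted(set(df.loc[limit.isna(), "chrom"]))
                raise ValueError(f"{label} intervals on unknown chromosomes: {missing}")
            if (df["end"] > limit).any():
                raise ValueError(f"{label} intervals extend past chromosome end")
        if len(self.genes):
            plus = self.genes["strand"] == "+"
            tss_ok = np.where(plus, self.genes["tss"] == self.genes["start"],
                              self.genes["tss"] == self.genes["end"] - 1)
            if not tss_ok.all():
                raise ValueError("TSS must be the strand-appropriate gene end")

    # -- accessors ---------------------------------------------------------
    def chrom_lengths(self) -> pd.Series:
        return self.chromosomes.set_index("name")["length"]

    def chrom_classes(self) -> pd.Series:
        return self.chromosomes.set_index("name")["chrom_class"]

    def zygotic_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["zygotic"]].reset_index(drop=True)

    def chrom_map(self, features: pd.Series | None = None) -> ChromosomeMap:
        """ChromosomeMap for normalization: gene name -> chromosome.

        TE consensus families have no single chromosome; only genes are
        mapped unless ``features`` supplies extra assignments.
        """
        feature_chrom = dict(zip(self.genes["name"], self.genes["chrom"]))
        if features is not None:
            feature_chrom.update(features.to_dict())
        return ChromosomeMap(feature_chrom, self.chrom_classes().to_dict())

    # -- serialization -----------------------------------------------------
    def write_te_bed(self, path) -> None:
        df = self.tes
        out = pd.DataFrame({
            "chrom": df["chrom"], "start": df["start"], "end": df["end"],
            "name": df["family"], "score": 0, "strand": df["strand"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)

    def write_gene_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, chrom in self.chromosomes.iterrows():
                fh.write(f"##sequence-region {chrom['name']} 1 {chrom['length']}\n")
            for g in self.genes.itertuples():
                attrs = f"ID={g.name};zygotic={'1' if g.zygotic else '0'}"
                fh.write("\t".join([
                    g.chrom, "toxy", "gene", str(g.start + 1), str(g.end),
                    ".", g.strand, ".", attrs,
                ]) + "\n")

    def write_chrom_table(self, path) -> None:
        self.chromosomes.to_csv(path, sep="\t", index=False)


def read_te_bed(path) -> pd.DataFrame:
    """Read a TE annotation BED (chrom, start, end, family, score, strand)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "family", "score", "strand"],
                     dtype={"chrom": str, "family": str})
    return df[TE_COLUMNS]


def read_gene_gff3(path) -> pd.DataFrame:
    """Read gene intervals from a GFF3 file into the internal gene frame."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = \
                line.rstrip("\n").split("\t")
            if ftype != "gene":
                continue
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            start0, end0 = int(start) - 1, int(end)
            rows.append({
                "name": fields.get("ID", f"{chrom}:{start}"),
                "chrom": chrom, "start": start0, "end": end0, "strand": strand,
                "tss": start0 if strand == "+" else end0 - 1,
                "zygotic": fields.get("zygotic", "0") == "1",
            })
    if not rows:
        return empty_genes()
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def read_chrom_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"name": str, "chrom_class": str})
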