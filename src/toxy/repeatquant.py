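"""TE and gene expression quantification, normalization and sex comparisons.

The normalization chain follows the study design for sexed embryo
libraries: raw per-feature tallies are divided by each library's median
autosomal gene count (so that sex-chromosome expression cannot distort the
normalizer), a pseudocount is added before log transformation, and TE
expression can further be divided by sex-matched DNA-seq abundance to
correct for copy number.  Y-enriched TE families are classified from
male/female DNA-seq abundance ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from toxy._stats import rank_sum_test
from toxy.annotation import ChromosomeMap
from toxy.samples import SampleMeta

logger = logging.getLogger(__name__)

#: one-way normalization states, in order
STATES = ("raw", "autosomal_median", "autosomal_median+pseudocount", "copy_number")


class NormalizationError(ValueError):
    pass


@dataclass
class FeatureCountTable:
    """Per-feature, per-sample read counts with a normalization state flag.

    ``counts`` is features x samples; ``feature_class`` tags each row as
    ``"gene"`` or ``"TE"``; ``state`` is one of :data:`STATES` and only ever
    advances.
    """

    counts: pd.DataFrame
    feature_class: pd.Series | str = "TE"
    state: str = "raw"

    def __post_init__(self) -> None:
        if isinstance(self.feature_class, str):
            self.feature_class = pd.Series(self.feature_class,
                                           index=self.counts.index)
        self.feature_class = self.feature_class.reindex(self.counts.index)
        if self.state not in STATES:
            raise ValueError(f"unknown normalization state {self.state!r}")
        vals = self.counts.to_numpy(dtype=float)
        if (vals[np.isfinite(vals)] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, feature_class: str) -> "FeatureCountTable":
        keep = self.feature_class == feature_class
        return FeatureCountTable(self.counts.loc[keep],
                                 self.feature_class.loc[keep], self.state)

    def advance_state(self, new_state: str) -> str:
        if STATES.index(new_state) <= STATES.index(self.state):
            raise NormalizationError(
                f"normalization state may only advance ({self.state!r} -> {new_state!r})")
        return new_state

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "feature_class", self.feature_class)
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, state: str = "raw") -> "FeatureCountTable":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        fclass = df.pop("feature_class")
        return cls(df, fclass, state)


# ---------------------------------------------------------------------------
# counting

def count_features(alignments_by_sample: Mapping[str, pd.DataFrame],
                   features: Sequence[str],
                   feature_class: str | pd.Series = "TE",
                   primary_only: bool = True) -> FeatureCountTable:
    """Tally alignment records per target feature per sample.

    ``alignments_by_sample`` maps sample id to an alignment frame (columns
    qname, mate, ref, ...; an optional boolean ``is_primary`` column marks
    primary records).  Features missing from a sample's records are counted
    0 with a warning; an empty alignment frame yields an all-zero column.
    """
    features = list(features)
    counts = pd.DataFrame(0, index=pd.Index(features, name="feature"),
                          columns=list(alignments_by_sample), dtype=int)
    for sid, alns in alignments_by_sample.items():
        if len(alns) == 0:
            logger.warning("sample %s: empty alignment set, all-zero counts", sid)
            continue
        if primary_only and "is_primary" in alns.columns:
            alns = alns[alns["is_primary"]]
        tally = alns["ref"].value_counts()
        unseen = [f for f in features if f not in tally.index]
        if unseen:
            logger.warning("sample %s: %d features with no alignments", sid, len(unseen))
        counts[sid] = tally.reindex(features).fillna(0).astype(int)
    return FeatureCountTable(counts, feature_class, "raw")


# ---------------------------------------------------------------------------
# normalization

def autosomal_median(genes: FeatureCountTable, chrom_map: ChromosomeMap) -> pd.Series:
    """Per-sample median raw count over autosomal genes."""
    gene_rows = genes.counts.loc[genes.feature_class == "gene"] \
        if (genes.feature_class == "gene").any() else genes.counts
    auto = [f for f in gene_rows.index if chrom_map.feature_class_of(f) == "autosome"]
    if not auto:
        raise NormalizationError("no autosomal genes available for normalization")
    return gene_rows.loc[auto].median(axis=0)


def normalize_autosomal_median(raw: FeatureCountTable, genes: FeatureCountTable,
                               chrom_map: ChromosomeMap, pseudocount: float = 1.0,
                               pseudocount_genes_only: bool = False,
                               ) -> FeatureCountTable:
    """Divide each sample by its median autosomal gene count, then add a
    pseudocount to every normalized value.

    ``genes`` supplies the raw gene counts defining the normalizer (it may
    be the same table as ``raw``).  With ``pseudocount_genes_only`` the
    pseudocount is restricted to gene rows.
    """
    if raw.state != "raw":
        raise NormalizationError("input must be in state 'raw'")
    med = autosomal_median(genes, chrom_map)
    med = med.reindex(raw.samples)
    if med.isna().any():
        missing = list(med.index[med.isna()])
        raise NormalizationError(f"no gene counts for samples {missing}")
    zero = med[med == 0]
    if len(zero):
        raise NormalizationError(
            f"median autosomal count is 0 in sample(s) {list(zero.index)}")
    values = raw.counts.div(med, axis=1)
    if pseudocount_genes_only:
        is_gene = (raw.feature_class == "gene").to_numpy()
        values.loc[is_gene] = values.loc[is_gene] + pseudocount
        state = "autosomal_median"
    else:
        values = values + pseudocount
        state = "autosomal_median+pseudocount"
    if pseudocount == 0:
        state = "autosomal_median"
    return FeatureCountTable(values, raw.feature_class.copy(), state)


def copy_number_normalize(rna: FeatureCountTable, dna: FeatureCountTable,
                          rna_design: Sequence[SampleMeta],
                          dna_design: Sequence[SampleMeta]) -> FeatureCountTable:
    """Divide TE expression by sex-matched DNA-seq abundance (copy number).

    For each RNA sample, the normalizer is the mean of the (already
    normalized) DNA values over DNA samples of the same sex.  TEs with DNA
    value 0 become missing (NaN), not 0.
    """
    if rna.state == "raw" or dna.state == "raw":
        raise NormalizationError("both tables must be normalized before "
                                 "copy-number normalization")
    shared = rna.counts.index.intersection(dna.counts.index)
    if shared.empty:
        raise NormalizationError("rna and dna tables share no features")
    sex_of = {s.sample_id: s.sex for s in dna_design}
    dna_by_sex = {}
    for sex in ("female", "male"):
        cols = [c for c in dna.samples if sex_of.get(c) == sex]
        if not cols:
            raise NormalizationError(f"no {sex} DNA sample available")
        dna_by_sex[sex] = dna.counts.loc[shared, cols].mean(axis=1)

    rna_sex = {s.sample_id: s.sex for s in rna_design}
    values = pd.DataFrame(index=shared, columns=rna.samples, dtype=float)
    for col in rna.samples:
        denom = dna_by_sex[rna_sex[col]]
        zero = denom == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} TEs with DNA abundance 0: "
                          "copy-number values undefined (NaN)")
        values[col] = rna.counts.loc[shared, col] / denom.where(~zero)
    return FeatureCountTable(values, rna.feature_class.reindex(shared),
                             "copy_number")


# ---------------------------------------------------------------------------
# sex comparisons

def _stage_sex_columns(design: Sequence[SampleMeta], stage: int,
                       columns: Sequence[str]) -> dict[str, list[str]]:
    cols = {"female": [], "male": []}
    for s in design:
        if s.stage == stage and s.sample_id in columns:
            cols[s.sex].append(s.sample_id)
    for sex, cc in cols.items():
        if not cc:
            raise ValueError(f"no {sex} replicates at stage {stage}")
    return cols


def sex_fold_difference(table: FeatureCountTable, design: Sequence[SampleMeta],
                        stage: int) -> pd.Series:
    """Per-feature log2(mean male / mean female) at one stage.

    Computed on normalized (pseudocounted) values; replicates are averaged
    arithmetically before the ratio.
    """
    cols = _stage_sex_columns(design, stage, table.samples)
    male = table.counts[cols["male"]].mean(axis=1)
    female = table.counts[cols["female"]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return pd.Series(np.log2(male / female), index=table.counts.index,
                         name=f"log2_male_over_female_stage{stage}")


def compare_sexes_wilcoxon(table: FeatureCountTable, design: Sequence[SampleMeta],
                           stage: int, method: str = "auto") -> tuple[float, float]:
    """Two-tailed rank-sum test of male vs female per-feature abundance.

    Each group's vector holds one value per feature: the mean of the
    normalized values over that sex's replicates at the stage.  No
    multiple-testing correction is applied (one test per stage).
    """
    cols = _stage_sex_columns(design, stage, table.samples)
    male = table.counts[cols["male"]].mean(axis=1).to_numpy()
    female = table.counts[cols["female"]].mean(axis=1).to_numpy()
    return rank_sum_test(male, female, method=method)


# ---------------------------------------------------------------------------
# correlation / clustering

def correlation_cluster(table: FeatureCountTable, linkage_method: str = "complete",
                        ) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Sample-sample Pearson correlation of log2 values plus a
    deterministic agglomerative clustering leaf order.

    Returns ``(correlation, leaf_order, linkage_matrix)``.  Distance is
    1 - Pearson r; linkage defaults to complete.
    """
    vals = np.log2(table.counts.to_numpy(dtype=float))
    if not np.isfinite(vals).all():
        raise ValueError("log2 transform requires strictly positive values "
                         "(normalize with a pseudocount first)")
    corr = pd.DataFrame(np.corrcoef(vals.T), index=table.samples,
                        columns=table.samples)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    if len(table.samples) < 2:
        return corr, list(table.samples), np.empty((0, 4))
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = [table.samples[i] for i in hierarchy.leaves_list(Z)]
    return corr, order, Z


# ---------------------------------------------------------------------------
# Y-enrichment classification

@dataclass
class YEnrichment:
    """Per-TE male/female DNA abundance ratios and the resulting partition."""

    table: pd.DataFrame  # columns: male, female, ratio, y_enriched
    threshold: float

    @property
    def y_enriched(self) -> set[str]:
        return set(self.table.index[self.table["y_enriched"]])

    @property
    def remaining(self) -> set[str]:
        return set(self.table.index[~self.table["y_enriched"]])


def classify_y_enriched(dna: FeatureCountTable, design: Sequence[SampleMeta],
                        threshold: float = 2.0) -> YEnrichment:
    """Partition TE families by male/female DNA-seq abundance ratio.

    A family is Y-enriched iff male abundance / female abundance >=
    ``threshold`` (default twofold, boundary inclusive).  Female abundance 0
    with male abundance > 0 classifies as Y-enriched with an infinite ratio.
    """
    sex_of = {s.sample_id: s.sex for s in design}
    male_cols = [c for c in dna.samples if sex_of.get(c) == "male"]
    female_cols = [c for c in dna.samples if sex_of.get(c) == "female"]
    if not male_cols or not female_cols:
        raise ValueError("need at least one male and one female DNA sample")
    male = dna.counts[male_cols].mean(axis=1)
    female = dna.counts[female_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = male / female
    ratio = ratio.where(~((female == 0) & (male > 0)), np.inf)
    enriched = ratio >= threshold
    enriched = enriched.where(~((female == 0) & (male == 0)), False)
    out = pd.DataFrame({"male": male, "female": female, "ratio": ratio,
                        "y_enriched": enriched.astype(bool)})
    return YEnrichment(out, threshold)
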