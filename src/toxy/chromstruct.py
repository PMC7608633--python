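"""Interval analyses relating enrichment, genes and TE insertions.

These operations characterize how heterochromatin and transposons are
arranged around genes on a repeat-rich chromosome: window-level enrichment
split by gene overlap, median per-bp meta-profiles around TSSs or TE
midpoints, gene-to-nearest-TE distances, counts of insertions near
zygotically expressed genes, and the regression of those counts on TE
expression.  All coordinates are 0-based half-open; overlap is any-overlap
on half-open intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from toxy._stats import pearson_with_p, rank_sum_test
from toxy.annotation import GenomeAnnotation
from toxy.chipnorm import EnrichmentTrack, PerBaseTrack


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in intervals.itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


# ---------------------------------------------------------------------------
# window classes

def window_gene_classes(track: EnrichmentTrack, annotation: GenomeAnnotation,
                        chromosome: str | None = None,
                        ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify windows by gene overlap and compare enrichment between
    classes.

    Returns ``(windows, pvalues)`` where ``windows`` adds boolean columns
    ``overlaps_gene`` and ``overlaps_zygotic`` (nested classes: zygotic
    implies gene), and ``pvalues`` holds two-tailed rank-sum p-values for
    all-vs-gene, all-vs-zygotic and gene-vs-zygotic on defined windows.
    Empty classes are skipped with a warning.
    """
    win = track.windows.copy()
    if chromosome is not None:
        win = win[win["chrom"] == chromosome].reset_index(drop=True)
    gene_trees = _trees(annotation.genes)
    zyg_trees = _trees(annotation.zygotic_genes())
    win["overlaps_gene"] = [
        bool(gene_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end))
        for r in win.itertuples()]
    win["overlaps_zygotic"] = [
        bool(zyg_trees.get(r.chrom, IntervalTree()).overlap(r.start, r.end))
        for r in win.itertuples()]
    # nesting by construction: a zygotic gene is a gene
    win.loc[win["overlaps_zygotic"], "overlaps_gene"] = True

    ok = win["value"].notna()
    groups = {
        "all": win.loc[ok, "value"],
        "gene": win.loc[ok & win["overlaps_gene"], "value"],
        "zygotic": win.loc[ok & win["overlaps_zygotic"], "value"],
    }
    pvalues: dict[str, float] = {}
    for a, b in (("all", "gene"), ("all", "zygotic"), ("gene", "zygotic")):
        if len(groups[a]) == 0 or len(groups[b]) == 0:
            warnings.warn(f"window class {a if len(groups[a]) == 0 else b} "
                          "is empty; comparison skipped")
            continue
        _, p = rank_sum_test(groups[a], groups[b])
        pvalues[f"{a}_vs_{b}"] = p
    return win, pvalues


# ---------------------------------------------------------------------------
# meta-profiles

@dataclass
class MetaProfile:
    """Median per-bp value at each position within +/- flank of an anchor."""

    positions: np.ndarray  # -flank .. +flank
    values: np.ndarray     # median across anchors, NaN where no anchor covers
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "median": self.values})


def metaprofile(track: PerBaseTrack, anchors: pd.DataFrame, flank: int = 5000,
                oriented: bool = True) -> MetaProfile:
    """Median per-bp enrichment around anchors.

    ``anchors`` has columns chrom, pos and optionally strand.  With
    ``oriented`` (the TSS convention) minus-strand anchors are flipped so
    that negative positions are upstream of the gene; TE-midpoint profiles
    pass ``oriented=False``.  Anchors truncated by chromosome ends
    contribute missing values at out-of-range positions.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    width = 2 * flank + 1
    mat = np.full((len(anchors), width), np.nan)
    for i, a in enumerate(anchors.itertuples()):
        arr = track[a.chrom]
        lo = max(0, a.pos - flank)
        hi = min(arr.size, a.pos + flank + 1)
        if hi > lo:
            mat[i, lo - (a.pos - flank):hi - (a.pos - flank)] = arr[lo:hi]
        if oriented and getattr(a, "strand", "+") == "-":
            mat[i] = mat[i, ::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med = np.nanmedian(mat, axis=0)
    return MetaProfile(np.arange(-flank, flank + 1), med, len(anchors))


def tss_anchors(annotation: GenomeAnnotation, subset: pd.DataFrame | None = None,
                ) -> pd.DataFrame:
    genes = subset if subset is not None else annotation.genes
    return pd.DataFrame({"chrom": genes["chrom"], "pos": genes["tss"],
                         "strand": genes["strand"]})


def te_midpoint_anchors(annotation: GenomeAnnotation,
                        subset: pd.DataFrame | None = None) -> pd.DataFrame:
    tes = subset if subset is not None else annotation.tes
    return pd.DataFrame({"chrom": tes["chrom"],
                         "pos": (tes["start"] + tes["end"]) // 2})


# ---------------------------------------------------------------------------
# distances

def _interval_gap(astart, aend, bstart, bend) -> int:
    """Gap in bp between closest edges of two half-open intervals (0 if
    they overlap or touch base-adjacent)."""
    if astart < bend and bstart < aend:
        return 0
    return max(bstart - aend, astart - bend)


def _nearest_gap(starts: np.ndarray, ends: np.ndarray, qstart: int, qend: int,
                 ) -> int:
    """Nearest gap from query to any of the sorted, disjoint intervals."""
    i = np.searchsorted(starts, qend)
    best = None
    for j in (i - 1, i):
        if 0 <= j < starts.size:
            g = _interval_gap(qstart, qend, int(starts[j]), int(ends[j]))
            best = g if best is None else min(best, g)
    # overlap can involve an interval starting before qend but ending after
    # qstart anywhere to the left; intervals are disjoint and sorted, so
    # checking the neighbour on each side suffices
    return best if best is not None else -1


def gene_te_distances(annotation: GenomeAnnotation,
                      genes: pd.DataFrame | None = None,
                      chromosome: str | None = None) -> pd.DataFrame:
    """Per-gene distance in bp to the nearest TE (0 when a TE overlaps the
    gene) and whether the gene has an internal insertion.

    Genes on chromosomes without any TE get a missing distance.  Returns a
    frame with columns gene, chrom, distance, internal_te.
    """
    gdf = genes if genes is not None else annotation.genes
    if chromosome is not None:
        gdf = gdf[gdf["chrom"] == chromosome]
    by_chrom = {}
    for chrom, grp in annotation.tes.groupby("chrom"):
        s = grp.sort_values("start")
        by_chrom[chrom] = (s["start"].to_numpy(), s["end"].to_numpy())
    rows = []
    for g in gdf.itertuples():
        if g.chrom not in by_chrom:
            rows.append((g.name, g.chrom, np.nan, False))
            continue
        starts, ends = by_chrom[g.chrom]
        d = _nearest_gap(starts, ends, g.start, g.end)
        rows.append((g.name, g.chrom, float(d), d == 0))
    return pd.DataFrame(rows, columns=["gene", "chrom", "distance", "internal_te"])


def internal_insertion_fraction(distances: pd.DataFrame) -> float:
    """Fraction of genes (with a defined distance) having an internal TE."""
    ok = distances["distance"].notna()
    if not ok.any():
        return float("nan")
    return float(distances.loc[ok, "internal_te"].mean())


def insertions_near_genes(annotation: GenomeAnnotation, genes: pd.DataFrame,
                          flank: int = 5000) -> pd.Series:
    """Count, per TE family, insertions lying within ``flank`` bp of (or
    inside) any of the given genes.

    The boundary is inclusive: an insertion exactly ``flank`` bp away
    qualifies; one at ``flank + 1`` does not.  Each TE placement counts
    once toward its family.
    """
    by_chrom = {}
    for chrom, grp in genes.groupby("chrom"):
        s = grp.sort_values("start")
        by_chrom[chrom] = (s["start"].to_numpy(), s["end"].to_numpy())
    counts: dict[str, int] = {f: 0 for f in annotation.tes["family"].unique()}
    for t in annotation.tes.itertuples():
        if t.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[t.chrom]
        gaps = np.maximum(np.maximum(starts - t.end, t.start - ends), 0)
        if (gaps <= flank).any():
            counts[t.family] += 1
    return pd.Series(counts, name="n_near").sort_index()


# ---------------------------------------------------------------------------
# regression

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    pvalue: float
    n: int


def regress_family_counts_vs_expression(family_counts: pd.Series,
                                        expression: pd.Series) -> RegressionResult:
    """OLS of per-family insertion counts on an expression measure, with
    the Pearson correlation and its two-sided p-value.

    The two series are aligned on family id; families missing from either
    side are dropped.
    """
    df = pd.concat({"x": expression, "y": family_counts}, axis=1).dropna()
    if len(df) < 2:
        raise ValueError("need at least two families with both values")
    x, y = df["x"].to_numpy(dtype=float), df["y"].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return RegressionResult(0.0, float(y.mean()), 0.0, 1.0, len(df))
    res = stats.linregress(x, y)
    r, p = pearson_with_p(x, y)
    return RegressionResult(float(res.slope), float(res.intercept), r, p, len(df))
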