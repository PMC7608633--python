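"""Window-level H3K9me3 enrichment and spike-in quantile normalization.

Enrichment in a genomic window is the depth-normalized ChIP read count over
the depth-normalized input read count, each library normalized by its
median autosomal per-bp coverage:

    (ChIP reads / median autosomal ChIP coverage)
    ---------------------------------------------
    (input reads / median autosomal input coverage)

Because every library carries the same spike-in chromatin, systematic
differences between libraries' spike-in enrichment distributions reflect
antibody pulldown efficiency.  A reference distribution (the average
spike-in enrichment across libraries, sorted) defines a quantile-matching
correction for each library's spike-in values; the same value-to-value
correction is then transferred to the library's sample windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "start", "end", "value"]


@dataclass
class EnrichmentTrack:
    """Tiled, non-overlapping windows with one non-negative value each.

    ``windows`` has columns chrom, start, end, value; missing data is NaN,
    never silently 0.  ``resolution`` tags window-level tracks; per-bp
    tracks are held by :class:`PerBaseTrack`.
    """

    windows: pd.DataFrame
    resolution: str = "window"

    def __post_init__(self) -> None:
        self.windows = self.windows.reset_index(drop=True)
        v = self.windows["value"]
        if (v.dropna() < 0).any():
            raise ValueError("enrichment values must be >= 0")
        for chrom, grp in self.windows.groupby("chrom"):
            s = grp.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"windows overlap on {chrom}")

    @property
    def values(self) -> pd.Series:
        return self.windows["value"]

    def defined(self) -> pd.DataFrame:
        return self.windows[self.windows["value"].notna()]

    def with_values(self, values) -> "EnrichmentTrack":
        out = self.windows.copy()
        out["value"] = np.asarray(values, dtype=float)
        return EnrichmentTrack(out, self.resolution)

    def to_bedgraph(self, path) -> None:
        self.defined().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path) -> "EnrichmentTrack":
        df = pd.read_csv(path, sep="\t", header=None, names=TRACK_COLUMNS,
                         dtype={"chrom": str})
        return cls(df)


class PerBaseTrack:
    """Per-bp enrichment as one float array per chromosome (NaN = missing)."""

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {c: np.asarray(a, dtype=float) for c, a in data.items()}
        self.resolution = "per-bp"

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def chroms(self) -> list[str]:
        return list(self.data)


@dataclass
class SpikeReference:
    """Sorted reference distribution of spike-in enrichment values."""

    values: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (np.diff(self.values) < 0).any():
            raise ValueError("reference values must be non-decreasing")

    def __len__(self) -> int:
        return self.values.size

    def to_tsv(self, path) -> None:
        pd.DataFrame({"value": self.values}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpikeReference":
        return cls(pd.read_csv(path, sep="\t")["value"].to_numpy())


# ---------------------------------------------------------------------------
# read bookkeeping

def split_spike_reads(alignments: pd.DataFrame, sample_contigs: set[str],
                      spike_contigs: set[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition alignments to a concatenated sample+spike reference.

    Each record goes to exactly one compartment by the contig of its
    alignment (the aligner reports a single best placement per read).
    Unknown contigs raise a configuration error.
    """
    refs = set(alignments["ref"].unique())
    unknown = refs - sample_contigs - spike_contigs
    if unknown:
        raise ValueError(f"contigs in neither compartment: {sorted(unknown)}")
    both = sample_contigs & spike_contigs
    if both:
        raise ValueError(f"contigs declared in both compartments: {sorted(both)}")
    is_spike = alignments["ref"].isin(spike_contigs)
    return (alignments[~is_spike].reset_index(drop=True),
            alignments[is_spike].reset_index(drop=True))


def make_windows(chromosomes: pd.DataFrame, window_size: int = 50_000) -> pd.DataFrame:
    """Tile chromosomes (frame with name, length) into fixed-width windows."""
    rows = []
    for c in chromosomes.itertuples():
        starts = np.arange(0, c.length, window_size)
        ends = np.minimum(starts + window_size, c.length)
        rows.append(pd.DataFrame({"chrom": c.name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _window_read_counts(reads: pd.DataFrame, windows: pd.DataFrame,
                        window_size: int) -> np.ndarray:
    """Reads per window, counted by read midpoint (no double counting)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    offsets = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        offsets[chrom] = (grp.index[0], len(grp))
    if len(reads) == 0:
        return counts
    reads = reads.reset_index(drop=True)
    mid = ((reads["start"].to_numpy() + reads["end"].to_numpy()) // 2)
    for chrom, grp in reads.groupby(reads["ref"].to_numpy(), sort=False):
        if chrom not in offsets:
            continue
        first, nwin = offsets[chrom]
        w = mid[grp.index.to_numpy()] // window_size
        w = w[(w >= 0) & (w < nwin)]
        np.add.at(counts, first + w, 1)
    return counts


def median_autosomal_coverage(reads: pd.DataFrame, chromosomes: pd.DataFrame) -> float:
    """Median per-bp read coverage over autosomal contigs."""
    autosomes = chromosomes[chromosomes["chrom_class"] == "autosome"]
    if autosomes.empty:
        raise ValueError("no autosomal contigs declared")
    per_bp = []
    for c in autosomes.itertuples():
        depth = np.zeros(c.length + 1, dtype=np.int64)
        sub = reads[reads["ref"] == c.name]
        if len(sub):
            s = np.clip(sub["start"].to_numpy(), 0, c.length)
            e = np.clip(sub["end"].to_numpy(), 0, c.length)
            np.add.at(depth, s, 1)
            np.add.at(depth, e, -1)
        per_bp.append(np.cumsum(depth[:-1]))
    return float(np.median(np.concatenate(per_bp)))


def window_enrichment(chip_reads: pd.DataFrame, input_reads: pd.DataFrame,
                      chromosomes: pd.DataFrame, window_size: int = 50_000,
                      mapq_min: int | None = None) -> EnrichmentTrack:
    """Per-window ChIP/input enrichment, each library depth-normalized by
    its median autosomal per-bp coverage.

    Windows with zero input reads get NaN (missing), not infinity.  With
    ``mapq_min`` set, only records at or above that mapping quality are
    used (the unique-read variant).
    """
    if mapq_min is not None:
        chip_reads = chip_reads[chip_reads["mapq"] >= mapq_min]
        input_reads = input_reads[input_reads["mapq"] >= mapq_min]
    windows = make_windows(chromosomes, window_size)
    chip_med = median_autosomal_coverage(chip_reads, chromosomes)
    input_med = median_autosomal_coverage(input_reads, chromosomes)
    if chip_med <= 0 or input_med <= 0:
        raise ValueError("median autosomal coverage must be > 0 for both libraries")
    chip_n = _window_read_counts(chip_reads, windows, window_size)
    input_n = _window_read_counts(input_reads, windows, window_size)
    zero = input_n == 0
    if zero.any():
        logger.info("%d windows with zero input reads set to missing", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        value = (chip_n / chip_med) / (input_n / input_med)
    value[zero] = np.nan
    windows["value"] = value
    return EnrichmentTrack(windows)


def per_base_enrichment(chip_reads: pd.DataFrame, input_reads: pd.DataFrame,
                        chromosomes: pd.DataFrame) -> PerBaseTrack:
    """Per-bp ChIP/input coverage ratio with median-autosomal normalization.

    Positions with zero input coverage are missing (NaN).
    """
    chip_med = median_autosomal_coverage(chip_reads, chromosomes)
    input_med = median_autosomal_coverage(input_reads, chromosomes)
    if chip_med <= 0 or input_med <= 0:
        raise ValueError("median autosomal coverage must be > 0 for both libraries")
    data = {}
    for c in chromosomes.itertuples():
        cov = {}
        for label, reads in (("chip", chip_reads), ("input", input_reads)):
            depth = np.zeros(c.length + 1, dtype=np.int64)
            sub = reads[reads["ref"] == c.name]
            if len(sub):
                np.add.at(depth, np.clip(sub["start"].to_numpy(), 0, c.length), 1)
                np.add.at(depth, np.clip(sub["end"].to_numpy(), 0, c.length), -1)
            cov[label] = np.cumsum(depth[:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (cov["chip"] / chip_med) / (cov["input"] / input_med)
        ratio[cov["input"] == 0] = np.nan
        data[c.name] = ratio
    return PerBaseTrack(data)


# ---------------------------------------------------------------------------
# spike-in quantile normalization

def build_spike_reference(spike_tracks: list[EnrichmentTrack],
                          provenance: list[str] | None = None) -> SpikeReference:
    """Average spike-in enrichment across libraries, sorted into a
    reference distribution.

    All tracks must cover the same windows; windows missing in any library
    are dropped from the reference.
    """
    if not spike_tracks:
        raise ValueError("need at least one spike-in track")
    mats = []
    base = spike_tracks[0].windows[["chrom", "start", "end"]]
    for t in spike_tracks:
        w = t.windows
        if not w[["chrom", "start", "end"]].reset_index(drop=True).equals(
                base.reset_index(drop=True)):
            raise ValueError("spike tracks cover different windows")
        mats.append(w["value"].to_numpy(dtype=float))
    mat = np.vstack(mats)
    mean = mat.mean(axis=0)
    mean = mean[np.isfinite(mean)]
    return SpikeReference(np.sort(mean), provenance or [])


@dataclass
class QuantileMap:
    """Monotone value-to-value correction derived from quantile matching.

    ``spike_values`` are the library's own sorted spike-in values with
    duplicates collapsed; ``corrected`` are the matched reference values
    (tied spike values get the mean of their reference block, so equal
    input values always receive equal corrections).  Between observed spike
    values the correction interpolates linearly; beyond the observed range
    it extrapolates as a constant.
    """

    spike_values: np.ndarray
    corrected: np.ndarray

    def __call__(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        out = np.interp(values, self.spike_values, self.corrected)
        out[np.isnan(values)] = np.nan
        return out


def quantile_correction_map(own_spike: EnrichmentTrack,
                            reference: SpikeReference) -> QuantileMap:
    """Quantile-match a library's spike values to the reference."""
    values = own_spike.windows["value"].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("spike track has no defined windows")
    if values.size != len(reference):
        raise ValueError(
            f"spike window count ({values.size}) does not match the "
            f"reference length ({len(reference)})")
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    matched = reference.values  # already sorted
    uniq, inverse = np.unique(sorted_vals, return_inverse=True)
    corrected = np.zeros(uniq.size)
    np.add.at(corrected, inverse, matched)
    counts = np.bincount(inverse, minlength=uniq.size)
    corrected /= counts
    corrected = np.maximum.accumulate(corrected)  # guard monotonicity under ties
    return QuantileMap(uniq, corrected)


def spikein_quantile_normalize(sample_track: EnrichmentTrack,
                               own_spike_track: EnrichmentTrack,
                               reference: SpikeReference) -> EnrichmentTrack:
    """Transfer the spike-derived quantile correction to sample windows.

    The correction learned on the library's spike-in windows is applied to
    every sample window of the same (or interpolated) enrichment value;
    missing windows stay missing.  The map is monotone, so sample window
    rank order is preserved.
    """
    qmap = quantile_correction_map(own_spike_track, reference)
    vals = sample_track.windows["value"].to_numpy(dtype=float)
    outside = np.isfinite(vals) & ((vals < qmap.spike_values[0]) |
                                   (vals > qmap.spike_values[-1]))
    if outside.any():
        logger.info("%d sample windows outside the spike value range: "
                    "constant extrapolation", int(outside.sum()))
    return sample_track.with_values(qmap(vals))
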