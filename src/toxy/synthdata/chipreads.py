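"""ChIP/input read simulation with a spike-in compartment.

Input reads fall uniformly over the concatenated sample+spike genome (the
spike fraction fixed by the wet-lab mixing ratio, 20% by default).  ChIP
reads are drawn window-wise in proportion to a monotone distortion of the
true enrichment landscape — the distortion stands in for library-specific
antibody pulldown efficiency, which the spike-in normalization is designed
to remove.  The spike genome carries one fixed enrichment landscape shared
by every library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from toxy.chipnorm import EnrichmentTrack, make_windows
from toxy.io import ALN_COLUMNS, empty_alignments


class IdentityDistortion:
    label = "identity"
    params: tuple = ()

    def __call__(self, v):
        return np.asarray(v, dtype=float)


@dataclass
class LinearDistortion:
    """v -> a * v; a > 1 mimics a more efficient pulldown."""

    a: float

    label = "linear"

    @property
    def params(self) -> tuple:
        return (self.a,)

    def __call__(self, v):
        return self.a * np.asarray(v, dtype=float)


@dataclass
class PowerDistortion:
    """v -> v ** g; g < 1 compresses the dynamic range."""

    g: float

    label = "power"

    @property
    def params(self) -> tuple:
        return (self.g,)

    def __call__(self, v):
        return np.asarray(v, dtype=float) ** self.g


@dataclass
class SpikeGenome:
    """Foreign-genome spike-in: contigs plus a fixed enrichment landscape."""

    chromosomes: pd.DataFrame  # name, length, chrom_class (class unused)
    enrichment: EnrichmentTrack

    @property
    def contigs(self) -> set[str]:
        return set(self.chromosomes["name"])


def make_spike_genome(n_windows: int = 200, window_size: int = 50_000,
                      landscape_seed: int = 424242) -> SpikeGenome:
    """One spike contig tiled into ``n_windows`` windows with a fixed
    log-normal enrichment landscape.

    The landscape seed is a constant by default: every library shares the
    same spike truth, which is the premise of the normalization.
    """
    rng = np.random.default_rng(landscape_seed)
    length = n_windows * window_size
    chroms = pd.DataFrame({"name": ["spike_1"], "length": [length],
                           "chrom_class": ["autosome"]})
    windows = make_windows(chroms, window_size)
    windows["value"] = np.exp(rng.normal(0.0, 0.6, size=len(windows)))
    return SpikeGenome(chroms, EnrichmentTrack(windows))


def _sample_reads(rng, windows: pd.DataFrame, weights: np.ndarray, n: int,
                  read_len: int) -> pd.DataFrame:
    if n == 0 or weights.sum() == 0:
        return empty_alignments()
    wi = rng.choice(len(windows), size=n, p=weights / weights.sum())
    span = (windows["end"] - windows["start"]).to_numpy()
    start = windows["start"].to_numpy()[wi] + (
        rng.random(n) * np.maximum(span[wi] - read_len, 1)).astype(np.int64)
    return pd.DataFrame({
        "qname": [f"r{i:08d}" for i in range(n)], "mate": 1,
        "ref": windows["chrom"].to_numpy()[wi], "start": start,
        "end": start + read_len,
        "strand": np.where(rng.random(n) < 0.5, "+", "-"), "mapq": 60,
    }, columns=ALN_COLUMNS)


def simulate_chip_reads(chromosomes: pd.DataFrame,
                        true_enrichment: EnrichmentTrack,
                        spike: SpikeGenome, spike_fraction: float = 0.2,
                        efficiency=None, depth: float = 5.0,
                        read_len: int = 100, seed: int = 0,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (ChIP reads, input reads) for one library.

    ``true_enrichment`` is the sample genome's window-level truth;
    ``efficiency`` is a monotone distortion applied to both sample and
    spike truth (identity by default).  ``depth`` is fold-coverage of the
    sample genome; spike reads are interleaved at ``spike_fraction`` of
    each library.  A zero-depth request returns empty read sets.
    """
    if not 0 <= spike_fraction < 1:
        raise ValueError("spike_fraction must lie in [0, 1)")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    efficiency = efficiency or IdentityDistortion()
    rng = np.random.default_rng(seed)

    g_sample = int(chromosomes["length"].sum())
    n_total = int(round(depth * g_sample / read_len))
    if n_total == 0:
        return empty_alignments(), empty_alignments()
    n_spike = int(rng.binomial(n_total, spike_fraction))
    n_sample = n_total - n_spike

    sw = true_enrichment.windows
    kw = spike.enrichment.windows
    span_s = (sw["end"] - sw["start"]).to_numpy(dtype=float)
    span_k = (kw["end"] - kw["start"]).to_numpy(dtype=float)

    def concat(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
        parts = [p for p in (a, b) if len(p)]
        if not parts:
            return empty_alignments()
        out = pd.concat(parts, ignore_index=True)
        out["qname"] = [f"r{i:08d}" for i in range(len(out))]
        return out

    # input: uniform over both compartments
    inp = concat(_sample_reads(rng, sw, span_s, n_sample, read_len),
                 _sample_reads(rng, kw, span_k, n_spike, read_len))
    # ChIP: proportional to the distorted enrichment landscape
    chip = concat(
        _sample_reads(rng, sw, span_s * efficiency(sw["value"].fillna(1.0)),
                      n_sample, read_len),
        _sample_reads(rng, kw, span_k * efficiency(kw["value"].fillna(1.0)),
                      n_spike, read_len))
    return chip, inp
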