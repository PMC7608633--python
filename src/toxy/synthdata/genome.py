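"""Synthetic genome construction with planted TE copies and genes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from toxy.annotation import GenomeAnnotation, empty_genes, empty_tes
from toxy.synthdata.spec import SyntheticGenomeSpec

_BASES = np.frombuffer(b"ACGT", dtype="S1")

INSERTION_COLUMNS = ["chrom", "pos", "family", "sample_id", "cell_fraction"]


class PlacementError(RuntimeError):
    """Raised when the requested density cannot be placed without overlap."""


def empty_insertions() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        INSERTION_COLUMNS, [str, int, str, str, float])})


@dataclass
class TruthSet:
    """Ground truth serialized alongside every synthetic dataset.

    ``germline_tes`` mirrors the TE annotation (reference copies);
    ``insertions`` holds planted de novo events (chrom, pos, family,
    carrier sample, cell fraction in (0, 1]); ``expression`` and
    ``enrichment`` are filled by the read/count simulators; ``distortions``
    records the per-library pulldown-efficiency label and parameters.
    """

    germline_tes: pd.DataFrame = field(default_factory=empty_tes)
    insertions: pd.DataFrame = field(default_factory=empty_insertions)
    expression: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    distortions: dict[str, tuple[str, tuple]] = field(default_factory=dict)

    def validate(self, annotation: GenomeAnnotation | None = None) -> None:
        if len(self.insertions):
            cf = self.insertions["cell_fraction"]
            if ((cf <= 0) | (cf > 1)).any():
                raise ValueError("cell fractions must lie in (0, 1]")
            if annotation is not None:
                lengths = annotation.chrom_lengths()
                limit = self.insertions["chrom"].map(lengths)
                if (self.insertions["pos"] <= 0).any() or (self.insertions["pos"] >= limit).any():
                    raise ValueError("insertion points must lie strictly inside chromosomes")

    def y_linked_families(self, annotation: GenomeAnnotation, min_ratio: float = 2.0) -> set[str]:
        """Families whose reference copy number on the Y is at least
        ``min_ratio`` times their copy number elsewhere."""
        if not len(self.germline_tes):
            return set()
        classes = annotation.chrom_classes()
        on_y = self.germline_tes["chrom"].map(classes) == "Y"
        counts = pd.crosstab(self.germline_tes["family"], on_y)
        y = counts.get(True, pd.Series(0, index=counts.index))
        rest = counts.get(False, pd.Series(0, index=counts.index))
        return set(counts.index[(y >= min_ratio * rest) & (y > 0)])

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.germline_tes.to_csv(outdir / "truth_germline_tes.tsv", sep="\t", index=False)
        self.insertions.to_csv(outdir / "truth_insertions.tsv", sep="\t", index=False)
        if self.expression is not None:
            self.expression.to_csv(outdir / "truth_expression.tsv", sep="\t")
        if self.enrichment is not None:
            self.enrichment.to_csv(outdir / "truth_enrichment.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    arr[hits] = rng.choice(_BASES, size=hits.size)
    return arr.tobytes().decode()


def _place_disjoint(rng: np.random.Generator, chrom: str, length: int,
                    sizes: list[int], occupied: list[tuple[int, int]],
                    max_tries: int = 200) -> list[tuple[int, int]]:
    """Place intervals of the given sizes without overlapping each other or
    ``occupied``; bounded rejection sampling."""
    placed: list[tuple[int, int]] = []
    taken = sorted(occupied)
    starts = np.array([iv[0] for iv in taken])
    ends = np.array([iv[1] for iv in taken])
    for size in sizes:
        if size > length:
            raise PlacementError(
                f"chromosome {chrom}: interval of {size} bp exceeds length {length}")
        for _ in range(max_tries):
            s = int(rng.integers(0, length - size + 1))
            e = s + size
            i = np.searchsorted(ends, s, side="right")
            if i < starts.size and starts[i] < e:
                continue
            placed.append((s, e))
            starts = np.insert(starts, i, s)
            ends = np.insert(ends, i, e)
            break
        else:
            raise PlacementError(
                f"chromosome {chrom}: could not place a {size} bp interval "
                f"after {max_tries} tries (density too high?)")
    return placed


def make_genome(spec: SyntheticGenomeSpec):
    """Build a synthetic genome from a spec.

    Returns ``(genome, te_library, annotation, truth)`` where ``genome`` and
    ``te_library`` map names to sequences.  TE copies are planted disjointly
    at the requested per-chromosome densities; genes are placed disjointly
    from each other (they may overlap TEs, as genes on a young Y commonly
    carry insertions); a configurable fraction of genes is placed adjacent
    to a TE copy.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    family_names = [f"TEfam{i:03d}" for i in range(spec.n_te_families)]
    lo, hi = spec.te_length_range
    fam_lengths = rng.integers(lo, hi + 1, size=spec.n_te_families)
    te_library = {name: _random_seq(rng, int(n)) for name, n in zip(family_names, fam_lengths)}
    fam_len = dict(zip(family_names, (int(v) for v in fam_lengths)))

    genome: dict[str, str] = {}
    te_rows, gene_rows = [], []
    for cs in spec.chromosomes:
        seq = np.frombuffer(_random_seq(rng, cs.length).encode(), dtype="S1").copy()

        n_te = int(round(cs.te_density * cs.length / 1e6))
        fams = rng.choice(family_names, size=n_te) if n_te else np.array([], dtype=object)
        sizes = [fam_len[f] for f in fams]
        te_iv = _place_disjoint(rng, cs.name, cs.length, sizes, [])
        order = np.argsort([iv[0] for iv in te_iv]) if te_iv else []
        te_iv = [te_iv[i] for i in order]
        fams = [fams[i] for i in order]
        for (s, e), fam in zip(te_iv, fams):
            strand = "+" if rng.random() < 0.5 else "-"
            copy = _diverge(rng, te_library[fam], spec.te_divergence)
            if strand == "-":
                copy = _revcomp(copy)
            seq[s:e] = np.frombuffer(copy.encode(), dtype="S1")
            te_rows.append((cs.name, s, e, fam, strand))

        n_gene = int(round(cs.gene_density * cs.length / 1e6))
        glo, ghi = spec.gene_length_range
        gsizes = [int(v) for v in rng.integers(glo, ghi + 1, size=n_gene)]
        gene_iv: list[tuple[int, int]] = []
        near = rng.random(n_gene) < spec.gene_near_te_fraction
        for k, gsize in enumerate(gsizes):
            if near[k] and te_iv:
                ts, te_end = te_iv[int(rng.integers(len(te_iv)))]
                offset = int(rng.integers(1, 2000))
                s = te_end + offset if rng.random() < 0.5 else ts - offset - gsize
                s = int(np.clip(s, 0, cs.length - gsize))
                gene_iv = _merge_nonoverlapping(gene_iv, (s, s + gsize))
                continue
            placed = _place_disjoint(rng, cs.name, cs.length, [gsize],
                                     sorted(gene_iv))
            gene_iv.append(placed[0])
        gene_iv.sort()
        zyg = rng.random(len(gene_iv)) < spec.zygotic_fraction
        for k, (s, e) in enumerate(gene_iv):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"{cs.name}_g{k:04d}", cs.name, s, e, strand,
                              s if strand == "+" else e - 1, bool(zyg[k])))

        genome[cs.name] = seq.tobytes().decode()

    chrom_df = pd.DataFrame({
        "name": [c.name for c in spec.chromosomes],
        "length": [c.length for c in spec.chromosomes],
        "chrom_class": [c.chrom_class for c in spec.chromosomes],
    })
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "family", "strand"]) \
        if te_rows else empty_tes()
    genes = pd.DataFrame(gene_rows, columns=["name", "chrom", "start", "end",
                                             "strand", "tss", "zygotic"]) \
        if gene_rows else empty_genes()
    annotation = GenomeAnnotation(chrom_df, genes, tes)
    truth = TruthSet(germline_tes=tes.copy())
    return genome, te_library, annotation, truth


def _merge_nonoverlapping(intervals: list[tuple[int, int]],
                          new: tuple[int, int]) -> list[tuple[int, int]]:
    """Append ``new`` if it does not overlap any existing interval; otherwise
    drop it silently (adjacency placement is best-effort)."""
    for s, e in intervals:
        if new[0] < e and s < new[1]:
            return intervals
    intervals.append(new)
    return intervals


def plant_insertions(annotation: GenomeAnnotation, te_library: dict[str, str],
                     samples, n_per_sample: int, cell_fraction: float = 1.0,
                     seed: int = 0, min_flank: int = 2000,
                     shared: pd.DataFrame | None = None) -> pd.DataFrame:
    """Plant de novo insertion points in unique (TE-free) sequence.

    Each carrier sample receives ``n_per_sample`` insertions of random
    families at points at least ``min_flank`` bp from any germline TE copy
    and from chromosome ends, so both flanks are uniquely mappable.
    ``shared`` optionally supplies pre-chosen (chrom, pos, family) rows to
    replicate across specific samples.  Returns the truth insertion frame.
    """
    if not 0 < cell_fraction <= 1:
        raise ValueError("cell_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    lengths = annotation.chrom_lengths()
    families = sorted(te_library)
    rows = []
    sample_ids = [s if isinstance(s, str) else s.sample_id for s in samples]

    def valid_point(chrom: str, pos: int) -> bool:
        if pos < min_flank or pos > lengths[chrom] - min_flank:
            return False
        tes = annotation.tes[annotation.tes["chrom"] == chrom]
        near = (tes["start"] - min_flank < pos) & (pos < tes["end"] + min_flank)
        if near.any():
            return False
        return all(not (r[0] == chrom and abs(r[1] - pos) < min_flank) for r in rows)

    if shared is not None:
        for r in shared.itertuples():
            rows.append((r.chrom, int(r.pos), r.family, r.sample_id, cell_fraction))

    probs = lengths / lengths.sum()
    for sid in sample_ids:
        placed = 0
        tries = 0
        while placed < n_per_sample:
            tries += 1
            if tries > 1000 * n_per_sample:
                raise PlacementError(
                    f"could not plant {n_per_sample} insertions for {sid}")
            chrom = str(rng.choice(lengths.index, p=probs.values))
            pos = int(rng.integers(min_flank, lengths[chrom] - min_flank))
            if not valid_point(chrom, pos):
                continue
            fam = str(rng.choice(families))
            rows.append((chrom, pos, fam, sid, cell_fraction))
            placed += 1
    return pd.DataFrame(rows, columns=INSERTION_COLUMNS)
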