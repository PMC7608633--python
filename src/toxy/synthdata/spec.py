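"""Declarative specification of a synthetic genome."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from toxy.annotation import CHROM_CLASSES


@dataclass
class ChromosomeSpec:
    """One synthetic chromosome.

    ``te_density`` and ``gene_density`` are copies (resp. genes) per Mb.
    The default architecture gives the Y a higher repeat density than the
    autosomes, mirroring a young, repeat-rich but still gene-bearing neo-Y.
    """

    name: str
    length: int
    chrom_class: str = "autosome"
    te_density: float = 10.0
    gene_density: float = 10.0

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.te_density < 0 or self.gene_density < 0:
            raise ValueError(f"chromosome {self.name}: densities must be >= 0")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(
                f"chromosome {self.name}: class must be one of {CHROM_CLASSES}")


def default_chromosomes() -> list[ChromosomeSpec]:
    return [
        ChromosomeSpec("chr2", 600_000, "autosome", te_density=10, gene_density=15),
        ChromosomeSpec("chr3", 600_000, "autosome", te_density=10, gene_density=15),
        ChromosomeSpec("chrX", 400_000, "X", te_density=10, gene_density=15),
        ChromosomeSpec("chrY", 400_000, "Y", te_density=40, gene_density=10),
    ]


@dataclass
class SyntheticGenomeSpec:
    """Parameters for :func:`toxy.synthdata.make_genome`.

    One RNG seed governs every random draw; regenerating with the same spec
    and seed yields byte-identical sequences and annotations.
    """

    chromosomes: list[ChromosomeSpec] = field(default_factory=default_chromosomes)
    n_te_families: int = 20
    te_length_range: tuple[int, int] = (500, 1500)
    gene_length_range: tuple[int, int] = (1000, 3000)
    zygotic_fraction: float = 0.4
    #: fraction of genes deliberately placed adjacent to a TE copy (< 2 kb)
    gene_near_te_fraction: float = 0.0
    #: per-base substitution rate applied to each planted TE copy
    te_divergence: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome is required")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c in self.chromosomes:
            c.validate()
        if self.n_te_families <= 0:
            raise ValueError("n_te_families must be > 0")
        lo, hi = self.te_length_range
        if not (0 < lo <= hi):
            raise ValueError("te_length_range must satisfy 0 < lo <= hi")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must satisfy 0 < lo <= hi")
        if not 0 <= self.zygotic_fraction <= 1:
            raise ValueError("zygotic_fraction must lie in [0, 1]")
        if not 0 <= self.gene_near_te_fraction <= 1:
            raise ValueError("gene_near_te_fraction must lie in [0, 1]")
        if not 0 <= self.te_divergence < 1:
            raise ValueError("te_divergence must lie in [0, 1)")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["te_length_range"] = list(self.te_length_range)
        data["gene_length_range"] = list(self.gene_length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticGenomeSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        chroms = [ChromosomeSpec(**c) for c in data.pop("chromosomes")]
        for key in ("te_length_range", "gene_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        spec = cls(chromosomes=chroms, **data)
        spec.validate()
        return spec
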