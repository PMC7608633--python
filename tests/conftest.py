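import numpy as np
import pandas as pd
import pytest

from toxy.annotation import GenomeAnnotation
from toxy.samples import SampleMeta
from toxy.synthdata import ChromosomeSpec, SyntheticGenomeSpec, make_genome


@pytest.fixture(scope="session")
def small_spec() -> SyntheticGenomeSpec:
    return SyntheticGenomeSpec(
        chromosomes=[
            ChromosomeSpec("chr2", 300_000, "autosome", te_density=20, gene_density=20),
            ChromosomeSpec("chrX", 200_000, "X", te_density=20, gene_density=20),
            ChromosomeSpec("chrY", 200_000, "Y", te_density=60, gene_density=15),
        ],
        n_te_families=10,
        te_length_range=(400, 800),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    """(genome, te_library, annotation, truth) for a 700-kb test genome."""
    return make_genome(small_spec)


@pytest.fixture(scope="session")
def rna_design() -> list[SampleMeta]:
    return [
        SampleMeta(f"{sex[0]}{stage}r{rep}", "dpse", sex, stage, rep, "RNA")
        for sex in ("female", "male")
        for stage in (2, 10)
        for rep in (1, 2, 3)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def flat_annotation() -> GenomeAnnotation:
    """Hand-laid annotation for interval tests (coordinates chosen by hand)."""
    chroms = pd.DataFrame({
        "name": ["c1", "c2"],
        "length": [100_000, 50_000],
        "chrom_class": ["autosome", "Y"],
    })
    genes = pd.DataFrame({
        "name": ["g1", "g2", "g3"],
        "chrom": ["c1", "c1", "c2"],
        "start": [1000, 30_000, 5_000],
        "end": [2000, 33_000, 8_000],
        "strand": ["+", "-", "+"],
        "tss": [1000, 32_999, 5_000],
        "zygotic": [True, False, True],
    })
    tes = pd.DataFrame({
        "chrom": ["c1", "c1", "c2"],
        "start": [2500, 40_000, 6_000],
        "end": [2600, 41_000, 6_500],
        "family": ["famA", "famB", "famA"],
        "strand": ["+", "-", "+"],
    })
    return GenomeAnnotation(chroms, genes, tes)
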