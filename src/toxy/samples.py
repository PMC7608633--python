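"""Sample metadata: the design axis for every cross-library comparison."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

SEXES = ("female", "male")
ASSAYS = ("RNA", "DNA", "ChIP", "input")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing library.

    Parameters
    ----------
    sample_id:
        Unique library identifier within a run.
    species:
        Free-text species label (e.g. ``"dpse"``).
    sex:
        ``"female"`` or ``"male"``.
    stage:
        Ordinal developmental stage (embryonic stage number); stages are
        totally ordered by this integer.
    replicate:
        Replicate index within a (species, sex, stage, assay) cell.
    assay:
        One of ``"RNA"``, ``"DNA"``, ``"ChIP"``, ``"input"``.
    """

    sample_id: str
    species: str
    sex: str
    stage: int
    replicate: int
    assay: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")


def check_design(samples: Iterable[SampleMeta]) -> list[SampleMeta]:
    """Validate a sample design: unique ids. Returns the samples as a list."""
    samples = list(samples)
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids in design: {dup}")
    return samples


def design_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    """Sample sheet as a DataFrame indexed by sample id."""
    df = pd.DataFrame(
        {
            "species": [s.species for s in samples],
            "sex": [s.sex for s in samples],
            "stage": [s.stage for s in samples],
            "replicate": [s.replicate for s in samples],
            "assay": [s.assay for s in samples],
        },
        index=pd.Index([s.sample_id for s in samples], name="sample_id"),
    )
    return df


def read_sample_sheet(path) -> list[SampleMeta]:
    """Read a TSV sample sheet (sample_id, species, sex, stage, replicate, assay)."""
    df = pd.read_csv(path, sep="\t")
    return check_design(
        SampleMeta(
            sample_id=str(r.sample_id),
            species=str(r.species),
            sex=str(r.sex),
            stage=int(r.stage),
            replicate=int(r.replicate),
            assay=str(r.assay),
        )
        for r in df.itertuples()
    )


def write_sample_sheet(samples: Sequence[SampleMeta], path) -> None:
    design_frame(samples).to_csv(path, sep="\t")
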