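"""Stage-by-sex RNA count simulation with a maternal-to-zygotic transition.

Before the transition stage, transcript pools are maternally deposited and
therefore sex-independent.  After it, zygotic genes switch on and male
samples inflate Y-linked TE families by a configurable fold — the
expression signature of Y-TE misregulation that the quantification module
is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from toxy.annotation import GenomeAnnotation
from toxy.samples import SampleMeta, check_design
from toxy.repeatquant import FeatureCountTable


@dataclass
class RnaEffects:
    """Effect sizes for :func:`simulate_rna_counts`.

    ``maternal_level``: mean TE read count (maternal pool and baseline
    zygotic TE expression).  ``gene_level``: mean gene read count.
    ``zygotic_stage``: first stage with zygotic transcription (the
    maternal-to-zygotic transition, ~embryonic stage 5).
    ``male_y_te_fold``: multiplicative male effect on Y-linked TE families
    at and after the transition.  ``dispersion``: negative-binomial
    dispersion alpha (variance = mu + alpha * mu^2); 0 gives deterministic
    counts equal to the means.  ``feature_sigma``: sd of the per-feature
    log-normal baseline variation (0 = identical baselines).
    """

    maternal_level: float = 2000.0
    gene_level: float = 100.0
    zygotic_stage: int = 5
    male_y_te_fold: float = 1.0
    dispersion: float = 0.2
    feature_sigma: float = 0.5

    def validate(self) -> None:
        if self.maternal_level <= 0 or self.gene_level <= 0:
            raise ValueError("expression levels must be > 0")
        if self.male_y_te_fold <= 0:
            raise ValueError("male_y_te_fold must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.feature_sigma < 0:
            raise ValueError("feature_sigma must be >= 0")


def simulate_rna_counts(annotation: GenomeAnnotation | None,
                        design: list[SampleMeta], effects: RnaEffects,
                        seed: int = 0, te_families: list[str] | None = None,
                        y_families: set[str] | None = None,
                        ) -> tuple[FeatureCountTable, pd.DataFrame]:
    """Simulate a raw feature count table (genes + TEs) for an RNA design.

    TE families default to those present in the annotation; ``y_families``
    (the families subject to the male fold effect) default to families whose
    copies lie mostly on Y-class chromosomes.  Returns ``(table,
    true_means)`` where ``true_means`` is the feature-by-sample mean matrix
    the counts were drawn from.
    """
    effects.validate()
    design = check_design(design)
    rna = [s for s in design if s.assay == "RNA"]
    if not rna:
        raise ValueError("design contains no RNA samples")
    rng = np.random.default_rng(seed)

    if te_families is None:
        if annotation is None:
            raise ValueError("need an annotation or an explicit te_families list")
        te_families = sorted(annotation.tes["family"].unique())
    if y_families is None:
        y_families = set()
        if annotation is not None and len(annotation.tes):
            classes = annotation.chrom_classes()
            on_y = annotation.tes["chrom"].map(classes) == "Y"
            tab = pd.crosstab(annotation.tes["family"], on_y)
            y_cnt = tab.get(True, pd.Series(0, index=tab.index))
            other = tab.get(False, pd.Series(0, index=tab.index))
            y_families = set(tab.index[(y_cnt >= 2 * other) & (y_cnt > 0)])

    if annotation is not None and len(annotation.genes):
        gene_names = list(annotation.genes["name"])
        zygotic = annotation.genes.set_index("name")["zygotic"]
    else:
        gene_names, zygotic = [], pd.Series(dtype=bool)

    features = gene_names + list(te_families)
    fclass = pd.Series(["gene"] * len(gene_names) + ["TE"] * len(te_families),
                       index=features, name="feature_class")

    base = np.concatenate([
        np.full(len(gene_names), effects.gene_level),
        np.full(len(te_families), effects.maternal_level),
    ]) * np.exp(rng.normal(0.0, effects.feature_sigma, size=len(features)))

    means = pd.DataFrame(index=pd.Index(features, name="feature"),
                         columns=[s.sample_id for s in rna], dtype=float)
    is_y_te = np.array([f in y_families for f in features])
    is_zyg = np.array([bool(zygotic.get(f, False)) for f in features])
    is_gene = fclass.to_numpy() == "gene"
    for s in rna:
        mu = base.copy()
        post = s.stage >= effects.zygotic_stage
        if not post:
            mu[is_gene & is_zyg] = 0.0  # zygotic genes silent pre-transition
        elif s.sex == "male":
            mu[~is_gene & is_y_te] *= effects.male_y_te_fold
        means[s.sample_id] = mu

    if effects.dispersion == 0:
        counts = means.copy()
    else:
        shape = 1.0 / effects.dispersion
        mu = means.to_numpy()
        lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=mu.shape) * mu / shape, 0.0)
        counts = pd.DataFrame(rng.poisson(lam), index=means.index,
                              columns=means.columns)

    table = FeatureCountTable(counts=counts, feature_class=fclass, state="raw")
    return table, means
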