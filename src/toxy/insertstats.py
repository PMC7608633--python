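"""Count models and distribution tests for de novo insertion calls.

Insertion counts per library scale with sequencing depth, so depth enters
every model: an ANOVA of counts on coverage, sex and developmental stage
(sequential, in that order); a coverage-only regression whose residuals
isolate the sex/stage signal; and a per-chromosome comparison of observed
insertion counts against expectations proportional to chromosome length
times sex-specific diploid copy number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from toxy._stats import rank_sum_test

RECORD_COLUMNS = ["sample_id", "sex", "stage", "coverage", "n_insertions"]

#: diploid copy numbers by chromosome class and sex
DEFAULT_COPY_NUMBERS = {
    "female": {"autosome": 2, "X": 2, "Y": 0},
    "male": {"autosome": 2, "X": 1, "Y": 1},
}


def check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"library records missing columns {sorted(missing)}")
    if (records["coverage"] <= 0).any():
        raise ValueError("coverage must be > 0")
    if (records["n_insertions"] < 0).any():
        raise ValueError("insertion counts must be >= 0")
    return records


# ---------------------------------------------------------------------------
# ANOVA

def _design_blocks(records: pd.DataFrame, stage_ordinal: bool,
                   ) -> list[tuple[str, pd.DataFrame]]:
    """Model-term blocks in the model's stated order."""
    blocks = [("coverage", records[["coverage"]].astype(float))]
    sex = pd.get_dummies(records["sex"], prefix="sex", drop_first=True,
                         dtype=float)
    blocks.append(("sex", sex))
    if stage_ordinal:
        blocks.append(("stage", records[["stage"]].astype(float)))
    else:
        stage = pd.get_dummies(records["stage"].astype("category"),
                               prefix="stage", drop_first=True, dtype=float)
        blocks.append(("stage", stage))
    return blocks


def fit_anova(records: pd.DataFrame, stage_ordinal: bool = False):
    """Sequential (type-I) ANOVA of insertion counts on coverage, sex and
    developmental stage, in that order.

    The sum of squares attributed to each term is the drop in residual sum
    of squares when the term's columns enter the model, in the stated
    order; F uses the full model's residual mean square.  ``stage_ordinal``
    treats stage as a numeric covariate instead of a categorical factor.
    Returns ``(anova_table, fitted_model)``; the fitted model exposes
    coefficient estimates and standard errors (columns ``coverage``,
    ``sex_male``, ``stage_*``).
    """
    records = check_records(records).copy()
    if records["sex"].nunique() < 2:
        raise ValueError("need both sexes in the design")
    if records["stage"].nunique() < 2:
        raise ValueError("need at least two stages in the design")
    blocks = _design_blocks(records, stage_ordinal)
    exog = pd.concat([b for _, b in blocks], axis=1)
    exog.insert(0, "const", 1.0)
    if len(records) <= exog.shape[1]:
        raise ValueError("need more observations than model terms")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        aliased = [name for name, _ in blocks]
        raise ValueError(f"collinear design: aliased terms among {aliased} "
                         "(e.g. sex confounded with stage)")
    y = records["n_insertions"].to_numpy(dtype=float)
    model = sm.OLS(y, exog).fit()

    rows = []
    rss_prev = float(((y - y.mean()) ** 2).sum())
    cols: list[str] = ["const"]
    for name, block in blocks:
        cols = cols + list(block.columns)
        rss = float(sm.OLS(y, exog[cols]).fit().ssr)
        df = block.shape[1]
        rows.append((name, df, rss_prev - rss))
        rss_prev = rss
    df_resid = int(model.df_resid)
    mse = model.ssr / df_resid if df_resid > 0 else np.nan
    table = pd.DataFrame(
        [(df, ss, ss / df) for _, df, ss in rows],
        index=[name for name, _, _ in rows],
        columns=["df", "sum_sq", "mean_sq"])
    with np.errstate(divide="ignore", invalid="ignore"):
        table["F"] = table["mean_sq"] / mse
        table["PR(>F)"] = stats.f.sf(table["F"], table["df"], df_resid)
    table.loc["Residual"] = [df_resid, model.ssr, mse, np.nan, np.nan]
    return table, model


# ---------------------------------------------------------------------------
# coverage residuals

def coverage_residuals(records: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Residuals of counts ~ coverage, compared male vs female per stage.

    Removes the library-size effect by OLS with intercept, then runs a
    two-tailed rank-sum test on the residuals within each stage (no
    multiple-testing correction).  Degenerate stages (all residuals equal
    or one sex absent) report p = 1.  Returns ``(records + residual
    column, per-stage p-values)``.
    """
    records = check_records(records).copy()
    X = sm.add_constant(records["coverage"].to_numpy(dtype=float))
    fit = sm.OLS(records["n_insertions"].to_numpy(dtype=float), X).fit()
    records["residual"] = fit.resid
    pvals = {}
    for stage, grp in records.groupby("stage"):
        male = grp.loc[grp["sex"] == "male", "residual"].to_numpy()
        female = grp.loc[grp["sex"] == "female", "residual"].to_numpy()
        if male.size == 0 or female.size == 0 or np.ptp(grp["residual"]) == 0:
            pvals[stage] = 1.0
            continue
        _, p = rank_sum_test(male, female)
        pvals[stage] = p
    return records, pd.Series(pvals, name="p_male_vs_female")


# ---------------------------------------------------------------------------
# chromosomal distribution

def largest_remainder_round(expected: np.ndarray, total: int) -> np.ndarray:
    """Round expectations to integers that sum exactly to ``total``."""
    floor = np.floor(expected).astype(int)
    short = total - floor.sum()
    order = np.argsort(-(expected - floor), kind="stable")
    floor[order[:short]] += 1
    return floor


def chromosome_distribution_test(calls: pd.DataFrame | pd.Series,
                                 chromosomes: pd.DataFrame, sex: str,
                                 copy_numbers: dict | None = None,
                                 method: str = "fisher") -> pd.DataFrame:
    """Observed vs expected insertion counts per chromosome under a uniform
    insertion rate.

    Expected counts distribute the genome-wide observed total in proportion
    to chromosome length times the sex's diploid copy number, rounded by
    largest remainder so they sum exactly to the total.  Each chromosome is
    then tested with a two-sided 2x2 Fisher's exact test of (on vs off the
    chromosome) x (observed vs expected); ``method="binomial"`` substitutes
    an exact binomial test of the observed on-chromosome count.

    ``calls`` is either a call frame with a ``chrom`` column or a
    precomputed per-chromosome count Series.  Calls on a chromosome with
    zero copies for the given sex (e.g. Y in females) are a validation
    error.
    """
    copy_numbers = copy_numbers or DEFAULT_COPY_NUMBERS
    if sex not in copy_numbers:
        raise ValueError(f"unknown sex {sex!r}")
    chrom_df = chromosomes.copy()
    chrom_df["copies"] = chrom_df["chrom_class"].map(copy_numbers[sex])

    if isinstance(calls, pd.Series):
        observed = calls
    else:
        observed = calls["chrom"].value_counts()
    observed = observed.reindex(chrom_df["name"]).fillna(0).astype(int)
    unknown = (set(calls["chrom"]) if not isinstance(calls, pd.Series)
               else set(calls.index)) - set(chrom_df["name"])
    if unknown:
        raise ValueError(f"calls on unknown chromosomes: {sorted(unknown)}")
    absent = chrom_df["copies"].to_numpy() == 0
    if (observed.to_numpy()[absent] > 0).any():
        bad = chrom_df["name"].to_numpy()[absent & (observed.to_numpy() > 0)]
        raise ValueError(f"{sex} genome cannot carry calls on {list(bad)}")

    total = int(observed.sum())
    weight = (chrom_df["length"] * chrom_df["copies"]).to_numpy(dtype=float)
    expected = total * weight / weight.sum()
    expected_int = largest_remainder_round(expected, total)

    pvals, direction = [], []
    for obs, exp in zip(observed.to_numpy(), expected_int):
        if method == "fisher":
            table = [[obs, total - obs], [int(exp), total - int(exp)]]
            _, p = stats.fisher_exact(table, alternative="two-sided")
        elif method == "binomial":
            p = stats.binomtest(obs, total, exp / total if total else 0.5).pvalue \
                if total else 1.0
        else:
            raise ValueError("method must be 'fisher' or 'binomial'")
        pvals.append(float(p))
        direction.append("enriched" if obs > exp else
                         "depleted" if obs < exp else "as expected")
    return pd.DataFrame({
        "chrom": chrom_df["name"].to_numpy(),
        "length": chrom_df["length"].to_numpy(),
        "copies": chrom_df["copies"].to_numpy(),
        "observed": observed.to_numpy(),
        "expected": expected_int,
        "expected_raw": expected,
        "p": pvals,
        "direction": direction,
    })


@dataclass
class InsertionRecordBuilder:
    """Assemble library insertion records from calls and sample metadata."""

    @staticmethod
    def from_calls(calls: pd.DataFrame, design, coverage: pd.Series,
                   autosomes_only: bool = False,
                   chromosomes: pd.DataFrame | None = None) -> pd.DataFrame:
        if autosomes_only:
            if chromosomes is None:
                raise ValueError("autosomes_only needs the chromosome table")
            auto = set(chromosomes.loc[
                chromosomes["chrom_class"] == "autosome", "name"])
            calls = calls[calls["chrom"].isin(auto)]
        counts = calls.groupby("sample_id").size()
        rows = []
        for s in design:
            rows.append((s.sample_id, s.sex, s.stage,
                         float(coverage[s.sample_id]),
                         int(counts.get(s.sample_id, 0))))
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)
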