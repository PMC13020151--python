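"""XCI-status and sex-bias classification, plus the categorical test battery.

A gene x tissue x individual observation is *silenced* when 0.5 <= 1-AE < 0.6
and *escaping* when 1-AE >= 0.6; a gene x tissue pair whose individual-level
calls disagree is *variable*. Sex-bias status comes from the shrunken sex
effect beta_mash and its local false sign rate: male-biased when LFSR < 0.05
and beta_mash > 0, female-biased when LFSR < 0.05 and beta_mash < 0,
otherwise unbiased. All thresholds are strict inequalities exactly as stated
and configurable through :class:`~xciscape.config.Thresholds`.

The categorical tests mirror the R conventions of ``binom.test`` (exact
one-sided tail), ``fisher.test`` (two-sided hypergeometric p with a
conditional-MLE odds ratio) and a Welch two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds

XCI_STATUSES = ("silenced", "escape", "variable")
BIAS_STATUSES = ("female", "male", "unbiased")


@dataclass
class CategoricalTestResult:
    """Outcome of one binomial / Fisher / Welch test."""

    test_name: str
    statistic: float
    p_value: float
    estimate: float
    n: int
    alternative: str
    table: list[list[int]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    @property
    def estimate_infinite(self) -> bool:
        return math.isinf(self.estimate)


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def classify_xci_individual(one_minus_ae: float, thresholds: Thresholds | None = None) -> str:
    """Call one observation 'silenced' (1-AE < 0.6) or 'escape' (1-AE >= 0.6)."""
    t = thresholds or Thresholds()
    v = float(one_minus_ae)
    if not 0.5 - 1e-9 <= v <= 1.0 + 1e-9:
        raise ValueError(f"1-AE must lie in [0.5, 1], got {v}")
    return "escape" if v >= t.escape_one_minus_ae else "silenced"


def classify_xci_gene_tissue(individual_statuses: Sequence[str]) -> str:
    """Combine individual-level calls: unanimous status, else 'variable'."""
    statuses = list(individual_statuses)
    if not statuses:
        raise ValueError("at least one individual-level status is required")
    unknown = set(statuses) - {"silenced", "escape"}
    if unknown:
        raise ValueError(f"unknown individual statuses: {sorted(unknown)}")
    uniq = set(statuses)
    return statuses[0] if len(uniq) == 1 else "variable"


def classify_sex_bias(
    beta_mash: float, lfsr: float, thresholds: Thresholds | None = None
) -> str:
    """'male' / 'female' / 'unbiased' from the sex effect and its LFSR."""
    t = thresholds or Thresholds()
    if not 0.0 <= lfsr <= 1.0:
        raise ValueError(f"lfsr must lie in [0, 1], got {lfsr}")
    if lfsr < t.lfsr and beta_mash > 0:
        return "male"
    if lfsr < t.lfsr and beta_mash < 0:
        return "female"
    return "unbiased"


def detect_nmxci(
    gene_ae: Mapping[str, float],
    exclude: Iterable[str] = (),
    thresholds: Thresholds | None = None,
) -> tuple[float, bool]:
    """Median AE across informative genes and the non-mosaic-XCI call.

    A female with essentially complete skewing of XCI toward one parental X
    shows near-monoallelic expression chromosome-wide; the call is median
    AE > 0.475 over all genes after excluding the PAR and known
    variable-escape genes (the ``exclude`` set, supplied as configuration).
    """
    t = thresholds or Thresholds()
    excl = set(exclude)
    values = [v for g, v in gene_ae.items() if g not in excl]
    if not values:
        raise ValueError("no genes remain after applying the exclusion set")
    arr = np.asarray(values, dtype=float)
    if np.any((arr < 0) | (arr > 0.5 + 1e-9)):
        raise ValueError("AE values must lie in [0, 0.5]")
    med = float(np.median(arr))
    return med, med > t.nmxci_median_ae


# ---------------------------------------------------------------------------
# Status-table construction and cross-tabulation
# ---------------------------------------------------------------------------

def build_status_table(
    ae: pd.DataFrame,
    sexbias: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Join AE, sex-bias and annotation tables into per gene x tissue statuses.

    ``ae`` must have gene_id / tissue / individual / ae columns (reader
    output); ``sexbias`` gene_id / tissue / beta_mash / lfsr; ``annotation``
    gene_id / region. Returns one row per gene x tissue present in the AE
    table, with xci_status, bias_status, the per-individual 1-AE values and
    their mean.
    """
    t = thresholds or Thresholds()
    df = ae.copy()
    df["one_minus_ae"] = 1.0 - df["ae"].astype(float)
    df["ind_status"] = [
        classify_xci_individual(v, t) for v in df["one_minus_ae"]
    ]
    grouped = (
        df.groupby(["gene_id", "tissue"], sort=True)
        .agg(
            one_minus_ae_values=("one_minus_ae", list),
            mean_one_minus_ae=("one_minus_ae", "mean"),
            statuses=("ind_status", list),
            n_individuals=("individual", "nunique"),
        )
        .reset_index()
    )
    grouped["xci_status"] = [classify_xci_gene_tissue(s) for s in grouped["statuses"]]
    grouped = grouped.drop(columns=["statuses"])
    merged = grouped.merge(
        sexbias[["gene_id", "tissue", "beta_mash", "lfsr"]],
        on=["gene_id", "tissue"],
        how="left",
    )
    merged = merged.merge(annotation[["gene_id", "region"]], on="gene_id", how="left")
    bias = []
    for b, l in zip(merged["beta_mash"], merged["lfsr"]):
        if pd.isna(b) or pd.isna(l):
            bias.append("unbiased")
        else:
            bias.append(classify_sex_bias(float(b), float(l), t))
    merged["bias_status"] = bias
    return merged


def crosstab(
    statuses: pd.DataFrame,
    region_filter: str | Sequence[str] | None = None,
) -> pd.DataFrame:
    """XCI-status x bias-status contingency table over gene x tissue pairs.

    region_filter may be a single region class, a sequence of classes, or the
    shorthand 'PAR' (= PAR1 + PAR2). Cell counts partition the filtered input
    exactly; rows/columns with zero counts are retained.
    """
    df = statuses
    if region_filter is not None:
        regions = _expand_region(region_filter)
        df = df[df["region"].isin(regions)]
    table = pd.crosstab(df["xci_status"], df["bias_status"]) if len(df) else pd.DataFrame()
    table = table.reindex(index=XCI_STATUSES, columns=BIAS_STATUSES, fill_value=0)
    table = table.fillna(0).astype(int)
    table.index.name = "xci_status"
    table.columns.name = "bias_status"
    return table


def _expand_region(region_filter) -> list[str]:
    if isinstance(region_filter, str):
        if region_filter == "PAR":
            return ["PAR1", "PAR2"]
        return [region_filter]
    out: list[str] = []
    for r in region_filter:
        out.extend(_expand_region(r))
    return out


# ---------------------------------------------------------------------------
# Categorical tests
# ---------------------------------------------------------------------------

def binomial_greater(successes: int, n: int, p0: float = 0.5) -> CategoricalTestResult:
    """Exact one-sided binomial test P(X >= successes | n, p0)."""
    if not 0 <= successes <= n:
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    res = stats.binomtest(successes, n, p0, alternative="greater")
    return CategoricalTestResult(
        test_name="binomial",
        statistic=float(successes),
        p_value=float(res.pvalue),
        estimate=successes / n,
        n=n,
        alternative="greater",
    )


def fisher_2x2(table) -> CategoricalTestResult:
    """Two-sided Fisher exact test with a conditional-MLE odds ratio.

    A table with a zero cell yields an estimate of 0 or inf (flagged via
    ``estimate_infinite``) rather than an error; an all-zero table is invalid.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    # conditional-MLE odds ratio, the estimator R's fisher.test reports;
    # zero cells yield 0 or inf rather than an error
    estimate = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    return CategoricalTestResult(
        test_name="fisher",
        statistic=estimate,
        p_value=float(min(p, 1.0)),
        estimate=estimate,
        n=int(arr.sum()),
        alternative="two_sided",
        table=arr.tolist(),
    )


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> CategoricalTestResult:
    """Welch unequal-variance two-sample t-test (two-sided)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return CategoricalTestResult(
                test_name="welch_t", statistic=0.0, p_value=1.0,
                estimate=0.0, n=len(a) + len(b), alternative="two_sided",
            )
        raise ValueError("both groups are constant; Welch t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return CategoricalTestResult(
        test_name="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        estimate=float(a.mean() - b.mean()),
        n=len(a) + len(b),
        alternative="two_sided",
    )
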