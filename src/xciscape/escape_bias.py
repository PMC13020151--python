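"""Coupling between the magnitude of XCI escape and sex-biased expression.

Observations are gene x tissue x individual allelic-expression values joined
to gene x tissue sex effects (beta_mash, LFSR). Each region x bias-direction
analysis splits observations into an escape side (1-AE >= 0.6) and a
silenced side (1-AE < 0.6); within each quadrant the Spearman correlation of
1-AE against beta_mash measures whether stronger escape predicts stronger
bias. The four quadrants of interest are (PAR, male, escape/silenced) and
(NPX, female, escape/silenced): in both regions the escape-side correlation
is expected negative — for PAR genes, deeper silencing in females leaves
relatively more male expression; for NPX genes, fuller escape adds female
expression.

Spearman p-values use the asymptotic t approximation for n >= 10 and exact
permutation enumeration below that, where the approximation is unreliable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CategoricalTestResult, fisher_2x2
from .config import Thresholds

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_N = 10  # below this, enumerate permutations for the p-value

QUADRANTS = (
    ("PAR", "male", "escape"),
    ("PAR", "male", "silenced"),
    ("NPX", "female", "escape"),
    ("NPX", "female", "silenced"),
)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class QuadrantSpec:
    """One region x bias-direction x XCI-side stratum."""

    region: str  # 'PAR' (PAR1 + PAR2) or 'NPX'
    bias_direction: str  # 'male' or 'female'
    xci_side: str  # 'escape' (1-AE >= threshold) or 'silenced'

    def __post_init__(self) -> None:
        if self.region not in ("PAR", "NPX"):
            raise ValueError(f"region must be PAR or NPX, got {self.region!r}")
        if self.bias_direction not in ("male", "female"):
            raise ValueError(f"bias_direction must be male or female")
        if self.xci_side not in ("escape", "silenced"):
            raise ValueError(f"xci_side must be escape or silenced")

    @property
    def label(self) -> str:
        return f"{self.region}_{self.bias_direction}_{self.xci_side}"


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (midrank ties) and two-sided p.

    Exact permutation p by full enumeration when n < 10; the asymptotic
    t approximation otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(xa).size < 2 or np.unique(ya).size < 2:
        raise ValueError("constant input; Spearman correlation undefined")
    rho = float(stats.spearmanr(xa, ya).statistic)
    if n >= EXACT_SPEARMAN_N:
        p = float(stats.spearmanr(xa, ya).pvalue)
    else:
        rx = stats.rankdata(xa)
        ry = stats.rankdata(ya)
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rx[perms] @ ry) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, min(p, 1.0)


# ---------------------------------------------------------------------------
# Observation assembly and quadrant filtering
# ---------------------------------------------------------------------------

def join_observations(
    ae: pd.DataFrame,
    sexbias: pd.DataFrame,
    annotation: pd.DataFrame,
    average_individuals: bool = False,
) -> pd.DataFrame:
    """Join AE observations to sex-bias estimates and region classes.

    By default every individual-level AE observation contributes one row, so
    a gene x tissue pair with several informative individuals appears several
    times; ``average_individuals`` collapses to one row per gene x tissue.
    """
    df = ae.copy()
    if average_individuals:
        df = df.groupby(["gene_id", "tissue"], as_index=False)["ae"].mean()
    df["one_minus_ae"] = 1.0 - df["ae"].astype(float)
    keep = [c for c in ("beta_mash", "lfsr", "mean_expression") if c in sexbias.columns]
    out = df.merge(sexbias[["gene_id", "tissue", *keep]], on=["gene_id", "tissue"], how="inner")
    out = out.merge(annotation[["gene_id", "region"]], on="gene_id", how="left")
    out["region_class"] = np.where(out["region"].isin(["PAR1", "PAR2"]), "PAR", "NPX")
    return out


def filter_quadrant(
    obs: pd.DataFrame, spec: QuadrantSpec, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Rows of ``obs`` falling in one quadrant.

    Requires significant bias in the spec's direction (lfsr < threshold and
    the matching beta sign) and the spec's side of the escape threshold.
    """
    t = thresholds or Thresholds()
    df = obs[obs["region_class"] == spec.region]
    sig = df["lfsr"] < t.lfsr
    if spec.bias_direction == "male":
        sig &= df["beta_mash"] > 0
    else:
        sig &= df["beta_mash"] < 0
    side = (
        df["one_minus_ae"] >= t.escape_one_minus_ae
        if spec.xci_side == "escape"
        else df["one_minus_ae"] < t.escape_one_minus_ae
    )
    return df[sig & side]


def quadrant_correlation(
    obs: pd.DataFrame, spec: QuadrantSpec, thresholds: Thresholds | None = None
) -> CorrelationResult:
    """Spearman correlation of 1-AE against beta_mash within one quadrant."""
    sub = filter_quadrant(obs, spec, thresholds)
    sub = sub.dropna(subset=["one_minus_ae", "beta_mash"])
    if len(sub) < 3:
        raise ValueError(f"quadrant {spec.label}: only {len(sub)} observations (< 3)")
    rho, p = spearman(sub["one_minus_ae"], sub["beta_mash"])
    return CorrelationResult(rho=rho, p_value=p, n=len(sub), group_label=spec.label)


def per_unit_correlations(
    obs: pd.DataFrame,
    unit: str,
    spec: QuadrantSpec,
    thresholds: Thresholds | None = None,
    min_n: int = 4,
) -> tuple[list[CorrelationResult], dict]:
    """One 1-AE vs beta correlation per gene or per tissue within a quadrant.

    Strata with fewer than ``min_n`` complete pairs, or with a constant
    variable, are skipped with a logged reason. The summary counts strata
    with rho < 0 and p < 0.05 — the paper-style 'relationship holds within
    k / m strata' statement.
    """
    if unit not in ("gene", "tissue"):
        raise ValueError(f"unit must be 'gene' or 'tissue', got {unit!r}")
    key = "gene_id" if unit == "gene" else "tissue"
    sub = filter_quadrant(obs, spec, thresholds).dropna(subset=["one_minus_ae", "beta_mash"])
    results: list[CorrelationResult] = []
    skipped = 0
    for label, grp in sub.groupby(key, sort=True):
        if len(grp) < min_n:
            logger.info("stratum %s skipped: n=%d < %d", label, len(grp), min_n)
            skipped += 1
            continue
        try:
            rho, p = spearman(grp["one_minus_ae"], grp["beta_mash"])
        except ValueError as exc:
            logger.info("stratum %s skipped: %s", label, exc)
            skipped += 1
            continue
        results.append(CorrelationResult(rho=rho, p_value=p, n=len(grp), group_label=str(label)))
    summary = {
        "n_strata": len(results),
        "n_skipped": skipped,
        "n_negative_significant": sum(1 for r in results if r.rho < 0 and r.p_value < 0.05),
    }
    return results, summary


def tissue_rank_analysis(
    obs: pd.DataFrame, spec: QuadrantSpec, thresholds: Thresholds | None = None
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Correlate per-tissue median sex bias against per-tissue median escape.

    Within one quadrant, each tissue contributes (median beta_mash,
    median 1-AE) over its qualifying observations; the result is the Spearman
    correlation of the two medians across tissues.
    """
    sub = filter_quadrant(obs, spec, thresholds).dropna(subset=["one_minus_ae", "beta_mash"])
    med = (
        sub.groupby("tissue")
        .agg(median_beta=("beta_mash", "median"), median_one_minus_ae=("one_minus_ae", "median"),
             n=("beta_mash", "size"))
        .reset_index()
    )
    if len(med) < 3:
        raise ValueError(f"quadrant {spec.label}: only {len(med)} tissues (< 3)")
    rho, p = spearman(med["median_one_minus_ae"], med["median_beta"])
    return (
        CorrelationResult(rho=rho, p_value=p, n=len(med), group_label=f"{spec.label}_tissues"),
        med,
    )


def expression_level_correlations(
    obs: pd.DataFrame, thresholds: Thresholds | None = None
) -> dict[str, pd.DataFrame]:
    """3x3 Spearman matrix of (beta_mash, 1-AE, mean expression) per quadrant.

    ``obs`` must carry a mean_expression column. Each of the four analysis
    quadrants yields a symmetric rho matrix with unit diagonal (and a
    parallel matrix of p-values stored under '<label>_p').
    """
    if "mean_expression" not in obs.columns:
        raise ValueError("observations lack a mean_expression column")
    variables = ["beta_mash", "one_minus_ae", "mean_expression"]
    out: dict[str, pd.DataFrame] = {}
    for region, direction, side in QUADRANTS:
        spec = QuadrantSpec(region, direction, side)
        sub = filter_quadrant(obs, spec, thresholds).dropna(subset=variables)
        rho_m = pd.DataFrame(np.eye(3), index=variables, columns=variables)
        p_m = pd.DataFrame(np.zeros((3, 3)), index=variables, columns=variables)
        for a, b in itertools.combinations(variables, 2):
            if len(sub) < 3:
                rho_m.loc[a, b] = rho_m.loc[b, a] = np.nan
                p_m.loc[a, b] = p_m.loc[b, a] = np.nan
                continue
            try:
                rho, p = spearman(sub[a], sub[b])
            except ValueError:
                rho, p = np.nan, np.nan
            rho_m.loc[a, b] = rho_m.loc[b, a] = rho
            p_m.loc[a, b] = p_m.loc[b, a] = p
        out[spec.label] = rho_m
        out[spec.label + "_p"] = p_m
    return out


# ---------------------------------------------------------------------------
# Enhancer proximity
# ---------------------------------------------------------------------------

def enhancer_proximity_overlap(
    gene_set: Iterable[str],
    ares: pd.DataFrame,
    direction: str,
    universe: Iterable[str],
    thresholds: Thresholds | None = None,
) -> CategoricalTestResult:
    """Fisher test: is ``gene_set`` enriched near sex-biased enhancers?

    AREs are filtered to adjusted p < threshold and the requested sex-effect
    sign (positive = male-biased activity). The 2x2 table over the gene
    universe crosses membership in ``gene_set`` with being the nearest gene
    of at least one qualifying element.
    """
    if direction not in ("male", "female"):
        raise ValueError(f"direction must be male or female, got {direction!r}")
    t = thresholds or Thresholds()
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    gset = set(gene_set) & uni
    if set(gene_set) - uni:
        logger.warning(
            "%d gene_set members outside the universe were dropped",
            len(set(gene_set) - uni),
        )
    sig = ares[ares["p_adj"] < t.are_p_adj]
    sig = sig[sig["sex_effect"] > 0] if direction == "male" else sig[sig["sex_effect"] < 0]
    near = set(sig["nearest_gene"]) & uni
    a = len(gset & near)
    b = len(gset - near)
    c = len(near - gset)
    d = len(uni - gset - near)
    return fisher_2x2([[a, b], [c, d]])
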