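"""TAD-resolved similarity of XCI escape: permutation tests and ANOVA.

The core question: do genes sharing a topologically associating domain (TAD)
show more similar allelic expression than genes in different TADs? For every
pair of distinct genes the distance is |AE_a - AE_b|; pairs are labeled
within-TAD or between-TAD, and the observed difference in median pairwise
distance (within minus between) is compared against a null built by randomly
shuffling the gene -> TAD assignment (preserving TAD sizes). A negative
observed difference that no shuffle matches gives an empirical p of 0.

Two complementary views of chromosome-scale organization are also provided:
a Wilcoxon comparison of adjacent- versus non-adjacent-TAD pair distances, a
Spearman correlation of pair distance against TAD rank gap, and a sequential
ANOVA (factor order TAD, gene, tissue) with Tukey HSD on TAD means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed median-distance difference against its shuffled-label null."""

    observed: float
    null_values: np.ndarray
    p_empirical: float
    n_perm: int
    seed: int
    median_within: float
    median_between: float
    alternative: str = "less"
    corrected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_empirical <= 1.0:
            raise ValueError(f"p_empirical {self.p_empirical} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "median_within": self.median_within,
            "median_between": self.median_between,
            "alternative": self.alternative,
            "corrected": self.corrected,
        }


# ---------------------------------------------------------------------------
# Gene -> TAD assignment
# ---------------------------------------------------------------------------

def assign_genes_to_tads(genes: pd.DataFrame, tads: pd.DataFrame) -> pd.Series:
    """Map each gene to the TAD containing its interval midpoint.

    Genes whose midpoint falls in no TAD get NaN (excluded downstream). If
    overlapping TADs both contain a midpoint, the TAD with the smaller start
    wins and a warning is logged.
    """
    out = {}
    t_start = tads["start"].to_numpy()
    t_end = tads["end"].to_numpy()
    t_id = tads["tad_id"].to_numpy()
    order = np.argsort(t_start, kind="stable")
    t_start, t_end, t_id = t_start[order], t_end[order], t_id[order]
    for _, g in genes.iterrows():
        mid = (int(g["start"]) + int(g["end"])) // 2
        hits = np.nonzero((t_start <= mid) & (mid < t_end))[0]
        if hits.size == 0:
            out[g["gene_id"]] = np.nan
        else:
            if hits.size > 1:
                logger.warning(
                    "gene %s midpoint %d inside %d overlapping TADs; using %s",
                    g["gene_id"], mid, hits.size, t_id[hits[0]],
                )
            out[g["gene_id"]] = t_id[hits[0]]
    return pd.Series(out, name="tad_id")


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

def _pair_arrays(values, assignment):
    """Condensed pair index arrays and distances for the permutation engine.

    ``values`` is either a Series indexed by gene_id (one value per gene) or
    a DataFrame gene x tissue (NaN = gene not measured in that tissue), in
    which case pairs are formed within each tissue and pooled. Returns
    (gene_ids, labels, pair_i, pair_j, dist).
    """
    if isinstance(values, pd.DataFrame):
        frame = values
    else:
        frame = pd.Series(values).to_frame("value")
    genes = [g for g in frame.index if g in assignment and pd.notna(assignment[g])]
    frame = frame.loc[genes]
    labels = np.asarray([assignment[g] for g in genes], dtype=object)
    pair_i: list[np.ndarray] = []
    pair_j: list[np.ndarray] = []
    dists: list[np.ndarray] = []
    n = len(genes)
    for col in frame.columns:
        v = frame[col].to_numpy(dtype=float)
        present = np.nonzero(~np.isnan(v))[0]
        if present.size < 2:
            continue
        ii, jj = np.triu_indices(present.size, k=1)
        gi, gj = present[ii], present[jj]
        pair_i.append(gi)
        pair_j.append(gj)
        dists.append(np.abs(v[gi] - v[gj]))
    if not pair_i:
        return genes, labels, np.empty(0, int), np.empty(0, int), np.empty(0)
    return (
        genes,
        labels,
        np.concatenate(pair_i),
        np.concatenate(pair_j),
        np.concatenate(dists),
    )


def pairwise_distances(
    values,
    assignment: Mapping[str, str],
    tad_ranks: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """All unordered pairs of distinct assigned genes with |AE| distances.

    Returns a frame with gene_a, gene_b, distance, relation (within_tad /
    between_tad) and tad_rank_gap (0 for same TAD; requires ``tad_ranks``
    for between-TAD gaps, else NaN). With a gene x tissue DataFrame input a
    ``tissue`` column records which tissue each pair came from.
    """
    is_frame = isinstance(values, pd.DataFrame)
    frame = values if is_frame else pd.Series(values).to_frame("value")
    genes, labels, pi, pj, dist = _pair_arrays(frame, assignment)
    gene_arr = np.asarray(genes, dtype=object)
    rows = {
        "gene_a": gene_arr[pi],
        "gene_b": gene_arr[pj],
        "distance": dist,
    }
    if is_frame:
        # reconstruct tissue of each pair in the same order _pair_arrays emits
        tissues = []
        sub = frame.loc[genes]
        for col in sub.columns:
            v = sub[col].to_numpy(dtype=float)
            m = int(np.sum(~np.isnan(v)))
            if m >= 2:
                tissues.extend([col] * (m * (m - 1) // 2))
        rows["tissue"] = tissues
    out = pd.DataFrame(rows)
    la, lb = labels[pi], labels[pj]
    out["tad_a"] = la
    out["tad_b"] = lb
    within = la == lb
    out["relation"] = np.where(within, "within_tad", "between_tad")
    if tad_ranks is not None:
        ra = np.asarray([tad_ranks[t] for t in la], dtype=float)
        rb = np.asarray([tad_ranks[t] for t in lb], dtype=float)
        out["tad_rank_gap"] = np.abs(ra - rb).astype(int)
    else:
        out["tad_rank_gap"] = np.where(within, 0, np.nan)
    return out


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def _median_diff(dist, within_mask):
    return float(np.median(dist[within_mask]) - np.median(dist[~within_mask]))


def tad_permutation_test(
    values,
    assignment: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 1,
    alternative: str = "less",
    corrected: bool = False,
) -> PermutationResult:
    """Shuffle gene -> TAD labels and compare the median-distance difference.

    The statistic is median(within-TAD distances) - median(between-TAD
    distances). Each permutation reassigns the multiset of TAD labels across
    genes, recomputes pair relations, and recomputes the statistic. With
    alternative='less' (genes within a TAD more similar than between), the
    empirical p is the fraction of null statistics <= the observed one;
    ``corrected`` switches to the (b + 1) / (n_perm + 1) estimator.
    """
    if alternative not in ("less", "greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    genes, labels, pi, pj, dist = _pair_arrays(values, assignment)
    if dist.size == 0:
        raise ValueError("fewer than 2 genes with values and TAD assignments")
    if len(set(labels.tolist())) < 2:
        raise ValueError("all genes fall in a single TAD; between-TAD side is empty")
    within = labels[pi] == labels[pj]
    if not within.any():
        raise ValueError("no within-TAD pair in the observed labeling")
    observed = _median_diff(dist, within)
    median_within = float(np.median(dist[within]))
    median_between = float(np.median(dist[~within]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(labels)
        w = perm[pi] == perm[pj]
        null[k] = _median_diff(dist, w)
    if alternative == "less":
        b = int(np.sum(null <= observed))
    elif alternative == "greater":
        b = int(np.sum(null >= observed))
    else:
        center = float(np.median(null))
        b = int(np.sum(np.abs(null - center) >= abs(observed - center)))
    p = (b + 1) / (n_perm + 1) if corrected else b / n_perm
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_empirical=float(min(p, 1.0)),
        n_perm=n_perm,
        seed=seed,
        median_within=median_within,
        median_between=median_between,
        alternative=alternative,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Adjacent vs non-adjacent TADs and rank-distance decay
# ---------------------------------------------------------------------------

def adjacency_analysis(
    values,
    assignment: Mapping[str, str],
    tad_ranks: Mapping[str, int],
) -> dict:
    """Compare distances of gene pairs in adjacent vs non-adjacent TADs.

    Uses between-TAD pairs only, split by rank gap == 1 versus > 1, with a
    two-sided Wilcoxon rank-sum (Mann-Whitney) test.
    """
    pairs = pairwise_distances(values, assignment, tad_ranks)
    between = pairs[pairs["relation"] == "between_tad"]
    adj = between.loc[between["tad_rank_gap"] == 1, "distance"].to_numpy()
    non = between.loc[between["tad_rank_gap"] > 1, "distance"].to_numpy()
    if adj.size == 0 or non.size == 0:
        raise ValueError(
            f"need both adjacent and non-adjacent between-TAD pairs "
            f"(got {adj.size} adjacent, {non.size} non-adjacent)"
        )
    if np.all(adj == adj[0]) and np.all(non == non[0]) and adj[0] == non[0]:
        w, p = float(adj.size * non.size / 2.0), 1.0
    else:
        res = stats.mannwhitneyu(adj, non, alternative="two-sided", method="auto")
        w, p = float(res.statistic), float(res.pvalue)
    return {
        "mean_adjacent": float(adj.mean()),
        "mean_nonadjacent": float(non.mean()),
        "n_adjacent": int(adj.size),
        "n_nonadjacent": int(non.size),
        "wilcoxon_W": w,
        "p": p,
    }


def rank_distance_correlation(
    values,
    assignment: Mapping[str, str],
    tad_ranks: Mapping[str, int],
):
    """Spearman correlation of pair distance against TAD rank gap.

    Uses between-TAD pairs only; a larger gap (more TADs between two genes)
    predicting a larger allelic-expression distance gives a positive rho.
    """
    from .escape_bias import CorrelationResult, spearman

    pairs = pairwise_distances(values, assignment, tad_ranks)
    between = pairs[pairs["relation"] == "between_tad"]
    gaps = between["tad_rank_gap"].to_numpy(dtype=float)
    dist = between["distance"].to_numpy(dtype=float)
    if np.unique(gaps).size < 2:
        raise ValueError("need at least 2 distinct TAD rank gaps")
    if np.unique(dist).size < 2:
        raise ValueError("pair distances are constant; correlation undefined")
    rho, p = spearman(gaps, dist)
    return CorrelationResult(rho=rho, p_value=p, n=int(gaps.size), group_label="rank_gap")


# ---------------------------------------------------------------------------
# ANOVA with sequential sums of squares + Tukey HSD
# ---------------------------------------------------------------------------

def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    d = np.zeros((codes.size, n_levels))
    d[np.arange(codes.size), codes] = 1.0
    return d[:, 1:]  # drop first level; intercept carries it


def tad_anova(records: pd.DataFrame) -> dict:
    """Sequential (type-I) ANOVA of 1-AE on TAD, gene and tissue, + Tukey HSD.

    ``records`` needs a one_minus_ae and a tad column; gene and tissue
    factors are included when present. Factors enter in the fixed order TAD,
    gene, tissue, so TAD absorbs shared variance first; gene is typically
    nested within TAD, which aliases part of the gene factor — aliased
    degrees of freedom are reported in ``aliased`` rather than raising.
    """
    factors = [c for c in ("tad", "gene", "tissue") if c in records.columns]
    df = records.dropna(subset=["one_minus_ae", *factors])
    y = df["one_minus_ae"].to_numpy(dtype=float)
    n = y.size
    if df["tad"].nunique() < 2:
        raise ValueError("need at least 2 TADs")
    blocks = []
    for factor in factors:
        codes, levels = pd.factorize(df[factor], sort=True)
        blocks.append((factor, _dummies(codes, len(levels)), len(levels)))

    X = np.ones((n, 1))
    yc = y - y.mean()
    total_ss = float(yc @ yc)
    rss_prev = total_ss
    rank_prev = 1
    rows = []
    aliased = {}
    for factor, block, n_levels in blocks:
        X = np.hstack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        df_factor = rank - rank_prev
        nominal_df = n_levels - 1
        if df_factor < nominal_df:
            aliased[factor] = nominal_df - df_factor
        rows.append({"factor": factor, "ss": rss_prev - rss, "df": df_factor})
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    table = []
    for r in rows:
        ms = r["ss"] / r["df"] if r["df"] > 0 else np.nan
        F = ms / ms_resid if r["df"] > 0 else np.nan
        p = float(stats.f.sf(F, r["df"], df_resid)) if r["df"] > 0 else np.nan
        table.append({**r, "ms": ms, "F": F, "p": p})
    anova = pd.DataFrame(table).set_index("factor")
    anova.loc["residual"] = {"ss": rss_prev, "df": df_resid, "ms": ms_resid,
                             "F": np.nan, "p": np.nan}

    tukey = None
    counts = df.groupby("tad").size()
    if (counts >= 2).all() and df_resid >= 1 and df["tad"].nunique() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hsd = pairwise_tukeyhsd(y, df["tad"].to_numpy())
        tukey = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
    return {
        "anova": anova,
        "tukey": tukey,
        "total_ss": total_ss,
        "aliased": aliased,
    }


# ---------------------------------------------------------------------------
# pair_unit plumbing
# ---------------------------------------------------------------------------

def values_for_pair_unit(ae: pd.DataFrame, pair_unit: str = "gene_mean"):
    """Collapse an AE table to the pairwise-analysis unit.

    'gene_mean' averages AE per gene across tissues and individuals, giving
    a Series indexed by gene; 'gene_tissue' averages per gene x tissue
    (across individuals) and returns a gene x tissue DataFrame so that pairs
    form within each tissue and pool across tissues.
    """
    if pair_unit == "gene_mean":
        return ae.groupby("gene_id")["ae"].mean()
    if pair_unit == "gene_tissue":
        return ae.groupby(["gene_id", "tissue"])["ae"].mean().unstack("tissue")
    raise ValueError(f"unknown pair_unit {pair_unit!r}")
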