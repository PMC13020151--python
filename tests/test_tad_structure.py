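"""Gene->TAD assignment, pairwise distances, permutation test, ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xciscape import tad_structure as ts


def make_tads(bounds):
    return pd.DataFrame(
        {
            "tad_id": [f"T{i + 1}" for i in range(len(bounds))],
            "start": [b[0] for b in bounds],
            "end": [b[1] for b in bounds],
            "rank": list(range(1, len(bounds) + 1)),
        }
    )


def make_genes(spec):
    return pd.DataFrame(
        {"gene_id": [s[0] for s in spec], "start": [s[1] for s in spec],
         "end": [s[2] for s in spec]}
    )


class TestAssignment:
    def test_midpoint_containment(self):
        tads = make_tads([(0, 500)])
        genes = make_genes([("g1", 100, 200)])
        out = ts.assign_genes_to_tads(genes, tads)
        assert out["g1"] == "T1"

    def test_gap_unassigned(self):
        tads = make_tads([(0, 100), (300, 400)])
        genes = make_genes([("g1", 150, 250)])  # midpoint 200 in the gap
        out = ts.assign_genes_to_tads(genes, tads)
        assert pd.isna(out["g1"])

    def test_boundary_spanning_gene_uses_midpoint(self):
        tads = make_tads([(0, 100), (100, 200)])
        # spans the boundary; midpoint 90 sits left of it
        genes = make_genes([("g1", 60, 120)])
        out = ts.assign_genes_to_tads(genes, tads)
        assert out["g1"] == "T1"

    def test_overlapping_tads_pick_smaller_start(self, caplog):
        tads = make_tads([(0, 300), (100, 400)])
        genes = make_genes([("g1", 180, 220)])  # midpoint 200 inside both
        with caplog.at_level("WARNING"):
            out = ts.assign_genes_to_tads(genes, tads)
        assert out["g1"] == "T1"
        assert any("overlapping" in r.message for r in caplog.records)


class TestPairwiseDistances:
    def test_three_genes_three_pairs(self):
        values = pd.Series({"A": 0.1, "B": 0.3, "C": 0.35})
        assignment = {"A": "T1", "B": "T1", "C": "T2"}
        pairs = ts.pairwise_distances(values, assignment)
        assert len(pairs) == 3
        within = pairs[pairs["relation"] == "within_tad"]["distance"].tolist()
        between = sorted(pairs[pairs["relation"] == "between_tad"]["distance"].tolist())
        assert within == pytest.approx([0.2])
        assert between == pytest.approx([0.05, 0.25])

    def test_equal_values_zero_distances(self):
        values = pd.Series({"A": 0.2, "B": 0.2, "C": 0.2})
        pairs = ts.pairwise_distances(values, {"A": "T1", "B": "T1", "C": "T2"})
        assert pairs["distance"].tolist() == pytest.approx([0.0, 0.0, 0.0])

    def test_pair_count_and_partition(self, rng):
        n = 12
        values = pd.Series(rng.uniform(0, 0.5, n), index=[f"g{i}" for i in range(n)])
        assignment = {f"g{i}": f"T{i % 3}" for i in range(n)}
        pairs = ts.pairwise_distances(values, assignment)
        assert len(pairs) == n * (n - 1) // 2
        counts = pairs["relation"].value_counts()
        assert counts.sum() == len(pairs)
        # within iff rank gap is zero
        assert ((pairs["tad_rank_gap"] == 0) == (pairs["relation"] == "within_tad")).all()

    def test_gene_tissue_unit_pools_within_tissue_pairs(self):
        frame = pd.DataFrame(
            {"t1": [0.1, 0.2, np.nan], "t2": [0.3, 0.1, 0.2]},
            index=["A", "B", "C"],
        )
        pairs = ts.pairwise_distances(frame, {"A": "T1", "B": "T1", "C": "T2"})
        # t1 contributes C(2,2)=1 pair, t2 C(3,2)=3 pairs
        assert len(pairs) == 4
        assert sorted(pairs["tissue"].tolist()) == ["t1", "t2", "t2", "t2"]


def exhaustive_permutation_p(values, assignment, alternative="less"):
    """Exact p over all orderings of the TAD label multiset (oracle)."""
    genes = list(values.index)
    labels = [assignment[g] for g in genes]
    v = values.to_numpy()
    ii, jj = np.triu_indices(len(genes), k=1)
    dist = np.abs(v[ii] - v[jj])

    def diff(lab):
        lab = np.asarray(lab, dtype=object)
        w = lab[ii] == lab[jj]
        return np.median(dist[w]) - np.median(dist[~w])

    observed = diff(labels)
    diffs = [diff(p) for p in itertools.permutations(labels)]
    if alternative == "less":
        return float(np.mean([d <= observed + 1e-12 for d in diffs]))
    return float(np.mean([d >= observed - 1e-12 for d in diffs]))


class TestPermutationTest:
    def test_strong_structure_gives_zero_p(self, rng):
        # tight within-TAD values, far-apart TAD means
        values, assignment = {}, {}
        for t, center in enumerate([0.05, 0.25, 0.45]):
            for k in range(5):
                g = f"g{t}_{k}"
                values[g] = center + rng.normal(0, 0.002)
                assignment[g] = f"T{t}"
        res = ts.tad_permutation_test(pd.Series(values), assignment, n_perm=500, seed=3)
        assert res.median_within < res.median_between
        assert res.p_empirical == 0.0

    def test_monte_carlo_matches_exhaustive_small(self, rng):
        values = pd.Series(rng.uniform(0, 0.5, 6), index=list("ABCDEF"))
        assignment = dict(zip("ABCDEF", ["T1", "T1", "T2", "T2", "T3", "T3"]))
        p_exact = exhaustive_permutation_p(values, assignment)
        n_perm = 4000
        res = ts.tad_permutation_test(values, assignment, n_perm=n_perm, seed=11)
        tol = 3 * math.sqrt(max(p_exact * (1 - p_exact), 1e-4) / n_perm)
        assert res.p_empirical == pytest.approx(p_exact, abs=tol)

    def test_label_exchangeability(self, rng):
        """Re-labeling genes before testing leaves the p-value unchanged."""
        n = 10
        values = pd.Series(rng.uniform(0, 0.5, n), index=[f"g{i}" for i in range(n)])
        assignment = {f"g{i}": f"T{i % 3}" for i in range(n)}
        res1 = ts.tad_permutation_test(values, assignment, n_perm=300, seed=5)
        perm = rng.permutation(n)
        renamed = {f"g{i}": f"h{perm[i]}" for i in range(n)}
        values2 = pd.Series({renamed[g]: v for g, v in values.items()})
        assignment2 = {renamed[g]: t for g, t in assignment.items()}
        res2 = ts.tad_permutation_test(values2, assignment2, n_perm=300, seed=5)
        assert res2.observed == pytest.approx(res1.observed, abs=1e-12)

    def test_single_tad_rejected(self):
        values = pd.Series({"A": 0.1, "B": 0.2})
        with pytest.raises(ValueError):
            ts.tad_permutation_test(values, {"A": "T1", "B": "T1"}, n_perm=10, seed=1)

    def test_corrected_p_never_zero(self, rng):
        values, assignment = {}, {}
        for t, center in enumerate([0.05, 0.45]):
            for k in range(4):
                g = f"g{t}_{k}"
                values[g] = center + rng.normal(0, 0.001)
                assignment[g] = f"T{t}"
        res = ts.tad_permutation_test(
            pd.Series(values), assignment, n_perm=200, seed=2, corrected=True
        )
        # shuffles reproducing the observed split tie with it, so the
        # corrected p sits near 2/70 (the 8-choose-4 split probability)
        # but can never reach zero
        assert 1 / 201 <= res.p_empirical < 0.06


class TestAdjacency:
    def _three_tad_setup(self):
        values = pd.Series(
            {"a1": 0.10, "a2": 0.12, "b1": 0.20, "b2": 0.22, "c1": 0.40, "c2": 0.42}
        )
        assignment = {"a1": "T1", "a2": "T1", "b1": "T2", "b2": "T2", "c1": "T3", "c2": "T3"}
        ranks = {"T1": 1, "T2": 2, "T3": 3}
        return values, assignment, ranks

    def test_hand_enumerated_means(self):
        values, assignment, ranks = self._three_tad_setup()
        out = ts.adjacency_analysis(values, assignment, ranks)
        # adjacent pairs: T1-T2 (4 pairs, dists .10 .12 .08 .10) and
        # T2-T3 (4 pairs, dists .20 .22 .18 .20); non-adjacent: T1-T3
        # (4 pairs, dists .30 .32 .28 .30)
        assert out["n_adjacent"] == 8 and out["n_nonadjacent"] == 4
        assert out["mean_adjacent"] == pytest.approx(0.15)
        assert out["mean_nonadjacent"] == pytest.approx(0.30)

    def test_all_equal_values(self):
        values = pd.Series({"a": 0.2, "b": 0.2, "c": 0.2})
        assignment = {"a": "T1", "b": "T2", "c": "T3"}
        out = ts.adjacency_analysis(values, assignment, {"T1": 1, "T2": 2, "T3": 3})
        assert out["mean_adjacent"] == out["mean_nonadjacent"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_monotone_gradient_adjacent_closer(self, rng):
        genes = {f"g{i}": 0.05 * i + rng.normal(0, 1e-4) for i in range(9)}
        assignment = {f"g{i}": f"T{i // 3}" for i in range(9)}
        ranks = {"T0": 1, "T1": 2, "T2": 3}
        out = ts.adjacency_analysis(pd.Series(genes), assignment, ranks)
        assert out["mean_adjacent"] < out["mean_nonadjacent"]

    def test_missing_side_rejected(self):
        values = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4})
        assignment = {"a": "T1", "b": "T1", "c": "T2", "d": "T2"}
        with pytest.raises(ValueError):
            ts.adjacency_analysis(values, assignment, {"T1": 1, "T2": 2})


class TestRankDistanceCorrelation:
    def test_monotone_rho_one(self):
        # arithmetic progression: equal gaps give tied distances, so the
        # midranks of gap and distance agree exactly
        values = pd.Series({"a": 0.0, "b": 0.25, "c": 0.5, "d": 0.75})
        assignment = {"a": "T1", "b": "T2", "c": "T3", "d": "T4"}
        ranks = {"T1": 1, "T2": 2, "T3": 3, "T4": 4}
        res = ts.rank_distance_correlation(values, assignment, ranks)
        assert res.rho == pytest.approx(1.0)

    def test_independent_near_zero_on_average(self, rng):
        rhos = []
        for _ in range(60):
            n = 12
            values = pd.Series(rng.uniform(0, 0.5, n), index=[f"g{i}" for i in range(n)])
            assignment = {f"g{i}": f"T{i % 4}" for i in range(n)}
            ranks = {f"T{k}": k + 1 for k in range(4)}
            rhos.append(ts.rank_distance_correlation(values, assignment, ranks).rho)
        assert abs(np.mean(rhos)) < 0.06

    def test_constant_rejected(self):
        values = pd.Series({"a": 0.1, "b": 0.1, "c": 0.1})
        assignment = {"a": "T1", "b": "T2", "c": "T3"}
        with pytest.raises(ValueError):
            ts.rank_distance_correlation(values, assignment, {"T1": 1, "T2": 2, "T3": 3})


class TestAnova:
    def _records(self, groups):
        """Tissue is shared across TADs; no gene factor (pure replication)."""
        rows = []
        for tad, vals in groups.items():
            for j, v in enumerate(vals):
                rows.append({"one_minus_ae": v, "tad": tad, "tissue": f"t{j}"})
        return pd.DataFrame(rows)

    def test_equal_means_f_near_zero(self):
        # equal TAD means; order scrambled so the residual is nonzero
        df = self._records({"T1": [0.6, 0.7, 0.8], "T2": [0.7, 0.6, 0.8]})
        out = ts.tad_anova(df)
        assert out["anova"].loc["tad", "F"] == pytest.approx(0.0, abs=1e-12)
        assert (out["tukey"]["p-adj"].astype(float) > 0.95).all()

    def test_two_groups_f_equals_t_squared(self, rng):
        # one-factor two-group ANOVA: F is the square of the pooled t
        a = rng.uniform(0.5, 1.0, 6)
        b = rng.uniform(0.5, 1.0, 6)
        df = pd.DataFrame(
            {
                "one_minus_ae": np.concatenate([a, b]),
                "tad": ["T1"] * 6 + ["T2"] * 6,
            }
        )
        out = ts.tad_anova(df)
        t_pooled = stats.ttest_ind(a, b, equal_var=True).statistic
        assert out["anova"].loc["tad", "F"] == pytest.approx(t_pooled**2, rel=1e-9)

    def test_balanced_three_tads_hand_computed(self):
        df = self._records({"T1": [0.6, 0.8], "T2": [0.7, 0.9], "T3": [0.9, 1.0]})
        out = ts.tad_anova(df)
        grand = np.mean([0.6, 0.8, 0.7, 0.9, 0.9, 1.0])
        ss_tad_hand = 2 * sum(
            (np.mean(v) - grand) ** 2 for v in ([0.6, 0.8], [0.7, 0.9], [0.9, 1.0])
        )
        assert out["anova"].loc["tad", "ss"] == pytest.approx(ss_tad_hand, abs=1e-12)
        assert out["total_ss"] == pytest.approx(
            sum((x - grand) ** 2 for x in [0.6, 0.8, 0.7, 0.9, 0.9, 1.0]), abs=1e-12
        )

    def test_ss_decomposition_on_random_data(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "one_minus_ae": rng.uniform(0.5, 1.0, n),
                "tad": rng.choice(["T1", "T2", "T3", "T4"], n),
                "gene": rng.choice([f"g{i}" for i in range(10)], n),
                "tissue": rng.choice(["t1", "t2", "t3"], n),
            }
        )
        out = ts.tad_anova(df)
        ss_sum = out["anova"]["ss"].sum()
        assert ss_sum == pytest.approx(out["total_ss"], abs=1e-9)

    def test_nested_gene_reported_aliased(self, rng):
        # genes strictly nested in TADs: TAD df absorbs one gene contrast per TAD
        rows = []
        for t in range(3):
            for g in range(3):
                for k in range(2):
                    rows.append(
                        {
                            "one_minus_ae": rng.uniform(0.5, 1.0),
                            "tad": f"T{t}",
                            "gene": f"T{t}_g{g}",
                            "tissue": f"s{k}",
                        }
                    )
        out = ts.tad_anova(pd.DataFrame(rows))
        assert out["aliased"].get("gene", 0) == 2  # 8 nominal df, 6 estimable

    def test_too_few_tads_rejected(self):
        df = self._records({"T1": [0.6, 0.7]})
        with pytest.raises(ValueError):
            ts.tad_anova(df)


class TestPairUnit:
    def test_gene_mean_collapses_everything(self, toy):
        vals = ts.values_for_pair_unit(toy.ae_table, "gene_mean")
        assert len(vals) == 8
        # PARG0001: AE 0.1 in every observation
        assert vals["PARG0001"] == pytest.approx(0.1)

    def test_gene_tissue_keeps_tissues_separate(self, toy):
        vals = ts.values_for_pair_unit(toy.ae_table, "gene_tissue")
        assert vals.shape == (8, 2)
        # NPXG0002 tissue01: mean of AE 0.30 and 0.45
        assert vals.loc["NPXG0002", "tissue01"] == pytest.approx(0.375)

    def test_toy_pair_count_gene_tissue(self, toy):
        vals = ts.values_for_pair_unit(toy.ae_table, "gene_tissue")
        assignment = dict(zip(toy.genes["gene_id"], toy.genes["tad_id"]))
        pairs = ts.pairwise_distances(vals, assignment)
        assert len(pairs) == 2 * (8 * 7 // 2)  # C(8,2) pairs in each of 2 tissues

    def test_unknown_unit(self, toy):
        with pytest.raises(ValueError):
            ts.values_for_pair_unit(toy.ae_table, "per_cell")
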