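"""Gene-level consolidation, presence calls, domains and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import to_tree
from scipy.spatial.distance import euclidean

from aqpmeta.consolidation import (
    AnalysisParams,
    cluster_profiles,
    condition_means,
    consolidate_matrix,
    consolidate_signal,
    expression_domain,
    median_max_divergence,
)


class TestConditionMeans:
    def test_arithmetic_mean_on_log2_scale(self, toy_design):
        matrix = pd.DataFrame(
            {"e1_control_r0": [4.0], "e1_control_r1": [6.0],
             "e1_drought_r0": [5.0], "e1_drought_r1": [5.0]},
            index=["p1"],
        )
        means = condition_means(matrix, toy_design)
        assert means.loc["p1", "control"] == 5.0
        assert means.loc["p1", "drought"] == 5.0

    def test_unknown_sample_rejected(self, toy_design):
        matrix = pd.DataFrame({"mystery": [1.0]}, index=["p1"])
        with pytest.raises(ValueError, match="missing from design"):
            condition_means(matrix, toy_design)

    def test_zero_noise_means_equal_planted_values(self, small_simulation):
        matrices, design, truth = small_simulation
        exp_id = sorted(matrices)[0]
        sub = design[design["experiment"] == exp_id]
        means = condition_means(matrices[exp_id], sub)
        tissue = sub["tissue"].iloc[0]
        species = truth.experiment_species[exp_id]
        for ps in means.index:
            gene = truth.probeset_gene[ps]
            if tissue not in truth.gene_tissues[gene]:
                continue
            for cond in means.columns:
                expected = (
                    truth.gene_baseline[gene]
                    + truth.effects.get((gene, exp_id, cond), 0.0)
                    + truth.probe_offset[ps][species]
                )
                assert means.loc[ps, cond] == pytest.approx(expected)


class TestConsolidateSignal:
    def test_max_and_presence(self):
        sig = consolidate_signal("g", "c", {"p1": 3.0, "p2": 7.2, "p3": 6.5})
        assert sig.log2_signal == 7.2 and sig.present

    def test_median_diagnostic(self):
        sig = consolidate_signal("g", "c", {"p1": 3.0, "p2": 7.2, "p3": 6.5},
                                 method="median")
        assert sig.log2_signal == 6.5

    def test_below_cutoff_absent_but_at_cutoff_present(self):
        assert not consolidate_signal("g", "c", {"p1": 2.0, "p2": 2.9}).present
        assert consolidate_signal("g", "c", {"p1": 3.2}).present

    def test_no_probe_sets_is_no_data_not_absent(self):
        sig = consolidate_signal("g", "c", {})
        assert sig.no_data and sig.log2_signal is None and not sig.present

    @given(
        st.dictionaries(
            st.sampled_from(["p1", "p2", "p3", "p4"]),
            st.floats(min_value=0.0, max_value=16.0),
            min_size=1,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_max_dominates_median(self, signals):
        mx = consolidate_signal("g", "c", signals, method="max")
        md = consolidate_signal("g", "c", signals, method="median")
        assert mx.log2_signal >= md.log2_signal
        # presence monotonicity: raising any probe signal never loses presence
        if mx.present:
            bumped = {k: v + 1.0 for k, v in signals.items()}
            assert consolidate_signal("g", "c", bumped).present


def test_median_max_divergence_flags_species_mismatch():
    """A probe set matching the hybridized species poorly drags the median to
    background while the max stays present — the flagged situation."""
    means = pd.DataFrame(
        {"c1": [7.0, 2.5], "c2": [7.1, 2.4]}, index=["pA", "pB"]
    )
    report = median_max_divergence(means, {"pA": "g1", "pB": "g1"})
    assert report["flagged"].all()
    same = pd.DataFrame({"c1": [7.0, 7.0]}, index=["pA", "pB"])
    report2 = median_max_divergence(same, {"pA": "g1", "pB": "g1"})
    assert (report2["gap"] == 0).all() and not report2["flagged"].any()


def test_no_flags_without_affinity_offsets():
    from aqpmeta.synthetic import SimulationConfig, simulate_expression
    from aqpmeta.consolidation import condition_means

    cfg = SimulationConfig(n_genes=12, n_pairs=2, noise_sd=0.0,
                           affinity_offset_sd=0.0, seed=5)
    matrices, design, truth = simulate_expression(cfg)
    for exp_id, matrix in matrices.items():
        sub = design[design["experiment"] == exp_id]
        means = condition_means(matrix, sub)
        report = median_max_divergence(means, truth.probeset_gene)
        if len(report):
            assert not report["flagged"].any()


class TestExpressionDomain:
    def test_domain_recovers_planted_tissue_sets(self, small_simulation):
        matrices, design, truth = small_simulation
        tables = []
        cond_tissue = {}
        controls = []
        for exp_id, matrix in matrices.items():
            sub = design[design["experiment"] == exp_id]
            means = condition_means(matrix, sub)
            means.columns = [f"{exp_id}:{c}" for c in means.columns]
            tables.append(consolidate_matrix(means, truth.probeset_gene))
            for _, row in sub.iterrows():
                key = f"{exp_id}:{row['condition']}"
                cond_tissue[key] = row["tissue"]
                if row["condition"] == "control":
                    controls.append(key)
        signals = pd.concat(tables, axis=1)
        domain = expression_domain(signals, cond_tissue, controls)
        for gene in domain.index:
            for tissue in domain.columns:
                present = domain.loc[gene, tissue] >= 3.2
                assert present == (tissue in truth.gene_tissues[gene])

    def test_sample_and_probe_order_invariance(self, small_simulation):
        matrices, design, truth = small_simulation
        exp_id = sorted(matrices)[0]
        sub = design[design["experiment"] == exp_id]
        matrix = matrices[exp_id]
        shuffled = matrix.iloc[::-1, ::-1]
        a = consolidate_matrix(condition_means(matrix, sub), truth.probeset_gene)
        b = consolidate_matrix(condition_means(shuffled, sub), truth.probeset_gene)
        pd.testing.assert_frame_equal(a, b)


def brute_force_complete_linkage(rows: np.ndarray) -> list[tuple[frozenset, float]]:
    """O(n^3) agglomeration oracle: merge the closest pair of clusters under
    complete linkage until one remains; record (merged leaf set, height)."""
    clusters: list[frozenset] = [frozenset([i]) for i in range(len(rows))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(
                    euclidean(rows[a], rows[b])
                    for a in clusters[i] for b in clusters[j]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


class TestClustering:
    def test_near_rows_merge_first(self):
        table = pd.DataFrame([[0, 0], [0, 1], [10, 10]],
                             index=["a", "b", "c"], columns=["t1", "t2"],
                             dtype=float)
        order, Z, newick = cluster_profiles(table, impute_absent_at=None)
        # first merge joins the two near rows a and b
        assert sorted(int(i) for i in Z[0, :2]) == [0, 1]
        assert newick.endswith(";") and "c" in newick

    def test_duplicate_rows_merge_at_height_zero(self):
        table = pd.DataFrame([[5, 5], [5, 5], [9, 1]],
                             index=["a", "b", "c"], dtype=float)
        _, Z, _ = cluster_profiles(table, impute_absent_at=None)
        assert Z[0, 2] == 0.0

    def test_tree_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        rows = rng.uniform(0, 10, size=(6, 4))
        table = pd.DataFrame(rows, index=[f"g{i}" for i in range(6)])
        _, Z, _ = cluster_profiles(table, impute_absent_at=None)
        oracle = brute_force_complete_linkage(rows)
        # same merge heights
        np.testing.assert_allclose(sorted(Z[:, 2]),
                                   sorted(h for _, h in oracle), rtol=1e-10)
        # same nested cluster composition
        tree = to_tree(Z)

        def leaf_sets(node, acc):
            if node.is_leaf():
                return frozenset([node.id])
            s = leaf_sets(node.get_left(), acc) | leaf_sets(node.get_right(), acc)
            acc.append(s)
            return s

        acc: list[frozenset] = []
        leaf_sets(tree, acc)
        assert set(acc) == {m for m, _ in oracle}

    def test_leaf_order_stable_under_permutation(self):
        rng = np.random.default_rng(3)
        rows = rng.uniform(0, 10, size=(7, 3))
        table = pd.DataFrame(rows, index=[f"g{i}" for i in range(7)])
        order1, _, nwk1 = cluster_profiles(table, impute_absent_at=None)
        perm = table.sample(frac=1, random_state=5)
        order2, _, nwk2 = cluster_profiles(perm, impute_absent_at=None)
        assert order1 == order2 and nwk1 == nwk2

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(pd.DataFrame([[1.0, 2.0]], index=["a"]))


def test_analysis_params_ordering_enforced():
    with pytest.raises(ValueError):
        AnalysisParams(fc_threshold=2.5)
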