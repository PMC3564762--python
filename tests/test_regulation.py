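"""Constrained ratios, fold-change classes and responsiveness codes."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aqpmeta.consolidation import AnalysisParams
from aqpmeta.regulation import (
    Comparison,
    ResponsivenessCell,
    build_comparisons,
    classify_regulation,
    consolidate_ratio,
    constrained_log2_ratio,
    make_event,
    regulation_distribution,
    responsiveness_map,
)

signals = st.floats(min_value=0.0, max_value=16.0)


class TestConstrainedRatio:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [(5.2, 4.2, 1.0),     # plain subtraction
         (3.0, 2.5, 0.0),     # both below background -> nulled
         (3.0, 5.0, -2.0),    # only one below -> computed (on/off switch)
         (3.2, 2.0, 1.2)],    # cutoff itself counts as above background
    )
    def test_cases(self, test, ref, expected):
        assert constrained_log2_ratio(test, ref) == pytest.approx(expected)

    @given(signals, signals)
    @settings(max_examples=300, deadline=None)
    def test_antisymmetry(self, a, b):
        assert constrained_log2_ratio(a, b) == pytest.approx(
            -constrained_log2_ratio(b, a)
        )


class TestConsolidateRatio:
    def test_max_absolute_with_sign(self):
        assert consolidate_ratio({"p1": 0.4, "p2": -1.2, "p3": 0.9}) == -1.2
        assert consolidate_ratio({"p1": 0.8}) == 0.8

    def test_tie_breaks_toward_higher_mean_signal(self):
        ratios = {"p1": 1.0, "p2": -1.0}
        assert consolidate_ratio(ratios, {"p1": 7.0, "p2": 4.0}) == 1.0
        assert consolidate_ratio(ratios, {"p1": 4.0, "p2": 7.0}) == -1.0

    def test_final_tie_breaks_lexicographically(self):
        assert consolidate_ratio({"pB": -1.0, "pA": 1.0},
                                 {"pA": 5.0, "pB": 5.0}) == 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "ratio,strength,direction",
        [(1.0, "moderate", "up"),
         (0.58, "none", "none"),      # 2**0.58 = 1.494 < 1.5
         (-2.1, "strong", "down"),    # 2**2.1 = 4.29
         (math.log2(1.5), "weak", "up"),    # FC exactly 1.5 is regulated
         (1.0, "moderate", "up"),           # FC exactly 2 -> upper class
         (2.0, "strong", "up"),             # FC exactly 4 -> upper class
         (0.0, "none", "none")],
    )
    def test_boundaries(self, ratio, strength, direction):
        ev = classify_regulation(ratio)
        assert (ev.strength, ev.direction) == (strength, direction)

    @given(st.floats(min_value=-6, max_value=6))
    @settings(max_examples=300, deadline=None)
    def test_exactly_one_class(self, ratio):
        ev = classify_regulation(ratio)
        fc = 2.0 ** abs(ratio)
        expected = ("none" if fc < 1.5 else "weak" if fc < 2
                    else "moderate" if fc < 4 else "strong")
        assert ev.strength == expected
        assert ev.fold_change == pytest.approx(fc)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_regulation(float("inf"))


class TestBuildComparisons:
    def test_treatment_vs_control(self, toy_design):
        comps = build_comparisons(toy_design)
        assert len(comps) == 1
        assert comps[0].test_condition == "drought"
        assert comps[0].reference_condition == "control"

    def test_time_series_against_t0(self):
        rows = [
            {"sample": f"s{i}", "experiment": "e1", "condition": f"tp{i}",
             "tissue": "leaf", "cue_category": "temporal oscillation",
             "genotype": "wt", "timepoint": t}
            for i, t in enumerate(("t0", "t1", "t2"))
        ]
        comps = build_comparisons(pd.DataFrame(rows))
        assert [(c.test_condition, c.reference_condition) for c in comps] == [
            ("tp1", "tp0"), ("tp2", "tp0")
        ]

    def test_never_crosses_experiments(self):
        rows = []
        for exp in ("e1", "e2"):
            for cond in ("control", "salt"):
                rows.append(
                    {"sample": f"{exp}_{cond}", "experiment": exp,
                     "condition": cond, "tissue": "root",
                     "cue_category": "abiotic stress", "genotype": "wt",
                     "timepoint": ""}
                )
        comps = build_comparisons(pd.DataFrame(rows))
        assert len(comps) == 2
        for c in comps:
            assert c.comparison_id.startswith(c.experiment_id)

    def test_missing_control_skipped(self, capsys):
        rows = [{"sample": "s1", "experiment": "e1", "condition": "salt",
                 "tissue": "root", "cue_category": "abiotic stress",
                 "genotype": "wt", "timepoint": ""}]
        assert build_comparisons(pd.DataFrame(rows)) == []
        assert "no control" in capsys.readouterr().err


def events_from_ratios(gene_ratio_pairs, comparison_id="c1"):
    return [make_event(g, comparison_id, r) for g, r in gene_ratio_pairs]


COMPARISONS = [
    Comparison("c1", "e1", "t", "control", "leaf", "abiotic stress"),
    Comparison("c2", "e1", "t2", "control", "leaf", "abiotic stress"),
    Comparison("c3", "e2", "t", "control", "root", "hormone"),
]


class TestResponsivenessMap:
    def build(self, ratios_by_comp):
        events = []
        for comp_id, ratio in ratios_by_comp:
            events.append(make_event("g1", comp_id, ratio))
        return responsiveness_map(events, COMPARISONS)

    def test_consistent_code(self):
        codes, _ = self.build([("c1", 0.7), ("c2", 0.8)])
        assert codes.loc["g1", ("abiotic stress", "leaf")] == "C"

    def test_interaction_code(self):
        codes, _ = self.build([("c1", 0.7), ("c2", -0.9)])
        assert codes.loc["g1", ("abiotic stress", "leaf")] == "x"

    def test_intermediate_and_none_codes(self):
        events = events_from_ratios([("g1", 0.7)], "c1") + \
            events_from_ratios([("g1", 0.2)], "c2") + \
            events_from_ratios([("g1", 0.1)], "c3")
        codes, n = responsiveness_map(events, COMPARISONS)
        assert codes.loc["g1", ("abiotic stress", "leaf")] == "1"
        assert codes.loc["g1", ("hormone", "root")] == "-"
        assert n[("abiotic stress", "leaf")] == 2

    def test_single_comparison_can_be_consistent(self):
        codes, _ = self.build([("c3", 1.0)])
        assert codes.loc["g1", ("hormone", "root")] == "C"


@given(
    st.integers(min_value=0, max_value=10),
    st.integers(min_value=0, max_value=10),
    st.integers(min_value=0, max_value=10),
)
@settings(max_examples=200, deadline=None)
def test_responsiveness_cell_invariants(n_up, n_down, n_extra):
    cell = ResponsivenessCell(
        gene_id="g", cue_category="cue", tissue="L",
        n_comparisons=n_up + n_down + n_extra, n_up=n_up, n_down=n_down,
    )
    code = cell.code
    assert cell.n_up + cell.n_down <= cell.n_comparisons
    if code == "-":
        assert n_up + n_down == 0
    elif code == "x":
        assert n_up >= 1 and n_down >= 1
    elif code == "C":
        assert n_extra == 0 and (n_up == 0 or n_down == 0)
        assert n_up + n_down >= 1
    else:
        assert int(code) == n_up + n_down


class TestDistribution:
    def test_counts_partition_events(self):
        events = (
            events_from_ratios([("g1", 0.7)], "c1")
            + events_from_ratios([("g1", 0.8)], "c2")
            + events_from_ratios([("g1", -2.5)], "c3")
            + events_from_ratios([("g2", 0.1)], "c1")
        )
        dist = regulation_distribution(events)
        assert dist.loc["g1", "weak_up"] == 2
        assert dist.loc["g1", "strong_down"] == 1
        assert not dist.loc["g1", "never_regulated"]
        assert dist.loc["g2", "never_regulated"]

    def test_planted_effects_recovered_at_zero_noise(self, small_simulation):
        from aqpmeta.consolidation import condition_means
        from aqpmeta.regulation import compute_events_probe_level

        matrices, design, truth = small_simulation
        comps = build_comparisons(design)
        events = []
        for exp_id, matrix in matrices.items():
            sub = design[design["experiment"] == exp_id]
            means = condition_means(matrix, sub)
            events.extend(
                compute_events_probe_level(
                    means, truth.probeset_gene,
                    [c for c in comps if c.experiment_id == exp_id],
                )
            )
        comp_by_id = {c.comparison_id: c for c in comps}
        for ev in events:
            comp = comp_by_id[ev.comparison_id]
            if comp.tissue not in truth.gene_tissues[ev.gene_id]:
                continue  # absent genes are constrained to background
            planted = truth.effects[
                (ev.gene_id, comp.experiment_id, comp.test_condition)
            ]
            assert ev.log2_ratio == pytest.approx(planted, abs=1e-9)
            assert ev.strength == classify_regulation(planted).strength
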