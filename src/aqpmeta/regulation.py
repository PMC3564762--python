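"""Constrained log2 ratios, fold-change classification and the responsiveness
map.

The log2 ratio of a comparison is *constrained*: it is set to 0 when the test
and the reference condition are BOTH below the background cutoff (3.2), which
prevents background-only cells from injecting noise.  If only one side is
below the cutoff the ratio is computed normally — such cases are genuine
on/off switches.

Fold change is ``2**|log2 ratio|``.  Classes are left-closed: no regulation
below FC 1.5, weak [1.5, 2), moderate [2, 4), strong [4, inf).  A constrained
(null) ratio still counts as a compared, non-regulated case.

The responsiveness map summarises each gene over every (cue category, tissue)
group of comparisons with a compact code: "-" no regulation at all, "C" all
comparisons regulated and in one direction, an integer for intermediate
cases, "x" when both up- and down-regulations occur in the group.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .consolidation import BACKGROUND_CUTOFF, AnalysisParams

STRENGTH_ORDER = ("none", "weak", "moderate", "strong")


@dataclass(frozen=True)
class Comparison:
    comparison_id: str
    experiment_id: str
    test_condition: str
    reference_condition: str
    tissue: str
    cue_category: str
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.test_condition == self.reference_condition:
            raise ValueError("test and reference conditions must differ")


@dataclass(frozen=True)
class RegulationEvent:
    gene_id: str
    comparison_id: str
    log2_ratio: float
    fold_change: float
    direction: str  # up | down | none
    strength: str   # none | weak | moderate | strong


@dataclass(frozen=True)
class ResponsivenessCell:
    gene_id: str
    cue_category: str
    tissue: str
    n_comparisons: int
    n_up: int
    n_down: int

    @property
    def code(self) -> str:
        regulated = self.n_up + self.n_down
        if regulated == 0:
            return "-"
        if self.n_up >= 1 and self.n_down >= 1:
            return "x"
        if regulated == self.n_comparisons:
            return "C"
        return str(regulated)


_TIME_ZERO = ("t0", "0", "predawn")


def build_comparisons(design: pd.DataFrame) -> list[Comparison]:
    """Derive the comparison inventory from a design sheet.

    Within each experiment: treatments (or transgenic lines) are compared to
    the control/wild-type condition; in a temporal series every later time
    point is compared to the initial one (t0 or predawn).  Comparisons never
    cross experiments.  Treatments lacking a control are skipped with a
    warning.
    """
    comparisons: list[Comparison] = []
    for exp_id, sub in design.groupby("experiment", sort=True):
        conds = sub.drop_duplicates("condition")
        timepoints = [str(t) for t in conds.get("timepoint", pd.Series([""] * len(conds)))]
        has_series = any(t not in ("", "nan") for t in timepoints)
        if has_series:
            t0_rows = conds[conds["timepoint"].astype(str).str.lower().isin(_TIME_ZERO)]
            if t0_rows.empty:
                print(f"warning: experiment {exp_id} has a time series without a "
                      "t0/predawn baseline; skipped", file=sys.stderr)
                continue
            ref = t0_rows.iloc[0]
            for _, row in conds.iterrows():
                if str(row["timepoint"]).lower() in _TIME_ZERO:
                    continue
                comparisons.append(
                    Comparison(
                        comparison_id=f"{exp_id}:{row['condition']}_vs_{ref['condition']}",
                        experiment_id=exp_id,
                        test_condition=row["condition"],
                        reference_condition=ref["condition"],
                        tissue=row["tissue"],
                        cue_category=row["cue_category"],
                        genotype=str(row.get("genotype", "")),
                    )
                )
            continue
        control_mask = conds["condition"].str.lower().isin(
            ("control", "wildtype", "wild_type", "wt")
        )
        if not control_mask.any():
            print(f"warning: experiment {exp_id} has no control condition; "
                  "skipped", file=sys.stderr)
            continue
        ref = conds[control_mask].iloc[0]
        for _, row in conds.iterrows():
            if row["condition"] == ref["condition"]:
                continue
            comparisons.append(
                Comparison(
                    comparison_id=f"{exp_id}:{row['condition']}_vs_{ref['condition']}",
                    experiment_id=exp_id,
                    test_condition=row["condition"],
                    reference_condition=ref["condition"],
                    tissue=row["tissue"],
                    cue_category=row["cue_category"],
                    genotype=str(row.get("genotype", "")),
                )
            )
    return comparisons


def constrained_log2_ratio(
    signal_test: float,
    signal_ref: float,
    cutoff: float = BACKGROUND_CUTOFF,
) -> float:
    """Signed log2 ratio, set to 0 when both signals are below the cutoff."""
    if signal_test < cutoff and signal_ref < cutoff:
        return 0.0
    return signal_test - signal_ref


def consolidate_ratio(
    probe_ratios: Mapping[str, float],
    probe_mean_signals: Mapping[str, float] | None = None,
) -> float:
    """Gene-level ratio = the probe-set ratio with largest absolute value.

    Sign is preserved.  An exact |ratio| tie with opposite signs is broken
    toward the probe set with the higher mean signal across the two compared
    conditions, then toward the lexicographically smaller probe-set id.
    """
    if not probe_ratios:
        raise ValueError("need at least one probe-set ratio")
    means = probe_mean_signals or {}

    def rank(ps: str) -> tuple:
        return (-abs(probe_ratios[ps]), -means.get(ps, float("-inf")), ps)

    best = min(sorted(probe_ratios), key=rank)
    return probe_ratios[best]


def classify_regulation(
    log2_ratio: float, params: AnalysisParams | None = None
) -> RegulationEvent:
    """Classify one ratio into direction and strength (gene/comparison unset)."""
    return make_event("", "", log2_ratio, params)


def make_event(
    gene_id: str,
    comparison_id: str,
    log2_ratio: float,
    params: AnalysisParams | None = None,
) -> RegulationEvent:
    if not math.isfinite(log2_ratio):
        raise ValueError("log2 ratio must be finite")
    params = params or AnalysisParams()
    fc = 2.0 ** abs(log2_ratio)
    if fc < params.fc_threshold:
        strength, direction = "none", "none"
    else:
        if fc < params.class_bounds[0]:
            strength = "weak"
        elif fc < params.class_bounds[1]:
            strength = "moderate"
        else:
            strength = "strong"
        direction = "up" if log2_ratio > 0 else "down"
    return RegulationEvent(
        gene_id=gene_id,
        comparison_id=comparison_id,
        log2_ratio=log2_ratio,
        fold_change=fc,
        direction=direction,
        strength=strength,
    )


def compute_events(
    gene_signals: pd.DataFrame,
    comparisons: Iterable[Comparison],
    params: AnalysisParams | None = None,
) -> list[RegulationEvent]:
    """Score every gene x comparison from a gene x condition signal table.

    The constrained ratio is applied at the gene level (signals are already
    consolidated); genes lacking either condition are skipped for that
    comparison.
    """
    params = params or AnalysisParams()
    events = []
    for comp in comparisons:
        if (comp.test_condition not in gene_signals.columns
                or comp.reference_condition not in gene_signals.columns):
            continue
        test = gene_signals[comp.test_condition]
        ref = gene_signals[comp.reference_condition]
        for gene in gene_signals.index:
            t, r = float(test[gene]), float(ref[gene])
            if math.isnan(t) or math.isnan(r):
                continue
            ratio = constrained_log2_ratio(t, r, params.background_cutoff)
            events.append(make_event(gene, comp.comparison_id, ratio, params))
    return events


def compute_events_probe_level(
    probe_means: pd.DataFrame,
    probeset_gene: Mapping[str, str],
    comparisons: Iterable[Comparison],
    params: AnalysisParams | None = None,
) -> list[RegulationEvent]:
    """Score gene x comparison from probe-set condition means.

    Per probe set the constrained ratio is computed, then the gene-level
    ratio is the maximal-absolute probe-set ratio (ties broken by mean
    signal across the two conditions, then probe-set id).
    """
    params = params or AnalysisParams()
    gene_rows: dict[str, list[str]] = {}
    for ps in probe_means.index:
        g = probeset_gene.get(ps)
        if g is not None:
            gene_rows.setdefault(g, []).append(ps)
    events = []
    for comp in comparisons:
        if (comp.test_condition not in probe_means.columns
                or comp.reference_condition not in probe_means.columns):
            continue
        test = probe_means[comp.test_condition]
        ref = probe_means[comp.reference_condition]
        for gene in sorted(gene_rows):
            ratios = {}
            means = {}
            for ps in gene_rows[gene]:
                ratios[ps] = constrained_log2_ratio(
                    float(test[ps]), float(ref[ps]), params.background_cutoff
                )
                means[ps] = 0.5 * (float(test[ps]) + float(ref[ps]))
            ratio = consolidate_ratio(ratios, means)
            events.append(make_event(gene, comp.comparison_id, ratio, params))
    return events


def responsiveness_map(
    events: Iterable[RegulationEvent],
    comparisons: Iterable[Comparison],
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the gene x (cue category, tissue) responsiveness-code table.

    Returns ``(codes, n_comparisons)``: codes is a DataFrame with a
    (cue_category, tissue) column MultiIndex holding the "-"/"C"/integer/"x"
    vocabulary; ``n_comparisons`` gives the number of comparisons per column.
    Groups without any comparison are omitted.
    """
    comp_group = {
        c.comparison_id: (c.cue_category, c.tissue) for c in comparisons
    }
    cells: dict[tuple[str, str, str], dict[str, int]] = {}
    group_comps: dict[tuple[str, str], set[str]] = {}
    for ev in events:
        group = comp_group.get(ev.comparison_id)
        if group is None:
            continue
        group_comps.setdefault(group, set()).add(ev.comparison_id)
        key = (ev.gene_id, *group)
        cell = cells.setdefault(key, {"n": 0, "up": 0, "down": 0})
        cell["n"] += 1
        if ev.strength != "none":
            cell["up" if ev.direction == "up" else "down"] += 1
    genes = sorted({k[0] for k in cells})
    groups = sorted(group_comps)
    codes = pd.DataFrame(
        "-", index=genes,
        columns=pd.MultiIndex.from_tuples(groups, names=["cue_category", "tissue"]),
    )
    for (gene, cue, tissue), cell in cells.items():
        rc = ResponsivenessCell(
            gene_id=gene, cue_category=cue, tissue=tissue,
            n_comparisons=cell["n"], n_up=cell["up"], n_down=cell["down"],
        )
        codes.loc[gene, (cue, tissue)] = rc.code
    n_comparisons = pd.Series(
        {g: len(group_comps[g]) for g in groups},
        index=codes.columns, name="n_comparisons",
    )
    codes.index.name = "gene"
    return codes, n_comparisons


def regulation_distribution(events: Iterable[RegulationEvent]) -> pd.DataFrame:
    """Count per-gene regulations by strength x direction.

    Columns: weak_up, moderate_up, strong_up, weak_down, moderate_down,
    strong_down, plus n_comparisons and a never_regulated flag.
    """
    counts: dict[str, dict[str, int]] = {}
    for ev in events:
        row = counts.setdefault(
            ev.gene_id,
            {f"{s}_{d}": 0 for s in STRENGTH_ORDER[1:] for d in ("up", "down")}
            | {"n_comparisons": 0},
        )
        row["n_comparisons"] += 1
        if ev.strength != "none":
            row[f"{ev.strength}_{ev.direction}"] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    reg_cols = [f"{s}_{d}" for s in STRENGTH_ORDER[1:] for d in ("up", "down")]
    out["never_regulated"] = out[reg_cols].sum(axis=1) == 0
    out.index.name = "gene"
    return out
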