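"""Duplicate-pair co-regulation profiling.

For each duplicate pair and each comparison both members have data for, the
pair is in exactly one state:

* ``none`` — neither member regulated (both FC < 1.5);
* ``divergent_single`` — exactly one member regulated;
* ``divergent_opposite`` — both regulated, opposite directions;
* ``convergent_weak`` / ``convergent_strong`` — both regulated in the same
  direction, sub-classed by the pair's minimum fold change against 2 (a
  convergent event is only as strong as its weaker member).

Comparisons where either member has no data (no valid probe set on the
array) are excluded from the denominator and counted separately, so
array-design gaps cannot inflate apparent divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .consolidation import AnalysisParams
from .regulation import Comparison, RegulationEvent

PAIR_STATES = (
    "none",
    "convergent_weak",
    "convergent_strong",
    "divergent_single",
    "divergent_opposite",
)


@dataclass(frozen=True)
class PairProfile:
    pair_id: str
    n_comparisons: int          # usable comparisons (both members scored)
    n_excluded: int             # comparisons lacking data for a member
    pct_none: float
    pct_convergent_weak: float
    pct_convergent_strong: float
    pct_divergent: float
    convergent_events: tuple[tuple[str, str], ...]  # (comparison_id, sub-class)


def classify_pair_state(
    ratio_a: float,
    ratio_b: float,
    params: AnalysisParams | None = None,
) -> str:
    """Classify one comparison of a duplicate pair into its regulation state."""
    params = params or AnalysisParams()
    fc_a, fc_b = 2.0 ** abs(ratio_a), 2.0 ** abs(ratio_b)
    reg_a, reg_b = fc_a >= params.fc_threshold, fc_b >= params.fc_threshold
    if not reg_a and not reg_b:
        return "none"
    if reg_a != reg_b:
        return "divergent_single"
    if (ratio_a > 0) != (ratio_b > 0):
        return "divergent_opposite"
    return (
        "convergent_strong"
        if min(fc_a, fc_b) >= params.class_bounds[0]
        else "convergent_weak"
    )


def pair_profile(
    pair_id: str,
    gene_a: str,
    gene_b: str,
    events: Iterable[RegulationEvent],
    params: AnalysisParams | None = None,
) -> PairProfile:
    """Score a pair's convergence/divergence profile across all comparisons."""
    params = params or AnalysisParams()
    by_comp: dict[str, dict[str, float]] = {}
    for ev in events:
        if ev.gene_id in (gene_a, gene_b):
            by_comp.setdefault(ev.comparison_id, {})[ev.gene_id] = ev.log2_ratio
    counts = {s: 0 for s in PAIR_STATES}
    convergent: list[tuple[str, str]] = []
    n_excluded = 0
    for comp_id in sorted(by_comp):
        ratios = by_comp[comp_id]
        if gene_a not in ratios or gene_b not in ratios:
            n_excluded += 1
            continue
        state = classify_pair_state(ratios[gene_a], ratios[gene_b], params)
        counts[state] += 1
        if state.startswith("convergent"):
            convergent.append((comp_id, state.removeprefix("convergent_")))
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"pair {pair_id!r}: no usable comparisons")
    pct = {s: 100.0 * counts[s] / n for s in PAIR_STATES}
    return PairProfile(
        pair_id=pair_id,
        n_comparisons=n,
        n_excluded=n_excluded,
        pct_none=pct["none"],
        pct_convergent_weak=pct["convergent_weak"],
        pct_convergent_strong=pct["convergent_strong"],
        pct_divergent=pct["divergent_single"] + pct["divergent_opposite"],
        convergent_events=tuple(convergent),
    )


def profile_pairs(
    pairs: Iterable[tuple[str, str, str]],
    events: Iterable[RegulationEvent],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Profile many pairs; rows are (gene_a/gene_b) pair ids."""
    events = list(events)
    rows = []
    for gene_a, gene_b, dup_type in pairs:
        pid = f"{gene_a}/{gene_b}"
        prof = pair_profile(pid, gene_a, gene_b, events, params)
        rows.append(
            {
                "pair": pid,
                "gene_a": gene_a,
                "gene_b": gene_b,
                "duplication": dup_type,
                "n_comparisons": prof.n_comparisons,
                "n_excluded": prof.n_excluded,
                "pct_none": prof.pct_none,
                "pct_convergent_weak": prof.pct_convergent_weak,
                "pct_convergent_strong": prof.pct_convergent_strong,
                "pct_divergent": prof.pct_divergent,
            }
        )
    return pd.DataFrame(rows)


def convergence_by_category(
    pairs: Iterable[tuple[str, str, str]],
    events: Iterable[RegulationEvent],
    comparisons: Iterable[Comparison],
    params: AnalysisParams | None = None,
) -> pd.DataFrame:
    """Break down each pair's convergent events over cue categories."""
    events = list(events)
    comp_cue = {c.comparison_id: c.cue_category for c in comparisons}
    rows = []
    for gene_a, gene_b, _ in pairs:
        pid = f"{gene_a}/{gene_b}"
        prof = pair_profile(pid, gene_a, gene_b, events, params)
        for comp_id, subclass in prof.convergent_events:
            rows.append(
                {
                    "pair": pid,
                    "comparison": comp_id,
                    "cue_category": comp_cue.get(comp_id, "unknown"),
                    "strength": subclass,
                }
            )
    return pd.DataFrame(rows, columns=["pair", "comparison", "cue_category", "strength"])


def join_sequence_divergence(
    profiles: pd.DataFrame,
    divergence: pd.DataFrame,
) -> pd.DataFrame:
    """Join expression profiles with per-pair sequence divergence.

    ``profiles`` comes from :func:`profile_pairs`; ``divergence`` needs a
    ``pair`` column plus any of dN, dS, ratio, fourDTV, duplication.  Pairs
    absent from either side keep their row with missing fields (warned).
    Subfamily means of convergence (everything before the first digit of the
    gene name defines the subfamily) are attached as a second frame.
    """
    import sys

    merged = profiles.merge(
        divergence, on="pair", how="outer", suffixes=("", "_seq")
    )
    incomplete = merged[merged.isna().any(axis=1)]["pair"].tolist()
    if incomplete:
        print(f"warning: pairs with missing fields after join: {incomplete}",
              file=sys.stderr)
    return merged


def subfamily_convergence(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean convergence percentages per subfamily prefix of gene_a."""
    def prefix(name: str) -> str:
        out = []
        for ch in name:
            if ch.isdigit():
                break
            out.append(ch)
        return "".join(out) or name

    work = profiles.copy()
    work["subfamily"] = [prefix(g) for g in work["gene_a"]]
    agg = work.groupby("subfamily")[
        ["pct_none", "pct_convergent_weak", "pct_convergent_strong", "pct_divergent"]
    ].mean()
    agg["pct_convergent"] = agg["pct_convergent_weak"] + agg["pct_convergent_strong"]
    return agg
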