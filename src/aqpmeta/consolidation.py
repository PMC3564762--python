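"""Gene-level consolidation of probe-set signals, presence calls, tissue
expression domains and hierarchical clustering of profiles.

Signals are log2-scale, already normalized per experiment upstream.  The
gene-level value is the maximum over the gene's valid probe sets (the median
is kept as a diagnostic: on a multispecies-designed chip the median is pulled
toward background whenever some probe sets match the hybridized species
poorly, which is exactly what ``median_max_divergence`` flags).

A gene is called *present* when its consolidated log2 signal reaches the
background cutoff (default 3.2; the value itself is present — only strictly
below the cutoff is absent).  Genes with no valid probe set are reported as
"no data", never as absent.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

BACKGROUND_CUTOFF = 3.2


@dataclass(frozen=True)
class AnalysisParams:
    """Shared thresholds of the meta-analysis.

    background_cutoff: log2 signal below which a measurement is treated as
        absence of detectable expression.
    fc_threshold: minimum fold change for a regulation call.
    class_bounds: fold-change boundaries between weak/moderate and
        moderate/strong regulation.
    """

    background_cutoff: float = BACKGROUND_CUTOFF
    fc_threshold: float = 1.5
    class_bounds: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if not 1.0 < self.fc_threshold < self.class_bounds[0] < self.class_bounds[1]:
            raise ValueError(
                "thresholds must satisfy 1 < fc_threshold < class_bounds[0] "
                "< class_bounds[1]"
            )


@dataclass(frozen=True)
class GeneSignal:
    gene_id: str
    condition: str
    log2_signal: float | None  # None when the gene has no valid probe set
    present: bool
    contributing_probesets: tuple[str, ...]
    method: str

    @property
    def no_data(self) -> bool:
        return self.log2_signal is None


def condition_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples into per-condition means (log2 scale).

    ``matrix`` is probe sets x samples; ``design`` must map every matrix
    column to a condition via its ``sample`` and ``condition`` columns.
    """
    sample_to_cond = dict(zip(design["sample"], design["condition"]))
    missing = [s for s in matrix.columns if s not in sample_to_cond]
    if missing:
        raise ValueError(f"samples missing from design sheet: {missing}")
    conditions = sorted({sample_to_cond[s] for s in matrix.columns})
    out = {}
    for cond in conditions:
        cols = [s for s in matrix.columns if sample_to_cond[s] == cond]
        if not cols:
            raise ValueError(f"condition {cond!r} has no samples")
        out[cond] = matrix[cols].mean(axis=1)
    return pd.DataFrame(out)


def consolidate_signal(
    gene_id: str,
    condition: str,
    probe_signals: Mapping[str, float],
    method: str = "max",
    cutoff: float = BACKGROUND_CUTOFF,
) -> GeneSignal:
    """Collapse one gene's probe-set signals for one condition.

    ``max`` is the production method; ``median`` is diagnostic.  A gene with
    no valid probe set yields a "no data" signal (``log2_signal is None``),
    distinct from an absent (below-cutoff) call.
    """
    if method not in ("max", "median"):
        raise ValueError(f"unknown consolidation method {method!r}")
    if not probe_signals:
        return GeneSignal(gene_id, condition, None, False, (), method)
    values = np.array([probe_signals[k] for k in sorted(probe_signals)])
    value = float(values.max() if method == "max" else np.median(values))
    return GeneSignal(
        gene_id=gene_id,
        condition=condition,
        log2_signal=value,
        present=value >= cutoff,
        contributing_probesets=tuple(sorted(probe_signals)),
        method=method,
    )


def consolidate_matrix(
    cond_means: pd.DataFrame,
    probeset_gene: Mapping[str, str],
    method: str = "max",
    cutoff: float = BACKGROUND_CUTOFF,
) -> pd.DataFrame:
    """Collapse a probe-set x condition matrix to gene x condition.

    Only probe sets present in ``probeset_gene`` (the valid set) contribute.
    """
    gene_rows: dict[str, list[str]] = {}
    for ps in cond_means.index:
        gene = probeset_gene.get(ps)
        if gene is not None:
            gene_rows.setdefault(gene, []).append(ps)
    data = {}
    for gene in sorted(gene_rows):
        sub = cond_means.loc[gene_rows[gene]]
        data[gene] = sub.max(axis=0) if method == "max" else sub.median(axis=0)
    out = pd.DataFrame(data).T
    out.index.name = "gene"
    return out


def median_max_divergence(
    cond_means: pd.DataFrame,
    probeset_gene: Mapping[str, str],
    cutoff: float = BACKGROUND_CUTOFF,
) -> pd.DataFrame:
    """Report the max - median gap per gene x condition for multi-probe genes.

    A row is flagged when the max is present while the median sits below the
    background cutoff — the signature of a probe set that matches the
    hybridized species poorly and drags an automatic median consolidation to
    background.
    """
    gene_rows: dict[str, list[str]] = {}
    for ps in cond_means.index:
        gene = probeset_gene.get(ps)
        if gene is not None:
            gene_rows.setdefault(gene, []).append(ps)
    rows = []
    for gene in sorted(gene_rows):
        pss = gene_rows[gene]
        if len(pss) < 2:
            continue
        sub = cond_means.loc[pss]
        for cond in cond_means.columns:
            mx = float(sub[cond].max())
            med = float(sub[cond].median())
            n_present = int((sub[cond] >= cutoff).sum())
            # background-dominated median: the max is present but at most
            # half the probe sets are, so the median is pulled toward (or
            # below) background by poorly-matching probe sets
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "n_probesets": len(pss),
                    "max": mx,
                    "median": med,
                    "gap": mx - med,
                    "n_present_probesets": n_present,
                    "flagged": mx >= cutoff and n_present <= len(pss) // 2,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "condition", "n_probesets", "max", "median", "gap",
            "n_present_probesets", "flagged",
        ],
    )


def expression_domain(
    gene_signals: pd.DataFrame,
    condition_tissue: Mapping[str, str],
    control_conditions: Iterable[str] | None = None,
    cutoff: float = BACKGROUND_CUTOFF,
) -> pd.DataFrame:
    """Build the gene x tissue expression-domain table from control samples.

    Cell value = maximal consolidated log2 signal over all control conditions
    of that tissue type; a cell below ``cutoff`` means the gene is absent in
    that tissue.  Tissues without any contributing condition are omitted with
    a warning.
    """
    if control_conditions is not None:
        wanted = [c for c in gene_signals.columns if c in set(control_conditions)]
    else:
        wanted = list(gene_signals.columns)
    by_tissue: dict[str, list[str]] = {}
    for cond in wanted:
        tissue = condition_tissue.get(cond)
        if tissue is None:
            continue
        by_tissue.setdefault(tissue, []).append(cond)
    requested = set(condition_tissue.values())
    for tissue in sorted(requested - set(by_tissue)):
        print(f"warning: tissue {tissue!r} has no control arrays; column omitted",
              file=sys.stderr)
    data = {
        tissue: gene_signals[conds].max(axis=1)
        for tissue, conds in sorted(by_tissue.items())
    }
    out = pd.DataFrame(data)
    out.index.name = "gene"
    return out


def cluster_profiles(
    table: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
    impute_absent_at: float | None = BACKGROUND_CUTOFF,
) -> tuple[list[str], np.ndarray, str]:
    """Hierarchically cluster gene profiles; return (leaf order, linkage, newick).

    Rows are sorted by label before clustering so the merge tree is invariant
    to input permutation (distance ties then break on the sorted positions).
    Below-cutoff cells are imputed at the cutoff value for the distance
    computation only when ``impute_absent_at`` is set.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to cluster")
    if table.isna().any().any():
        raise ValueError("missing values must be imputed before clustering")
    table = table.sort_index()
    values = table.to_numpy(dtype=float)
    if impute_absent_at is not None:
        values = np.maximum(values, impute_absent_at)
    dists = pdist(values, metric=metric)
    if np.allclose(dists, dists[0]):
        print("warning: all pairwise distances equal; leaf order is arbitrary "
              "but deterministic", file=sys.stderr)
    Z = linkage(dists, method=method)
    tree = to_tree(Z)
    labels = list(table.index)
    order = [labels[i] for i in tree.pre_order(lambda leaf: leaf.id)]

    def newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = newick(node.get_left())
        right = newick(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return order, Z, newick(tree) + ";"
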