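"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the structure of a collection of independent Affymetrix
experiments run on a multispecies-designed chip: each gene is measured by 1-3
probe sets designed on different species, probe sets carry species-dependent
affinity offsets (cross-species hybridization is never *more* efficient, so
offsets are <= 0 for non-matching species), genes absent from a tissue give
background-level signal, and treatment conditions carry planted log2 effects.

Every matrix entry decomposes exactly as

    baseline + planted effect + affinity offset + Gaussian noise

where the baseline is the gene's expression level in expressed tissues or a
per-(probe set, experiment) background level in absent tissues.  The additive
Gaussian-on-log2 noise model is a deliberate stand-in: GcRMA-style normalized
intensities are approximately log-normal, but no distributional form is
asserted for real arrays (see docs/methods.md).

All randomness flows from a single integer seed through deterministic
sub-streams, so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codonevol import (
    CODON_TABLE,
    FOURFOLD_PREFIXES,
    NUCLEOTIDES,
    STOP_CODONS,
)

TISSUES = ("root", "leaf", "xylem", "stem", "seedling", "catkin")
CUE_CATEGORIES = (
    "abiotic stress",
    "nutrition",
    "hormone",
    "biotic",
    "temporal oscillation",
)

#: default probe-set multiplicity mix: most genes carry a single probe set,
#: a minority carry three (multi-species design redundancy)
DEFAULT_MULTIPLICITY = {1: 0.59, 2: 0.06, 3: 0.35}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the synthetic array collection.

    Log2-scale landmarks: background around 2.5 (below the presence cutoff of
    3.2), expressed genes around 8.  Replicate noise defaults to 0.1 log2
    units; planted contrasts default to the grid {0, ±0.7, ±1.5, ±2.5} which
    spans the none/weak/moderate/strong fold-change classes.
    """

    n_genes: int = 50
    n_pairs: int = 10
    probe_multiplicity: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MULTIPLICITY)
    )
    n_species: int = 12
    affinity_offset_sd: float = 1.0
    background_mean: float = 2.5
    background_sd: float = 0.2
    expressed_mean: float = 8.0
    expressed_spread: float = 1.5
    noise_sd: float = 0.1
    effect_grid: Sequence[float] = (0.0, 0.7, -0.7, 1.5, -1.5, 2.5, -2.5)
    n_experiments: int = 4
    n_treatments_per_experiment: int = 3
    n_replicates: int = 2
    pair_effect_rho: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_pairs": self.n_pairs,
            "n_species": self.n_species,
            "n_experiments": self.n_experiments,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name in ("affinity_offset_sd", "background_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.background_mean < 3.2 < self.expressed_mean:
            raise ValueError(
                "background_mean must lie below the 3.2 cutoff and "
                "expressed_mean above it"
            )
        if 2 * self.n_pairs > self.n_genes:
            raise ValueError("n_pairs pairs require 2*n_pairs distinct genes")
        if not 0.0 <= self.pair_effect_rho <= 1.0:
            raise ValueError("pair_effect_rho must lie in [0, 1]")
        if not self.probe_multiplicity or any(
            k not in (1, 2, 3) or v < 0 for k, v in self.probe_multiplicity.items()
        ):
            raise ValueError("probe_multiplicity must weight {1,2,3} non-negatively")


@dataclass
class GroundTruth:
    """Planted parameters of one simulated collection."""

    gene_baseline: dict[str, float]
    gene_tissues: dict[str, frozenset[str]]
    probeset_gene: dict[str, str]
    probe_species: dict[str, str]
    probe_offset: dict[str, dict[str, float]]  # probeset -> species -> offset
    effects: dict[tuple[str, str, str], float]  # (gene, experiment, condition)
    pairs: list[tuple[str, str, str]]  # (gene_a, gene_b, duplication_type)
    experiment_species: dict[str, str]
    background_level: dict[tuple[str, str], float]  # (experiment, probeset)


def _choose_multiplicity(rng: np.random.Generator, weights: Mapping[int, float]) -> int:
    ks = sorted(weights)
    p = np.array([weights[k] for k in ks], dtype=float)
    p = p / p.sum()
    return int(rng.choice(ks, p=p))


def simulate_expression(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, GroundTruth]:
    """Simulate per-experiment probe-set x sample matrices plus design sheet.

    Returns ``(matrices, design, truth)`` where ``matrices`` maps experiment id
    to a probe-set x sample DataFrame of log2 signals, ``design`` is the
    sample-design sheet (sample, experiment, condition, tissue, cue_category,
    genotype, timepoint) and ``truth`` records every planted parameter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:03d}" for i in range(config.n_genes)]
    species = [f"species{i:02d}" for i in range(config.n_species)]

    gene_baseline = {
        g: float(
            config.expressed_mean
            + rng.uniform(-config.expressed_spread, config.expressed_spread)
        )
        for g in gene_ids
    }
    gene_tissues = {}
    for g in gene_ids:
        k = int(rng.integers(1, len(TISSUES) + 1))
        chosen = rng.choice(len(TISSUES), size=k, replace=False)
        gene_tissues[g] = frozenset(TISSUES[i] for i in sorted(chosen))

    probeset_gene: dict[str, str] = {}
    probe_species: dict[str, str] = {}
    probe_offset: dict[str, dict[str, float]] = {}
    for g in gene_ids:
        m = _choose_multiplicity(rng, config.probe_multiplicity)
        design_species = rng.choice(config.n_species, size=min(m, config.n_species),
                                    replace=False)
        for j, sp_idx in enumerate(design_species):
            ps = f"{g}_ps{j}"
            probeset_gene[ps] = g
            probe_species[ps] = species[int(sp_idx)]
            # zero offset on the design species, <=0 elsewhere
            offsets = {}
            for sp in species:
                if sp == species[int(sp_idx)]:
                    offsets[sp] = 0.0
                else:
                    offsets[sp] = float(
                        -abs(rng.normal(0.0, config.affinity_offset_sd))
                    )
            probe_offset[ps] = offsets

    pair_genes = gene_ids[: 2 * config.n_pairs]
    pairs = [
        (pair_genes[2 * i], pair_genes[2 * i + 1], "S" if i % 3 else "T")
        for i in range(config.n_pairs)
    ]
    partner = {a: b for a, b, _ in pairs} | {b: a for a, b, _ in pairs}
    # duplicates inherit the ancestral expression domain: pair members share
    # their expressed-tissue set (their *regulation* may still diverge)
    for a, b, _ in pairs:
        gene_tissues[b] = gene_tissues[a]

    probesets = sorted(probeset_gene)
    matrices: dict[str, pd.DataFrame] = {}
    design_rows = []
    effects: dict[tuple[str, str, str], float] = {}
    experiment_species: dict[str, str] = {}
    background_level: dict[tuple[str, str], float] = {}
    grid = list(config.effect_grid)

    for e in range(config.n_experiments):
        exp_id = f"exp{e:02d}"
        erng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + e]).generate_state(1)[0]
        )
        hyb_species = species[e % config.n_species]
        experiment_species[exp_id] = hyb_species
        tissue = TISSUES[e % len(TISSUES)]
        cue = CUE_CATEGORIES[e % len(CUE_CATEGORIES)]
        conditions = ["control"] + [
            f"treat{t}" for t in range(config.n_treatments_per_experiment)
        ]

        # planted per-(gene, condition) effects; correlated within pairs
        for g in gene_ids:
            for cond in conditions[1:]:
                key = (g, exp_id, cond)
                if key in effects:
                    continue
                eff = float(grid[erng.integers(0, len(grid))])
                effects[key] = eff
                mate = partner.get(g)
                if mate is not None and (mate, exp_id, cond) not in effects:
                    if erng.random() < config.pair_effect_rho:
                        effects[(mate, exp_id, cond)] = eff
                    else:
                        effects[(mate, exp_id, cond)] = float(
                            grid[erng.integers(0, len(grid))]
                        )

        for ps in probesets:
            background_level[(exp_id, ps)] = float(
                erng.normal(config.background_mean, config.background_sd)
            )

        samples = []
        data = np.empty((len(probesets), len(conditions) * config.n_replicates))
        col = 0
        for cond in conditions:
            for r in range(config.n_replicates):
                sample = f"{exp_id}_{cond}_r{r}"
                samples.append(sample)
                design_rows.append(
                    {
                        "sample": sample,
                        "experiment": exp_id,
                        "condition": cond,
                        "tissue": tissue,
                        "cue_category": cue,
                        "genotype": hyb_species,
                        "timepoint": "",
                    }
                )
                for i, ps in enumerate(probesets):
                    g = probeset_gene[ps]
                    if tissue in gene_tissues[g]:
                        base = gene_baseline[g]
                        eff = effects.get((g, exp_id, cond), 0.0)
                        off = probe_offset[ps][hyb_species]
                    else:
                        base = background_level[(exp_id, ps)]
                        eff = 0.0
                        off = 0.0
                    noise = (
                        float(erng.normal(0.0, config.noise_sd))
                        if config.noise_sd > 0
                        else 0.0
                    )
                    data[i, col] = base + eff + off + noise
                col += 1
        matrices[exp_id] = pd.DataFrame(data, index=probesets, columns=samples)

    design = pd.DataFrame(design_rows)
    truth = GroundTruth(
        gene_baseline=gene_baseline,
        gene_tissues=gene_tissues,
        probeset_gene=probeset_gene,
        probe_species=probe_species,
        probe_offset=probe_offset,
        effects=effects,
        pairs=pairs,
        experiment_species=experiment_species,
        background_level=background_level,
    )
    return matrices, design, truth


# ---------------------------------------------------------------------------
# codon-alignment fixtures with planted substitution counts
# ---------------------------------------------------------------------------

#: third-position transitions within a four-fold family are synonymous and
#: are NOT transversions; A<->C is the transversion used for 4DTV planting
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _safe_nonsyn_mutation(codon: str) -> str:
    """Mutate position 1 to change the amino acid without creating a stop."""
    for base in NUCLEOTIDES:
        if base == codon[0]:
            continue
        mutant = base + codon[1:]
        if mutant in STOP_CODONS:
            continue
        if CODON_TABLE[mutant] != CODON_TABLE[codon]:
            return mutant
    raise ValueError(f"no safe nonsynonymous mutation for codon {codon}")


@dataclass(frozen=True)
class PlantedCounts:
    """Planted substitution inventory of a simulated codon-alignment pair."""

    synonymous: int  # total synonymous differences (incl. 4DTV transversions)
    nonsynonymous: int
    fourfold_sites: int
    fourfold_transversions: int


def simulate_codon_pair(
    n_codons: int,
    n_syn: int = 0,
    n_nonsyn: int = 0,
    n_4dtv: int = 0,
    seed: int = 0,
) -> tuple[str, str, PlantedCounts]:
    """Build an aligned CDS pair with exact planted substitution counts.

    Base codons are drawn from four-fold degenerate families only, so every
    unmutated codon contributes one shared four-fold site and the planted
    counts are unambiguous.  ``n_syn`` synonymous third-position transitions,
    ``n_4dtv`` synonymous third-position transversions and ``n_nonsyn``
    first-position amino-acid changes are placed on distinct codons.  Since a
    four-fold transversion is itself synonymous, the alignment carries
    ``n_syn + n_4dtv`` synonymous differences in total, and
    ``n_codons - n_nonsyn`` shared four-fold sites.
    """
    for name, v in {"n_codons": n_codons, "n_syn": n_syn,
                    "n_nonsyn": n_nonsyn, "n_4dtv": n_4dtv}.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if n_syn + n_nonsyn + n_4dtv > n_codons:
        raise ValueError(
            "requested substitutions exceed available codons "
            f"({n_syn}+{n_nonsyn}+{n_4dtv} > {n_codons})"
        )
    if n_4dtv > n_codons - n_nonsyn:
        raise ValueError("more four-fold transversions requested than four-fold sites")

    rng = np.random.default_rng(seed)
    prefixes = sorted(FOURFOLD_PREFIXES)
    codons = [
        prefixes[int(rng.integers(0, len(prefixes)))]
        + NUCLEOTIDES[int(rng.integers(0, 4))]
        for _ in range(n_codons)
    ]
    seq_a = list(codons)
    seq_b = list(codons)
    slots = list(rng.permutation(n_codons))
    for _ in range(n_syn):
        i = slots.pop()
        c = seq_b[i]
        seq_b[i] = c[:2] + _TRANSITION[c[2]]
    for _ in range(n_4dtv):
        i = slots.pop()
        c = seq_b[i]
        seq_b[i] = c[:2] + _TRANSVERSION[c[2]]
    for _ in range(n_nonsyn):
        i = slots.pop()
        seq_b[i] = _safe_nonsyn_mutation(seq_b[i])
    planted = PlantedCounts(
        synonymous=n_syn + n_4dtv,
        nonsynonymous=n_nonsyn,
        fourfold_sites=n_codons - n_nonsyn,
        fourfold_transversions=n_4dtv,
    )
    return "".join(seq_a), "".join(seq_b), planted


# ---------------------------------------------------------------------------
# EST collection
# ---------------------------------------------------------------------------

def simulate_est_collection(
    genes: Mapping[str, str],
    tissue_profiles: Mapping[str, Mapping[str, int]],
    seed: int = 0,
    divergence: float = 0.0,
    min_length: int = 100,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw single-pass-read-like subsequences of genes with tissue metadata.

    ``genes`` maps gene id -> nucleotide sequence; ``tissue_profiles`` maps
    gene id -> {tissue: number of reads}.  Each read is a contiguous
    subsequence of length >= ``min_length`` with ``divergence`` planted
    mismatch rate (uniformly placed substitutions).  Returns
    ``(records, metadata)`` where records are ``(est_id, sequence)`` and the
    metadata table has columns est_id, gene, tissue, length, n_mismatches.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    rows = []
    counter = 0
    for gene in sorted(tissue_profiles):
        seq = genes.get(gene)
        if seq is None:
            raise KeyError(f"no sequence for gene {gene!r}")
        if len(seq) < min_length:
            raise ValueError(
                f"gene {gene!r} is shorter ({len(seq)} nt) than the minimum "
                f"read length {min_length}"
            )
        profile = tissue_profiles[gene]
        for tissue in sorted(profile):
            for _ in range(profile[tissue]):
                length = int(rng.integers(min_length, len(seq) + 1))
                start = int(rng.integers(0, len(seq) - length + 1))
                read = list(seq[start:start + length])
                n_mut = int(round(divergence * length))
                if n_mut:
                    positions = rng.choice(length, size=n_mut, replace=False)
                    for p in positions:
                        choices = [b for b in NUCLEOTIDES if b != read[p]]
                        read[p] = choices[int(rng.integers(0, 3))]
                est_id = f"est{counter:05d}"
                counter += 1
                records.append((est_id, "".join(read)))
                rows.append(
                    {
                        "est_id": est_id,
                        "gene": gene,
                        "tissue": tissue,
                        "length": length,
                        "n_mismatches": n_mut,
                    }
                )
    return records, pd.DataFrame(rows)
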