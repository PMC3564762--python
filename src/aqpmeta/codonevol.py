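"""Pairwise coding-sequence divergence: dN, dS (Nei–Gojobori 1986 counting with
Jukes–Cantor correction) and 4DTV (proportion of shared four-fold degenerate
third-codon positions that differ by a transversion).

The estimator works on a pre-made codon alignment of two sequences.  Codon
columns containing a gap in either sequence are dropped before counting.
Internal stop codons are rejected.

Counting conventions
--------------------
* Synonymous/nonsynonymous *sites* per codon: at each of the three positions
  the fraction of the three possible single-nucleotide changes that preserve
  the encoded amino acid (a change producing a stop codon is nonsynonymous).
  Summed over positions this gives ``s``; ``n = 3 - s``, so ``n + s == 3``
  exactly for every sense codon.
* Observed differences between two codons: a single difference is classified
  directly; two or three differences are averaged, with equal weights, over
  every mutational pathway whose intermediate codons are not stop codons.
* Proportions are corrected for multiple hits with the Jukes–Cantor formula
  ``d = -(3/4) ln(1 - 4p/3)``; the correction is undefined for ``p >= 3/4``.
* A 4DTV site is a codon third position at which both sequences carry a
  four-fold degenerate codon AND the first two codon positions are identical
  across the two sequences; a transversion is a purine<->pyrimidine difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = ("A", "C", "G", "T")
PURINES = frozenset("AG")

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))

#: dinucleotide prefixes whose four codons all encode the same amino acid
FOURFOLD_PREFIXES: frozenset[str] = frozenset(
    p
    for p in {c[:2] for c in SENSE_CODONS}
    if all(p + b in CODON_TABLE for b in NUCLEOTIDES)
    and len({CODON_TABLE[p + b] for b in NUCLEOTIDES}) == 1
)


def is_transversion(a: str, b: str) -> bool:
    """True when the two (different) bases are one purine and one pyrimidine."""
    return (a in PURINES) != (b in PURINES)


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Return ``(synonymous_sites, nonsynonymous_sites)`` for a sense codon.

    Raises ``ValueError`` for stop codons or malformed input.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in CODON_TABLE:
        raise ValueError(f"not a valid codon: {codon!r}")
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE.get(mutant) == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


def codon_difference_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Return ``(Sd, Nd)``: observed synonymous and nonsynonymous differences.

    Multi-hit codon pairs are averaged over all mutational pathways that avoid
    stop-codon intermediates, with equal weights.  If every pathway passes
    through a stop (possible only for contrived pairs), all pathways are used.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in CODON_TABLE:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd

    paths = [walk(order) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:  # fall back to all pathways, classifying through stops
        valid = []
        for order in permutations(diff_positions):
            sd = nd = 0.0
            current = codon_a
            for pos in order:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
                if CODON_TABLE.get(current) == CODON_TABLE.get(nxt):
                    sd += 1.0
                else:
                    nd += 1.0
                current = nxt
            valid.append((sd, nd))
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


@dataclass(frozen=True)
class DivergenceEstimate:
    """Pairwise divergence summary for one aligned CDS pair."""

    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: float | None  # dN/dS; None when dS == 0 (undefined)
    n_4fold_sites: int
    n_4fold_transversions: int
    fourDTV: float | None  # None when no qualifying site


def _codon_columns(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal lengths")
    if len(seq_a) % 3:
        raise ValueError("alignment length must be divisible by 3")
    columns = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue  # drop any codon column with a gap in either sequence
        for c in (ca, cb):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon {c!r} at position {i}")
            if c not in CODON_TABLE:
                raise ValueError(f"invalid codon {c!r} at position {i}")
        columns.append((ca, cb))
    return columns


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction ``d = -(3/4) ln(1 - 4p/3)``."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"correction undefined for proportion {p} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_dn_ds(seq_a: str, seq_b: str) -> DivergenceEstimate:
    """Estimate dN, dS, dN/dS and 4DTV for two aligned coding sequences."""
    columns = _codon_columns(seq_a, seq_b)
    if not columns:
        raise ValueError("no ungapped codon columns in alignment")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in columns:
        sa, _ = codon_site_counts(ca)
        sb, _ = codon_site_counts(cb)
        s_a += sa
        s_b += sb
        d_s, d_n = codon_difference_counts(ca, cb)
        sd += d_s
        nd += d_n
    n_codons = len(columns)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    ratio = dN / dS if dS > 0 else None
    n_sites, n_tv, fourdtv = compute_4dtv(seq_a, seq_b)
    return DivergenceEstimate(
        n_codons=n_codons, N_sites=N, S_sites=S, Nd=nd, Sd=sd,
        pN=pN, pS=pS, dN=dN, dS=dS, ratio=ratio,
        n_4fold_sites=n_sites, n_4fold_transversions=n_tv, fourDTV=fourdtv,
    )


def compute_4dtv(seq_a: str, seq_b: str) -> tuple[int, int, float | None]:
    """Count shared four-fold degenerate sites and transversions among them.

    Returns ``(n_4fold_sites, n_transversions, fourDTV)``; ``fourDTV`` is
    ``None`` when no site qualifies.
    """
    n_sites = n_tv = 0
    for ca, cb in _codon_columns(seq_a, seq_b):
        if ca[:2] != cb[:2]:
            continue
        if ca[:2] not in FOURFOLD_PREFIXES:
            continue
        n_sites += 1
        if ca[2] != cb[2] and is_transversion(ca[2], cb[2]):
            n_tv += 1
    return n_sites, n_tv, (n_tv / n_sites if n_sites else None)


def ratio_table(pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Build a per-pair divergence report with a dN/dS column and range summary.

    ``pairs`` needs columns ``pair``, ``duplication``, ``dN``, ``dS`` and an
    optional boolean ``pseudogene`` column.  The ratio is recomputed as
    ``dN/dS`` rounded to 3 decimals (``NA`` when ``dS == 0``); the summary
    reports the minimum over all pairs and the maximum over non-pseudogene
    pairs, both rounded to 2 decimals.
    """
    required = {"pair", "duplication", "dN", "dS"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    out = pairs.copy()
    if "pseudogene" not in out.columns:
        out["pseudogene"] = False
    ratios = []
    for dn, ds in zip(out["dN"], out["dS"]):
        ratios.append(round(dn / ds, 3) if ds > 0 else None)
    out["ratio"] = ratios
    defined = out["ratio"].notna()
    summary = {
        "min_ratio": round(float(out.loc[defined, "ratio"].min()), 2),
        "max_ratio_non_pseudogene": round(
            float(out.loc[defined & ~out["pseudogene"].astype(bool), "ratio"].max()), 2
        ),
        "n_pairs": int(len(out)),
    }
    return out, summary


def estimate_pairs(
    alignments: Iterable[tuple[str, str, str, str]],
) -> pd.DataFrame:
    """Estimate divergence for many pairs.

    ``alignments`` yields ``(pair_id, duplication_type, seq_a, seq_b)``.
    Returns a divergence table (one row per pair).
    """
    rows = []
    for pair_id, dup, seq_a, seq_b in alignments:
        est = estimate_dn_ds(seq_a, seq_b)
        rows.append(
            {
                "pair": pair_id,
                "duplication": dup,
                "n_codons": est.n_codons,
                "N_sites": est.N_sites,
                "S_sites": est.S_sites,
                "Nd": est.Nd,
                "Sd": est.Sd,
                "dN": est.dN,
                "dS": est.dS,
                "ratio": est.ratio,
                "fourDTV": est.fourDTV,
            }
        )
    return pd.DataFrame(rows)
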