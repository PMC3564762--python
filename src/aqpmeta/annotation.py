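"""Probe-set -> gene reannotation and EST -> gene assignment.

Alignment execution is delegated to an external aligner (or to synthetic
fixtures); this module's contract starts at the standard 12-column tabular
hit format.  Coordinates are 1-based inclusive; a minus-strand hit is encoded
by subject start > subject end, never by negative coordinates.

Validity filtering follows the meta-analysis rules: a probe set is rejected
when it is designed on the minus strand, when its best-hit bit score is tied
across more than one gene (ambiguous), when its target falls entirely within
an intron, or when its target is flagged invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

EST_MIN_IDENTITY = 96.0  # percent identity, strict ">"
EST_MIN_LENGTH = 100     # alignment length in bp, ">="


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.q_start > self.q_end:
            raise ValueError("query coordinates must satisfy q_start <= q_end")

    @property
    def minus_strand(self) -> bool:
        return self.s_start > self.s_end

    @property
    def s_interval(self) -> tuple[int, int]:
        """Subject interval as (low, high), 1-based inclusive."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, 1-based incl.
    coding_sequence: str = ""

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon ({start},{end}) of {self.gene_id} reversed")
            if start <= prev_end:
                raise ValueError(f"exons of {self.gene_id} overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class ProbeSetRecord:
    probeset_id: str
    evidence_sources: frozenset[str] = frozenset()
    assigned_gene: str | None = None
    design_species: str | None = None
    region: str | None = None  # "exonic" | "intronic" | None
    flags: set[str] = field(default_factory=set)

    @property
    def valid(self) -> bool:
        return self.assigned_gene is not None and not self.flags


@dataclass(frozen=True)
class ESTAssignment:
    est_id: str
    assigned_gene: str
    tissue: str | None
    bit_score: float
    percent_identity: float
    align_length: int


def parse_tabular_hits(source) -> list[AlignmentHit]:
    """Parse 12-column tabular alignment rows from a path or open text handle.

    Malformed rows raise ``ValueError`` carrying the 1-based line number.
    Blank lines and ``#`` comment lines are skipped.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    hits = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:  # tolerate whitespace-delimited test fixtures
            fields = line.split()
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated fields, got {len(fields)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


def filter_est_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = EST_MIN_IDENTITY,
    min_length: int = EST_MIN_LENGTH,
) -> list[AlignmentHit]:
    """Keep hits above ``min_identity`` (strict) and at least ``min_length`` bp."""
    return [
        h
        for h in hits
        if h.percent_identity > min_identity and h.align_length >= min_length
    ]


def _hit_rank(hit: AlignmentHit) -> tuple:
    """Sort key: best hit first (bit score, identity, length, subject id)."""
    return (-hit.bit_score, -hit.percent_identity, -hit.align_length, hit.subject_id)


def best_hits_per_query(
    hits: Iterable[AlignmentHit],
) -> dict[str, list[AlignmentHit]]:
    """Group hits by query and sort each group best-first (deterministic)."""
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    for q in grouped:
        grouped[q].sort(key=_hit_rank)
    return grouped


def assign_ests(
    forward_hits: Iterable[AlignmentHit] | None,
    reverse_hits: Iterable[AlignmentHit],
    metadata: Mapping[str, str] | None = None,
) -> list[ESTAssignment]:
    """Assign each EST to a single gene by its best reverse hit.

    ``forward_hits`` (gene queries vs EST collection) restrict the candidate
    ESTs to those detected in the forward search; pass ``None`` to consider
    every EST with a reverse hit.  Reverse hits (EST queries vs transcripts)
    decide the assignment: highest bit score, ties broken by higher identity,
    then longer alignment, then lexicographically smaller gene id.  ESTs with
    no passing reverse hit remain unassigned (omitted).
    """
    metadata = metadata or {}
    candidates = None
    if forward_hits is not None:
        candidates = {h.subject_id for h in forward_hits}
    grouped = best_hits_per_query(reverse_hits)
    assignments = []
    for est_id in sorted(grouped):
        if candidates is not None and est_id not in candidates:
            continue
        best = grouped[est_id][0]
        assignments.append(
            ESTAssignment(
                est_id=est_id,
                assigned_gene=best.subject_id,
                tissue=metadata.get(est_id),
                bit_score=best.bit_score,
                percent_identity=best.percent_identity,
                align_length=best.align_length,
            )
        )
    return assignments


def _locate_gene(
    hit: AlignmentHit, gene_models: Sequence[GeneModel]
) -> tuple[str | None, str | None]:
    """Map a genomic hit to an overlapping gene model and region class.

    The subject id of the hit is matched against the chromosome (genomic
    alignment) or directly against a gene id (transcript alignment).  The
    region is ``exonic`` when the hit interval overlaps any exon, and
    ``intronic`` when it lies inside the gene span without touching an exon.
    """
    lo, hi = hit.s_interval
    for gm in gene_models:
        if hit.subject_id == gm.gene_id:
            return gm.gene_id, "exonic"
        if hit.subject_id != gm.chromosome:
            continue
        span_lo, span_hi = gm.span
        if hi < span_lo or lo > span_hi:
            continue
        for ex_lo, ex_hi in gm.exons:
            if not (hi < ex_lo or lo > ex_hi):
                return gm.gene_id, "exonic"
        return gm.gene_id, "intronic"
    return None, None


def reannotate_probesets(
    target_hits: Iterable[AlignmentHit],
    gene_models: Sequence[GeneModel],
) -> dict[str, ProbeSetRecord]:
    """Assign each probe set to the gene of its best target-sequence hit.

    The best hit per probe set follows the same tie-break cascade as EST
    assignment.  A tie in best bit score that maps to more than one distinct
    gene raises the ``ambiguous`` flag.  Intronic placement and minus-strand
    design raise their respective flags; probe sets whose best hit overlaps no
    gene model stay unassigned with the ``invalid_target`` flag.
    """
    grouped = best_hits_per_query(target_hits)
    records: dict[str, ProbeSetRecord] = {}
    for ps_id in sorted(grouped):
        ranked = grouped[ps_id]
        best = ranked[0]
        gene, region = _locate_gene(best, gene_models)
        record = ProbeSetRecord(probeset_id=ps_id, assigned_gene=gene, region=region)
        if gene is None:
            record.flags.add("invalid_target")
        else:
            top_genes = set()
            for h in ranked:
                if h.bit_score < best.bit_score:
                    break
                g, _ = _locate_gene(h, gene_models)
                if g is not None:
                    top_genes.add(g)
            if len(top_genes) > 1:
                record.flags.add("ambiguous")
            if region == "intronic":
                record.flags.add("intronic")
        if best.minus_strand:
            record.flags.add("minus_strand")
        records[ps_id] = record
    return records


def reconcile_evidence(
    source_sets: Mapping[str, Iterable[str]],
    records: Mapping[str, ProbeSetRecord] | None = None,
) -> tuple[dict[str, int], dict[str, frozenset[str]]]:
    """Combine evidence sources into a Venn breakdown and per-probe-set union.

    Returns ``(venn_counts, evidence)``: ``venn_counts`` maps each non-empty
    source combination (sources joined by ``&`` in sorted order) to the number
    of probe sets carrying exactly that combination; ``evidence`` maps each
    probe set to its full evidence-source set.  When ``records`` is given the
    evidence sets are written onto the records in place.
    """
    if not source_sets:
        raise ValueError("at least one evidence source required")
    sets = {name: frozenset(ids) for name, ids in source_sets.items()}
    union = sorted(set().union(*sets.values()))
    evidence: dict[str, frozenset[str]] = {}
    venn: dict[str, int] = {}
    for ps in union:
        combo = frozenset(name for name, ids in sets.items() if ps in ids)
        evidence[ps] = combo
        key = "&".join(sorted(combo))
        venn[key] = venn.get(key, 0) + 1
    if records is not None:
        for ps, combo in evidence.items():
            if ps in records:
                records[ps].evidence_sources = combo  # type: ignore[misc]
    return venn, evidence


REJECTION_ORDER = ("minus_strand", "ambiguous", "intronic", "invalid_target")


def filter_probesets(
    records: Mapping[str, ProbeSetRecord],
) -> tuple[dict[str, ProbeSetRecord], list[tuple[str, str]]]:
    """Split records into valid probe sets and a rejection log.

    A record is rejected when any flag is raised or no gene is assigned; the
    logged reason is the first raised flag in the order minus_strand,
    ambiguous, intronic, invalid_target.
    """
    valid: dict[str, ProbeSetRecord] = {}
    rejected: list[tuple[str, str]] = []
    for ps in sorted(records):
        rec = records[ps]
        if rec.valid:
            valid[ps] = rec
            continue
        reason = next(
            (f for f in REJECTION_ORDER if f in rec.flags),
            "unassigned" if rec.assigned_gene is None else "flagged",
        )
        rejected.append((ps, reason))
    return valid, rejected


def est_tissue_table(
    assignments: Iterable[ESTAssignment],
    all_genes: Iterable[str] | None = None,
    known_tissues: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tabulate EST counts per gene x tissue.

    Genes listed in ``all_genes`` but lacking ESTs appear as zero rows —
    absence of expression evidence is informative and must not be silently
    dropped.  Unknown tissue labels are kept verbatim (a warning is printed to
    stderr when ``known_tissues`` is supplied).
    """
    import sys

    rows: dict[str, dict[str, int]] = {}
    tissues: set[str] = set()
    known = set(known_tissues) if known_tissues is not None else None
    for a in assignments:
        tissue = a.tissue or "unknown"
        if known is not None and tissue not in known:
            print(f"warning: unknown tissue label {tissue!r}", file=sys.stderr)
        tissues.add(tissue)
        rows.setdefault(a.assigned_gene, {})
        rows[a.assigned_gene][tissue] = rows[a.assigned_gene].get(tissue, 0) + 1
    genes = set(rows)
    if all_genes is not None:
        genes |= set(all_genes)
    table = pd.DataFrame(
        0, index=sorted(genes), columns=sorted(tissues) or ["unknown"], dtype=int
    )
    for gene, counts in rows.items():
        for tissue, n in counts.items():
            table.loc[gene, tissue] = n
    table.index.name = "gene"
    return table
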