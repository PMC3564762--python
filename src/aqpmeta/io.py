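"""On-disk TSV/JSON contracts binding the pipeline stages together.

Every writer's output is parseable by its reader with lossless field values;
TSV with a header row is the universal tabular contract, JSON is used only
for nested summaries and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import GeneModel, ProbeSetRecord
from .regulation import RegulationEvent
from .synthetic import GroundTruth


def save_simulation(
    outdir: str | Path,
    matrices: Mapping[str, pd.DataFrame],
    design: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Write per-experiment matrices, the design sheet and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for exp_id, matrix in matrices.items():
        matrix.to_csv(outdir / f"matrix_{exp_id}.tsv", sep="\t",
                      index_label="probeset")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    annotation = pd.DataFrame(
        {
            "probeset_id": sorted(truth.probeset_gene),
            "gene_id": [truth.probeset_gene[p] for p in sorted(truth.probeset_gene)],
            "design_species": [truth.probe_species[p]
                               for p in sorted(truth.probeset_gene)],
            "valid": True,
        }
    )
    annotation.to_csv(outdir / "probe_annotation.tsv", sep="\t", index=False)
    pd.DataFrame(truth.pairs, columns=["gene_a", "gene_b", "duplication"]).to_csv(
        outdir / "pairs.tsv", sep="\t", index=False
    )
    truth_json = {
        "gene_baseline": truth.gene_baseline,
        "gene_tissues": {g: sorted(t) for g, t in truth.gene_tissues.items()},
        "effects": {
            f"{g}|{e}|{c}": v for (g, e, c), v in sorted(truth.effects.items())
        },
        "experiment_species": truth.experiment_species,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth_json, indent=1))


def load_matrices(outdir: str | Path) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    outdir = Path(outdir)
    matrices = {}
    for path in sorted(outdir.glob("matrix_*.tsv")):
        exp_id = path.stem.removeprefix("matrix_")
        matrices[exp_id] = pd.read_csv(path, sep="\t", index_col="probeset")
    design = pd.read_csv(outdir / "design.tsv", sep="\t",
                         keep_default_na=False, dtype={"timepoint": str})
    return matrices, design


def load_probe_annotation(path: str | Path) -> dict[str, str]:
    """Read a probe-annotation TSV into a valid probeset -> gene map."""
    df = pd.read_csv(path, sep="\t")
    valid = df[df["valid"].astype(bool)] if "valid" in df.columns else df
    return dict(zip(valid["probeset_id"], valid["gene_id"]))


def write_probe_annotation(
    path: str | Path,
    records: Mapping[str, ProbeSetRecord],
) -> None:
    rows = []
    for ps in sorted(records):
        rec = records[ps]
        rows.append(
            {
                "probeset_id": ps,
                "gene_id": rec.assigned_gene or "",
                "evidence": ",".join(sorted(rec.evidence_sources)),
                "region": rec.region or "",
                "flags": ",".join(sorted(rec.flags)),
                "valid": rec.valid,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene-model TSV: gene_id, chromosome, strand, exon_start, exon_end rows."""
    df = pd.read_csv(path, sep="\t")
    models = []
    for (gene, chrom, strand), sub in df.groupby(
        ["gene_id", "chromosome", "strand"], sort=True
    ):
        exons = tuple(
            sorted(zip(sub["exon_start"].astype(int), sub["exon_end"].astype(int)))
        )
        models.append(GeneModel(gene_id=gene, chromosome=chrom,
                                strand=strand, exons=exons))
    return models


def events_to_frame(events: Iterable[RegulationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": ev.gene_id,
                "comparison": ev.comparison_id,
                "log2_ratio": ev.log2_ratio,
                "fold_change": ev.fold_change,
                "direction": ev.direction,
                "strength": ev.strength,
            }
            for ev in events
        ]
    )


def frame_to_events(df: pd.DataFrame) -> list[RegulationEvent]:
    return [
        RegulationEvent(
            gene_id=row["gene"],
            comparison_id=row["comparison"],
            log2_ratio=float(row["log2_ratio"]),
            fold_change=float(row["fold_change"]),
            direction=row["direction"],
            strength=row["strength"],
        )
        for _, row in df.iterrows()
    ]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
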