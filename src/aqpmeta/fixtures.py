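"""Typed readers for the packaged reference tables.

Two small TSV fixtures ship with the package:

* ``pair_divergence.tsv`` — the duplicate-pair divergence table (duplication
  type, dN, dS, printed dN/dS, pseudogene flag);
* ``responsiveness_map.tsv`` — the gene x (cue, tissue) responsiveness-code
  map with its per-column comparison counts.

Each reader verifies a SHA-256 checksum so silent fixture corruption cannot
propagate into downstream numbers.
"""

from __future__ import annotations

import hashlib
import re
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "pair_divergence.tsv":
        "85ca653561f9b58f6b5d662bb3109c1b9be1b7f396c92cae6b1c8a1140b567d5",
    "responsiveness_map.tsv":
        "d800056b5ff60a0a7e14c36adf56ba6696dd73c77e87d2ee5eea76399614aa11",
}

CODE_PATTERN = re.compile(r"^(-|C|x|\d+)$")


def _load_text(name: str) -> str:
    text = resources.files("aqpmeta.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(f"fixture {name!r} checksum mismatch: {digest}")
    return text


def read_pair_divergence() -> pd.DataFrame:
    """Duplicate-pair divergence table: one row per pair.

    Columns: pair, duplication (S/T/Nd), dN, dS, dNdS_printed, pseudogene.
    """
    from io import StringIO

    df = pd.read_csv(StringIO(_load_text("pair_divergence.tsv")),
                     sep="\t", comment="#")
    df["pseudogene"] = df["pseudogene"].astype(bool)
    return df


def read_responsiveness_map() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Responsiveness-code map.

    Returns ``(codes, columns)``: ``codes`` is a gene x column DataFrame of
    codes in {-, C, x, integer-as-string} with a positional column index;
    ``columns`` describes each column (group, cue, tissue, n_comparisons).
    """
    lines = [ln for ln in _load_text("responsiveness_map.tsv").splitlines()
             if ln and not ln.startswith("#")]
    header = {}
    gene_rows = []
    for ln in lines:
        fields = ln.split("\t")
        if fields[0] in ("group", "cue", "tissue", "n_comparisons"):
            header[fields[0]] = fields[1:]
        else:
            gene_rows.append(fields)
    n_cols = len(header["group"])
    columns = pd.DataFrame(
        {
            "group": header["group"],
            "cue": header["cue"],
            "tissue": header["tissue"],
            "n_comparisons": [int(x) for x in header["n_comparisons"]],
        }
    )
    genes = [r[0] for r in gene_rows]
    data = [r[1:] for r in gene_rows]
    codes = pd.DataFrame(data, index=genes)
    codes.index.name = "gene"
    if codes.shape[1] != n_cols:
        raise ValueError("responsiveness map rows do not match header width")
    bad = [
        (g, c) for g, row in codes.iterrows() for c in row
        if not CODE_PATTERN.match(c)
    ]
    if bad:
        raise ValueError(f"invalid responsiveness codes: {bad[:5]}")
    return codes, columns


def never_regulated_genes(codes: pd.DataFrame) -> list[str]:
    """Genes whose entire responsiveness row is '-' (never regulated)."""
    return sorted(g for g, row in codes.iterrows() if (row == "-").all())
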