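"""Readers and writers for the pipeline's plain-text table dialects.

Gene abundances, taxonomy hits and group labels travel as TSV; enzyme
alignment hits use the BLAST tabular (outfmt-6-like) layout with a
companion reference-map TSV translating subject ids to enzyme names; the
BA panel and clinical tables are CSV.  All writers are deterministic so
that identical simulations produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .vocab import RANKS

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_abundance(abundance: pd.DataFrame, path) -> None:
    abundance.rename_axis("gene_id").to_csv(path, sep="\t")


def read_abundance(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_groups(groups: pd.Series, path) -> None:
    groups.rename_axis("sample_id").rename("group").to_csv(path, sep="\t")


def read_groups(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col="sample_id")
    return frame["group"]


def write_enzyme_hits(hits: pd.DataFrame, hits_path, refmap_path) -> None:
    """Write hits as BLAST outfmt-6 plus the sseqid -> enzyme reference map."""
    out = pd.DataFrame({
        "qseqid": hits["gene_id"],
        "sseqid": hits["enzyme"].map(lambda e: f"ref|{e}"),
        "pident": hits["pident"].round(2),
        "length": 300,
        "mismatch": ((100 - hits["pident"]) * 3).astype(int),
        "gapopen": 0,
        "qstart": 1,
        "qend": 300,
        "sstart": 1,
        "send": 300,
        "evalue": hits["evalue"],
        "bitscore": hits["bitscore"].round(1),
    })
    out.to_csv(hits_path, sep="\t", index=False, header=False)
    refmap = (
        hits[["enzyme"]].drop_duplicates().sort_values("enzyme")
        .assign(sseqid=lambda d: "ref|" + d["enzyme"])
    )
    refmap[["sseqid", "enzyme"]].to_csv(refmap_path, sep="\t", index=False)


def read_enzyme_hits(hits_path, refmap_path) -> pd.DataFrame:
    """Read outfmt-6 hits and translate subject ids to enzyme names."""
    raw = pd.read_csv(hits_path, sep="\t", names=OUTFMT6_COLUMNS)
    refmap = pd.read_csv(refmap_path, sep="\t")
    mapping = dict(zip(refmap["sseqid"], refmap["enzyme"]))
    unknown = set(raw["sseqid"]) - set(mapping)
    if unknown:
        raise ValueError(f"subject ids missing from reference map: {sorted(unknown)[:5]}")
    return pd.DataFrame({
        "gene_id": raw["qseqid"],
        "enzyme": raw["sseqid"].map(mapping),
        "pident": raw["pident"],
        "evalue": raw["evalue"],
        "bitscore": raw["bitscore"],
    })


def write_taxhits(taxhits: pd.DataFrame, path) -> None:
    taxhits[["gene_id", "evalue", *RANKS]].to_csv(path, sep="\t", index=False)


def read_taxhits(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    frame["evalue"] = frame["evalue"].astype(float)
    return frame


def write_ba_panel(panel: pd.DataFrame, path) -> None:
    panel.rename_axis("sample_id").to_csv(path)


def read_ba_panel(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_clinical(table: pd.DataFrame, path) -> None:
    table.rename_axis("subject_id").to_csv(path)


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
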