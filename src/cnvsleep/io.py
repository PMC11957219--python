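"""Readers and writers for the tab-delimited interchange formats.

Coordinates are written 0-based half-open (BED convention) everywhere.
Floats are written with a fixed format so identical inputs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"

CNV_COLUMNS = ["individual_id", "chrom", "start", "end", "cnv_type"]
LOCUS_COLUMNS = ["label", "chrom", "start", "end", "cnv_type"]


def write_cnv_calls(calls: pd.DataFrame, path) -> None:
    calls[CNV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cnv_calls(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "chrom": str})
    missing = set(CNV_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"CNV call table {path} missing columns: {sorted(missing)}")
    bad = ~calls["cnv_type"].isin(["DEL", "DUP"])
    if bad.any():
        raise ValueError(
            f"CNV call table {path}: invalid cnv_type {calls.loc[bad, 'cnv_type'].iloc[0]!r}"
        )
    return calls


def write_gene_model(genes: pd.DataFrame, bed_path, loeuf_path) -> None:
    """Gene intervals as 4-column BED plus a LOEUF sidecar TSV."""
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        bed_path, sep="\t", index=False, header=False
    )
    genes[["gene_id", "loeuf"]].to_csv(
        loeuf_path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def write_loci(loci: pd.DataFrame, path) -> None:
    loci[LOCUS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_loci(path) -> pd.DataFrame:
    loci = pd.read_csv(path, sep="\t", dtype={"label": str, "chrom": str})
    missing = set(LOCUS_COLUMNS) - set(loci.columns)
    if missing:
        raise ValueError(f"locus table {path} missing columns: {sorted(missing)}")
    return loci


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"individual_id": str})


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
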