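"""LOEUF-weighted CNV burden scoring.

The per-individual burden statistic is Σ 1/LOEUF over the distinct genes
covered by that individual's deletions (and, separately, duplications).
LOEUF (loss-of-function observed/expected upper-bound fraction) is a
gene-level constraint score on [0.03, 2]; low values mark genes intolerant
to haploinsufficiency, so 1/LOEUF up-weights the genes whose loss is most
deleterious.  Alongside the weighted sum, genes are counted in four
intolerance categories:

    highly intolerant      0.03 <= LOEUF < 0.2
    intolerant             0.2  <= LOEUF < 0.35
    moderately intolerant  0.35 <= LOEUF < 1
    tolerant               1    <= LOEUF <= 2

The tolerant bin is closed at the top; LOEUF values outside [0.03, 2] are
clamped on ingestion.  Genes without a LOEUF annotation are retained in the
gene model but contribute neither to the weighted sum nor to any category.
"""

from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

LOEUF_MIN = 0.03
LOEUF_MAX = 2.0

CATEGORY_NAMES = (
    "highly_intolerant",
    "intolerant",
    "moderately_intolerant",
    "tolerant",
)
# interior edges; lower bounds inclusive, top bin closed at LOEUF_MAX
CATEGORY_EDGES = np.array([0.2, 0.35, 1.0])

CNV_TYPES = ("DEL", "DUP")


def normalize_chrom(chrom: pd.Series | Sequence[str]) -> pd.Series:
    """Strip a leading 'chr' so calls and genes share a naming convention."""
    s = pd.Series(chrom, copy=False).astype(str)
    return s.str.replace(r"^chr", "", regex=True)


def clamp_loeuf(values: np.ndarray, *, warn: bool = True) -> np.ndarray:
    """Clamp LOEUF values into [0.03, 2]; NaN passes through unchanged."""
    arr = np.asarray(values, dtype=float)
    out_of_range = (~np.isnan(arr)) & ((arr < LOEUF_MIN) | (arr > LOEUF_MAX))
    if warn and out_of_range.any():
        logger.warning(
            "%d LOEUF value(s) outside [%.2f, %.2f]; clamped",
            int(out_of_range.sum()), LOEUF_MIN, LOEUF_MAX,
        )
    return np.clip(arr, LOEUF_MIN, LOEUF_MAX)


def loeuf_category(values) -> np.ndarray:
    """Map LOEUF values to category index 0..3 (-1 for missing).

    Lower bounds are inclusive for every bin; the tolerant bin additionally
    includes its upper bound (values are clamped to <= 2 upstream).
    """
    arr = np.asarray(values, dtype=float)
    idx = np.digitize(arr, CATEGORY_EDGES, right=False)
    idx = np.where(np.isnan(arr), -1, idx)
    return idx.astype(int)


def read_gene_model(gene_path, loeuf_path=None) -> pd.DataFrame:
    """Read a BED-like gene table plus an optional LOEUF sidecar TSV.

    The BED file carries ``chrom start end gene_id`` (0-based half-open);
    the sidecar carries ``gene_id loeuf``.  Genes missing from the sidecar
    get NaN LOEUF.  Out-of-range LOEUF is clamped with a logged warning.
    """
    try:
        genes = pd.read_csv(
            gene_path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "gene_id": str},
        )
    except ValueError as exc:
        raise ValueError(f"unparseable gene table {gene_path}: {exc}") from exc
    for col in ("start", "end"):
        coerced = pd.to_numeric(genes[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 1
            raise ValueError(
                f"unparseable coordinate in column '{col}' of {gene_path}, line {line}"
            )
        genes[col] = coerced.astype(np.int64)
    if genes["gene_id"].duplicated().any():
        dupes = genes.loc[genes["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene IDs in {gene_path}: {list(dupes[:5])}")
    if (genes["start"] >= genes["end"]).any():
        raise ValueError(f"gene with start >= end in {gene_path}")
    genes["chrom"] = normalize_chrom(genes["chrom"])

    if loeuf_path is not None:
        loeuf = pd.read_csv(loeuf_path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in loeuf.columns or "loeuf" not in loeuf.columns:
            loeuf.columns = ["gene_id", "loeuf"][: len(loeuf.columns)]
        genes = genes.merge(loeuf[["gene_id", "loeuf"]], on="gene_id", how="left")
    else:
        genes["loeuf"] = np.nan
    genes["loeuf"] = clamp_loeuf(genes["loeuf"].to_numpy())
    return genes.reset_index(drop=True)


def read_gene_model_gtf(gtf_path, loeuf_path=None) -> pd.DataFrame:
    """Read gene records from a GTF (1-based closed -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        rows.append((normalize_chrom([feat.seqid])[0], feat.start - 1, feat.end, gene_id))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    if genes["gene_id"].duplicated().any():
        raise ValueError(f"duplicate gene IDs in {gtf_path}")
    if loeuf_path is not None:
        loeuf = pd.read_csv(loeuf_path, sep="\t", dtype={"gene_id": str})
        genes = genes.merge(loeuf[["gene_id", "loeuf"]], on="gene_id", how="left")
    else:
        genes["loeuf"] = np.nan
    genes["loeuf"] = clamp_loeuf(genes["loeuf"].to_numpy())
    return genes


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub.index)
        )
    return trees


def annotate_cnvs(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    *,
    overlap: str = "any",
) -> list[np.ndarray]:
    """For each CNV call, the gene-model row indices it covers.

    A gene is covered when its half-open interval shares >= 1 bp with the
    call (``overlap="any"``, the default) or lies fully inside the call
    (``overlap="containment"``).  Calls on chromosomes absent from the gene
    model yield empty lists.
    """
    if overlap not in ("any", "containment"):
        raise ValueError(f"unknown overlap rule: {overlap!r}")
    trees = _gene_trees(genes)
    chroms = normalize_chrom(calls["chrom"]).to_numpy()
    starts = calls["start"].to_numpy()
    ends = calls["end"].to_numpy()
    hits: list[np.ndarray] = []
    for chrom, s, e in zip(chroms, starts, ends):
        tree = trees.get(chrom)
        if tree is None:
            hits.append(np.empty(0, dtype=np.int64))
            continue
        ivs = tree.overlap(s, e)
        if overlap == "containment":
            ivs = [iv for iv in ivs if iv.begin >= s and iv.end <= e]
        hits.append(np.array(sorted(iv.data for iv in ivs), dtype=np.int64))
    return hits


def burden_columns() -> list[str]:
    cols = []
    for t in ("del", "dup"):
        cols.append(f"{t}_sum_inv_loeuf")
        cols.extend(f"{t}_n_{c}" for c in CATEGORY_NAMES)
        cols.append(f"{t}_n_genes")
    return cols


def burden_scores(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    *,
    gene_hits: list[np.ndarray] | None = None,
    individual_ids: Sequence[str] | None = None,
    overlap: str = "any",
) -> pd.DataFrame:
    """Per-individual Σ1/LOEUF and LOEUF-category gene counts, DEL and DUP.

    Genes covered by several same-type calls in one individual count once
    (the covered gene set is de-duplicated per individual and type).
    Individuals listed in ``individual_ids`` but absent from the calls get
    explicit zero rows.  ``{del,dup}_n_genes`` counts distinct covered genes
    with a LOEUF annotation, so the four category counts partition it.
    """
    if gene_hits is None:
        gene_hits = annotate_cnvs(calls, genes, overlap=overlap)

    loeuf = genes["loeuf"].to_numpy()
    inv_loeuf = np.where(np.isnan(loeuf), 0.0, 1.0 / loeuf)
    cat = loeuf_category(loeuf)

    ind = calls["individual_id"].to_numpy()
    typ = calls["cnv_type"].to_numpy()
    n_hits = np.array([len(h) for h in gene_hits], dtype=np.int64)
    if n_hits.sum() > 0:
        long = pd.DataFrame(
            {
                "individual_id": np.repeat(ind, n_hits),
                "cnv_type": np.repeat(typ, n_hits),
                "gene_idx": np.concatenate([h for h in gene_hits if len(h)])
                if n_hits.sum()
                else np.empty(0, dtype=np.int64),
            }
        ).drop_duplicates()
    else:
        long = pd.DataFrame(columns=["individual_id", "cnv_type", "gene_idx"])

    pieces = {}
    for cnv_type, tag in (("DEL", "del"), ("DUP", "dup")):
        sub = long[long["cnv_type"] == cnv_type]
        if len(sub):
            gi = sub["gene_idx"].to_numpy(dtype=np.int64)
            df = pd.DataFrame(
                {
                    "individual_id": sub["individual_id"].to_numpy(),
                    "inv": inv_loeuf[gi],
                    "cat": cat[gi],
                }
            )
            agg = df.groupby("individual_id").agg(
                s=("inv", "sum"), n=("cat", lambda c: int((c >= 0).sum()))
            )
            counts = (
                df[df["cat"] >= 0]
                .groupby(["individual_id", "cat"])
                .size()
                .unstack(fill_value=0)
                .reindex(columns=range(4), fill_value=0)
            )
            counts.columns = [f"{tag}_n_{c}" for c in CATEGORY_NAMES]
            piece = agg.rename(columns={"s": f"{tag}_sum_inv_loeuf", "n": f"{tag}_n_genes"})
            piece = piece.join(counts).fillna(0)
        else:
            piece = pd.DataFrame(
                {
                    col: pd.Series(dtype=float)
                    for col in [f"{tag}_sum_inv_loeuf", f"{tag}_n_genes"]
                    + [f"{tag}_n_{c}" for c in CATEGORY_NAMES]
                }
            )
        pieces[tag] = piece

    if individual_ids is None:
        ids = pd.Index(pd.unique(ind), name="individual_id")
    else:
        ids = pd.Index(individual_ids, name="individual_id")
    out = pd.DataFrame(index=ids)
    for tag in ("del", "dup"):
        out = out.join(pieces[tag])
    out = out.fillna(0.0)
    for col in out.columns:
        if "_n_" in col or col.endswith("_n_genes"):
            out[col] = out[col].astype(np.int64)
    return out[burden_columns()].reset_index()
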