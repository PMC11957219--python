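"""Score Σ1/LOEUF burden for hand-written CNV calls against a tiny gene model.

Shows the weighting arithmetic: a deletion covering genes with LOEUF
0.1, 0.5 and 2.0 scores 1/0.1 + 1/0.5 + 1/2 = 12.5, with one gene in each
of the highly-intolerant, moderately-intolerant and tolerant categories.
"""

import pandas as pd

from cnvsleep import burden_scores

genes = pd.DataFrame(
    {
        "chrom": ["1", "1", "1", "1"],
        "start": [1_000, 20_000, 40_000, 60_000],
        "end": [5_000, 30_000, 50_000, 70_000],
        "gene_id": ["CONSTRAINED", "AVERAGE", "TOLERANT", "UNSCORED"],
        "loeuf": [0.1, 0.5, 2.0, float("nan")],
    }
)
calls = pd.DataFrame(
    {
        "individual_id": ["sample1", "sample1", "sample2"],
        "chrom": ["1", "1", "1"],
        "start": [0, 35_000, 25_000],
        "end": [32_000, 72_000, 28_000],
        "cnv_type": ["DEL", "DEL", "DUP"],
    }
)

scores = burden_scores(calls, genes, individual_ids=["sample1", "sample2", "sample3"])
print(scores[["individual_id", "del_sum_inv_loeuf", "dup_sum_inv_loeuf",
              "del_n_genes"]].to_string(index=False))
# sample1's two deletions cover all four genes: Σ1/LOEUF = 12.5 (the
# unscored gene contributes nothing); sample2 duplicates one average gene
# (Σ = 2.0); sample3 has no calls and an explicit zero row.
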