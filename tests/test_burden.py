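"""Gene-model ingestion, CNV annotation and Σ1/LOEUF burden scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvsleep import burden
from conftest import make_calls


def brute_force_hits(calls, genes):
    """Independent all-pairs half-open overlap oracle."""
    gene_rows = [
        (gi, str(c).removeprefix("chr"), s, e)
        for gi, c, s, e in zip(genes.index, genes["chrom"], genes["start"], genes["end"])
    ]
    out = []
    for c in calls.itertuples(index=False):
        cc = str(c.chrom).removeprefix("chr")
        hit = [
            gi for gi, gc, gs, ge in gene_rows
            if gc == cc and c.start < ge and gs < c.end
        ]
        out.append(np.array(sorted(hit), dtype=np.int64))
    return out


def brute_force_scores(calls, genes):
    """Independent per-individual loop re-implementation of the burden score."""
    hits = brute_force_hits(calls, genes)
    records = {}
    for c, h in zip(calls.itertuples(index=False), hits):
        key = (c.individual_id, c.cnv_type)
        records.setdefault(key, set()).update(h)
    rows = {}
    for (ind, typ), gene_set in records.items():
        tag = typ.lower()
        row = rows.setdefault(ind, {})
        s = n = 0.0
        cat_counts = [0, 0, 0, 0]
        for gi in gene_set:
            l = genes.loc[gi, "loeuf"]
            if np.isnan(l):
                continue
            s += 1.0 / l
            n += 1
            if l < 0.2:
                cat_counts[0] += 1
            elif l < 0.35:
                cat_counts[1] += 1
            elif l < 1.0:
                cat_counts[2] += 1
            else:
                cat_counts[3] += 1
        row[f"{tag}_sum_inv_loeuf"] = s
        row[f"{tag}_n_genes"] = n
        for name, cnt in zip(burden.CATEGORY_NAMES, cat_counts):
            row[f"{tag}_n_{name}"] = cnt
    return rows


class TestReadGeneModel:
    def test_loeuf_join_leaves_unmatched_genes_missing(self, tmp_path, toy_genes):
        bed = tmp_path / "genes.bed"
        tsv = tmp_path / "loeuf.tsv"
        toy_genes[["chrom", "start", "end", "gene_id"]].to_csv(
            bed, sep="\t", header=False, index=False
        )
        pd.DataFrame({"gene_id": ["g1", "g2"], "loeuf": [0.1, 0.5]}).to_csv(
            tsv, sep="\t", index=False
        )
        genes = burden.read_gene_model(bed, tsv)
        assert list(genes["gene_id"]) == ["g1", "g2", "g3"]
        assert genes.loc[2, "gene_id"] == "g3" and np.isnan(genes.loc[2, "loeuf"])
        assert genes.loc[0, "loeuf"] == 0.1

    def test_out_of_range_loeuf_clamped_with_warning(self, tmp_path, toy_genes, caplog):
        bed = tmp_path / "genes.bed"
        tsv = tmp_path / "loeuf.tsv"
        toy_genes[["chrom", "start", "end", "gene_id"]].to_csv(
            bed, sep="\t", header=False, index=False
        )
        pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "loeuf": [2.5, 0.01, 0.5]}).to_csv(
            tsv, sep="\t", index=False
        )
        with caplog.at_level("WARNING"):
            genes = burden.read_gene_model(bed, tsv)
        assert genes.loc[0, "loeuf"] == 2.0
        assert genes.loc[1, "loeuf"] == 0.03
        assert any("clamp" in r.message.lower() for r in caplog.records)

    def test_empty_gene_file_gives_zero_scores(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("")
        genes = burden.read_gene_model(bed)
        assert len(genes) == 0
        calls = make_calls([("i1", "1", 0, 1000, "DEL")])
        scores = burden.burden_scores(calls, genes)
        assert scores.loc[0, "del_sum_inv_loeuf"] == 0.0
        assert scores.loc[0, "del_n_genes"] == 0

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t0\t10\tg1\n1\t20\t30\tg1\n")
        with pytest.raises(ValueError, match="duplicate"):
            burden.read_gene_model(bed)

    def test_unparseable_coordinate_names_line(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t0\t10\tg1\n1\tXX\t30\tg2\n")
        with pytest.raises(ValueError, match="line 2"):
            burden.read_gene_model(bed)

    def test_gtf_reader_converts_to_half_open(self, tmp_path):
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\tgene\t501\t800\t.\t-\t.\tgene_id "g2";\n'
        )
        genes = burden.read_gene_model_gtf(gtf)
        assert list(genes["start"]) == [100, 500]
        assert list(genes["end"]) == [200, 800]
        assert list(genes["chrom"]) == ["1", "1"]


class TestAnnotate:
    def test_half_open_boundary_one_bp_overlap(self, toy_genes):
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [199], "end": [300], "gene_id": ["g"],
             "loeuf": [0.5]}
        )
        hits = burden.annotate_cnvs(make_calls([("i", "1", 100, 200, "DEL")]), genes)
        assert list(hits[0]) == [0]

    def test_half_open_boundary_touching_is_no_overlap(self):
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [200], "end": [300], "gene_id": ["g"],
             "loeuf": [0.5]}
        )
        hits = burden.annotate_cnvs(make_calls([("i", "1", 100, 200, "DEL")]), genes)
        assert len(hits[0]) == 0

    def test_chr_prefix_normalized(self, toy_genes):
        hits = burden.annotate_cnvs(
            make_calls([("i", "chr1", 0, 2000, "DEL")]), toy_genes
        )
        assert list(hits[0]) == [0, 1, 2]

    def test_unknown_chromosome_yields_empty(self, toy_genes):
        hits = burden.annotate_cnvs(make_calls([("i", "9", 0, 2000, "DEL")]), toy_genes)
        assert len(hits[0]) == 0

    def test_containment_rule_excludes_partial(self, toy_genes):
        calls = make_calls([("i", "1", 150, 900, "DEL")])
        assert list(burden.annotate_cnvs(calls, toy_genes)[0]) == [0, 1]
        assert list(burden.annotate_cnvs(calls, toy_genes, overlap="containment")[0]) == [1]

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(5)
        starts = np.sort(rng.integers(0, 100_000, 50))
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(["1", "2"], 50),
                "start": starts,
                "end": starts + rng.integers(10, 5000, 50),
                "gene_id": [f"g{i}" for i in range(50)],
                "loeuf": rng.uniform(0.03, 2, 50),
            }
        )
        cs = rng.integers(0, 100_000, 30)
        calls = make_calls(
            [
                (f"i{j % 7}", rng.choice(["1", "2"]), s, s + rng.integers(100, 20_000),
                 rng.choice(["DEL", "DUP"]))
                for j, s in enumerate(cs)
            ]
        )
        got = burden.annotate_cnvs(calls, genes)
        expected = brute_force_hits(calls, genes)
        for g, e in zip(got, expected):
            assert list(g) == list(e)


class TestBurdenScores:
    def test_sum_and_category_arithmetic(self):
        genes = pd.DataFrame(
            {
                "chrom": ["1"] * 3,
                "start": [0, 100, 200],
                "end": [50, 150, 250],
                "gene_id": ["a", "b", "c"],
                "loeuf": [0.1, 0.5, 2.0],
            }
        )
        calls = make_calls([("i", "1", 0, 250, "DEL")])
        scores = burden.burden_scores(calls, genes).set_index("individual_id")
        assert scores.loc["i", "del_sum_inv_loeuf"] == pytest.approx(12.5)
        assert scores.loc["i", "del_n_highly_intolerant"] == 1
        assert scores.loc["i", "del_n_intolerant"] == 0
        assert scores.loc["i", "del_n_moderately_intolerant"] == 1
        assert scores.loc["i", "del_n_tolerant"] == 1
        assert scores.loc["i", "dup_sum_inv_loeuf"] == 0.0

    @pytest.mark.parametrize(
        "loeuf,category",
        [
            (0.03, "highly_intolerant"),
            (0.2, "intolerant"),
            (0.35, "moderately_intolerant"),  # lower bound inclusive
            (1.0, "tolerant"),
            (2.0, "tolerant"),  # top bin closed
        ],
    )
    def test_category_boundaries(self, loeuf, category):
        idx = burden.loeuf_category([loeuf])[0]
        assert burden.CATEGORY_NAMES[idx] == category

    def test_missing_loeuf_contributes_nothing(self, toy_genes):
        calls = make_calls([("i", "1", 0, 2000, "DEL")])
        scores = burden.burden_scores(calls, toy_genes).set_index("individual_id")
        # g1 (0.1) + g2 (0.5); g3 has no LOEUF
        assert scores.loc["i", "del_sum_inv_loeuf"] == pytest.approx(12.0)
        assert scores.loc["i", "del_n_genes"] == 2

    def test_same_type_duplicate_coverage_counts_once(self, toy_genes):
        calls = make_calls(
            [("i", "1", 0, 300, "DEL"), ("i", "1", 50, 250, "DEL"),
             ("i", "1", 0, 300, "DUP")]
        )
        scores = burden.burden_scores(calls, toy_genes).set_index("individual_id")
        assert scores.loc["i", "del_sum_inv_loeuf"] == pytest.approx(10.0)
        assert scores.loc["i", "dup_sum_inv_loeuf"] == pytest.approx(10.0)

    def test_absent_individuals_get_zero_rows(self, toy_genes):
        calls = make_calls([("i1", "1", 0, 300, "DEL")])
        scores = burden.burden_scores(
            calls, toy_genes, individual_ids=["i1", "i2"]
        ).set_index("individual_id")
        assert (scores.loc["i2"] == 0).all()

    def test_matches_independent_loop_oracle_on_simulated_cohort(self, small_sim):
        sub_ids = small_sim.cohort["individual_id"][:200]
        calls = small_sim.calls[small_sim.calls["individual_id"].isin(sub_ids)]
        got = burden.burden_scores(
            calls, small_sim.genes, individual_ids=sub_ids
        ).set_index("individual_id")
        expected = brute_force_scores(calls, small_sim.genes)
        for ind, row in expected.items():
            for col, val in row.items():
                assert got.loc[ind, col] == pytest.approx(val), (ind, col)

    def test_row_permutation_invariance(self, small_sim):
        calls = small_sim.calls.head(500)
        ids = sorted(calls["individual_id"].unique())
        a = burden.burden_scores(calls, small_sim.genes, individual_ids=ids)
        shuffled = calls.sample(frac=1.0, random_state=3).reset_index(drop=True)
        b = burden.burden_scores(shuffled, small_sim.genes, individual_ids=ids)
        pd.testing.assert_frame_equal(a, b)

    def test_score_additivity_over_disjoint_call_sets(self, toy_genes):
        part1 = make_calls([("i", "1", 0, 180, "DEL")])
        part2 = make_calls([("i", "1", 600, 1400, "DEL")])
        both = pd.concat([part1, part2], ignore_index=True)
        s_both = burden.burden_scores(both, toy_genes).set_index("individual_id")
        s1 = burden.burden_scores(part1, toy_genes).set_index("individual_id")
        s2 = burden.burden_scores(part2, toy_genes).set_index("individual_id")
        # parts cover disjoint gene sets, so scores add
        assert s_both.loc["i", "del_sum_inv_loeuf"] == pytest.approx(
            s1.loc["i", "del_sum_inv_loeuf"] + s2.loc["i", "del_sum_inv_loeuf"]
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        loeuf=st.floats(min_value=0.03, max_value=2.0, allow_nan=False),
        covered_before=st.booleans(),
    )
    def test_monotonicity_adding_a_deletion(self, loeuf, covered_before):
        """Covering a new gene adds exactly 1/LOEUF; re-covering adds 0."""
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [100], "end": [200], "gene_id": ["g"],
             "loeuf": [loeuf]}
        )
        base = (
            [("i", "1", 90, 150, "DEL")] if covered_before else
            [("i", "1", 300, 400, "DEL")]
        )
        before = burden.burden_scores(make_calls(base), genes).set_index("individual_id")
        after = burden.burden_scores(
            make_calls(base + [("i", "1", 120, 250, "DEL")]), genes
        ).set_index("individual_id")
        delta = after.loc["i", "del_sum_inv_loeuf"] - before.loc["i", "del_sum_inv_loeuf"]
        expected = 0.0 if covered_before else 1.0 / loeuf
        assert delta == pytest.approx(expected, abs=1e-12)
        # per-gene contribution bounded by the LOEUF span
        if not covered_before:
            assert 0.5 <= delta <= 1 / 0.03 + 1e-9
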