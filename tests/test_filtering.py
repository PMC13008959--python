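import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from circscape import filtering
from circscape.filtering import (
    RetentionConfig,
    apply_retention,
    circ_linear_ratio,
    classify_context,
    condition_overlap,
    merge_unique,
    score_stratification,
)


def cand(**kw):
    base = dict(
        chrom="chr1",
        acceptor=100,
        donor=500,
        strand="+",
        score=0.5,
        bsj_reads=2,
        sample="cold_R1",
        condition="cold",
        library="rnaser",
    )
    base.update(kw)
    return base


class TestClassifyContext:
    def test_contained_in_one_gene(self, toy_annotation):
        ctx, hosts = classify_context("chr1", 100, 500, toy_annotation)
        assert ctx == "intragenic" and hosts == {"A"}

    def test_one_endpoint_outside_all_genes(self, toy_annotation):
        ctx, hosts = classify_context("chr1", 100, 5000, toy_annotation)
        assert ctx == "intergenic" and hosts == set()

    def test_containment_requires_single_gene(self, toy_annotation):
        # acceptor in A and B's overlap zone, donor only inside B
        ctx, hosts = classify_context("chr1", 950, 1500, toy_annotation)
        assert ctx == "intragenic" and hosts == {"B"}


class TestRetention:
    def test_boundary_scores_dropped(self):
        df = pd.DataFrame(
            [
                cand(score=0.1, library="rnaser"),
                cand(score=0.100001, library="rnaser"),
                cand(score=0.9, library="control", sample="CK_C1", condition="CK"),
                cand(score=0.900001, library="control", sample="CK_C1", condition="CK"),
            ]
        )
        kept = apply_retention(df, RetentionConfig())
        assert list(kept["score"]) == [0.100001, 0.900001]

    def test_low_rnaser_score_dropped(self):
        df = pd.DataFrame([cand(score=0.05)])
        assert apply_retention(df, RetentionConfig()).empty

    def test_high_control_score_retained(self):
        df = pd.DataFrame(
            [cand(score=0.95, library="control", sample="CK_C1", condition="CK")]
        )
        assert len(apply_retention(df, RetentionConfig())) == 1

    def test_ultralong_span_dropped(self):
        df = pd.DataFrame([cand(score=0.8, acceptor=0, donor=250_000)])
        assert apply_retention(df, RetentionConfig(max_span=100_000)).empty

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_threshold(self, scores, t1, t2):
        lo, hi = sorted([t1, t2])
        df = pd.DataFrame([cand(score=round(s, 6)) for s in scores])
        keep_lo = apply_retention(df, RetentionConfig(rnaser_min_score=lo))
        keep_hi = apply_retention(df, RetentionConfig(rnaser_min_score=hi))
        assert set(keep_hi["score"]) <= set(keep_lo["score"])


class TestMergeUnique:
    def test_support_aggregated_across_samples(self):
        df = pd.DataFrame(
            [
                cand(bsj_reads=3, sample="cold_R1"),
                cand(bsj_reads=2, sample="cold_R2"),
            ]
        )
        (circ,) = merge_unique(df)
        assert circ.total_reads == 5
        assert circ.n_supporting_samples == 2
        assert not circ.low_support

    def test_single_read_single_sample_flagged(self):
        df = pd.DataFrame([cand(bsj_reads=1)])
        (circ,) = merge_unique(df)
        assert circ.low_support

    def test_opposite_strands_stay_distinct(self):
        df = pd.DataFrame([cand(strand="+"), cand(strand="-")])
        assert len(merge_unique(df)) == 2

    def test_per_condition_reads(self):
        df = pd.DataFrame(
            [
                cand(bsj_reads=3, condition="cold"),
                cand(bsj_reads=4, condition="heat", sample="heat_R1"),
            ]
        )
        (circ,) = merge_unique(df)
        assert circ.reads_per_condition == {"cold": 3, "heat": 4}


class TestConditionOverlap:
    def test_example_partition(self):
        res = condition_overlap(
            {"cold": {"a", "b", "c"}, "heat": {"b"}, "salt": {"b"}, "UVB": {"b"}}
        )
        assert res["unique_per_condition"]["cold"] == 2
        assert res["shared_by_all"] == 1

    def test_disjoint_sets_share_nothing(self):
        res = condition_overlap({"cold": {"a"}, "heat": {"b"}})
        assert res["shared_by_all"] == 0

    @given(
        st.dictionaries(
            st.sampled_from(["cold", "heat", "salt", "UVB"]),
            st.sets(st.integers(0, 49), max_size=50),
            min_size=2,
            max_size=4,
        )
    )
    def test_partition_sums_to_union(self, sets):
        res = condition_overlap(sets)
        assert sum(res["partition"].values()) == res["union_size"]

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError):
            condition_overlap({"cold": {"a"}})


class TestCircLinearRatio:
    @pytest.mark.parametrize(
        "c,l,expected", [(5, 0, 1.0), (0, 7, 0.0), (3, 7, 0.3), (0, 0, 0.0)]
    )
    def test_examples(self, c, l, expected):
        assert circ_linear_ratio(c, l) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            circ_linear_ratio(-1, 2)

    def test_rnaser_clr_dominates_control(self, bundle):
        """The RNase R libraries must show higher circular-to-linear
        ratios than controls (rank-sum, alpha 0.01)."""
        merged = pd.concat(
            [bundle.candidates, bundle.chloro_candidates], ignore_index=True
        )
        clr = filtering.clr_table(merged, bundle.linear_counts)
        rn = clr.loc[clr["library"] == "rnaser", "clr"]
        ct = clr.loc[clr["library"] == "control", "clr"]
        p = stats.mannwhitneyu(rn, ct, alternative="greater").pvalue
        assert p < 0.01
        contrast = filtering.clr_library_contrast(clr)
        assert contrast["fisher_p"] < 0.01
        assert contrast["median_clr_rnaser"] > contrast["median_clr_control"]


class TestScoreStratification:
    def test_single_bin_all_intragenic(self, toy_annotation):
        df = pd.DataFrame([cand(score=0.95, acceptor=100, donor=500)] * 10)
        table = score_stratification(df, toy_annotation)
        row = table[table["bin_left"] == 0.9].iloc[0]
        assert row["intragenic"] == 1  # distinct junctions, not rows
        assert row["intergenic_fraction"] == 0

    def test_score_one_falls_in_last_bin(self, toy_annotation):
        df = pd.DataFrame([cand(score=1.0)])
        table = score_stratification(df, toy_annotation)
        assert table.iloc[-1]["intragenic"] + table.iloc[-1]["intergenic"] == 1

    def test_low_bin_is_intergenic_enriched_on_synthetic_data(self, bundle):
        nuclear = bundle.candidates[
            bundle.candidates["chrom"] != "scaffold_UL"
        ]
        ann = bundle.annotation
        ann.known_contigs |= set(bundle.genome.contigs)
        table = score_stratification(nuclear, ann)
        low = table.iloc[0]["intergenic_fraction"]
        high = table.iloc[-1]["intergenic_fraction"]
        assert low > high

    def test_empty_input_gives_empty_table(self, toy_annotation):
        table = score_stratification(pd.DataFrame(columns=["chrom"]), toy_annotation)
        assert table.empty


class TestEndToEndRecovery:
    def test_retention_recovers_exactly_the_planted_circs(self, bundle):
        ann = bundle.annotation
        ann.known_contigs |= set(bundle.genome.contigs)
        retained = apply_retention(bundle.candidates, RetentionConfig(), ann)
        circs = merge_unique(retained, ann)
        planted = {
            (c["contig"], c["acceptor"], c["donor"], c["strand"])
            for c in bundle.truth.planted_circs
        }
        assert {c.key for c in circs} == planted
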