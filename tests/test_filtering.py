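"""Filter funnel: stage predicates and boundaries, count conservation,
nesting, final-set order invariance, gene-specific cutoffs, and the
exome-scale annotation fixture."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from updtrio.annotation import (
    AnnotationSimConfig,
    EngineeredVariant,
    read_annotation_table,
    simulate_annotated_variants,
    write_annotation_table,
)
from updtrio.filtering import (
    CONSEQUENCE_CLASSES,
    FilterConfig,
    GeneCutoffMap,
    exceeds_gene_cutoff,
    passes_funnel,
    run_funnel,
    stage_exonic_splice,
    stage_maf,
    stage_parent_shared,
    stage_synonymous_cadd,
)


def toy_table(rows):
    defaults = dict(chrom="1", pos=100, ref="A", alt="G", gene="GENE1",
                    consequence="exonic_nonsynonymous", cadd_phred=25.0,
                    pop_maf=0.0, gt_child="0/1", gt_mother="0/1", gt_father="0/0")
    if not rows:
        return pd.DataFrame(columns=list(defaults))
    return pd.DataFrame([{**defaults, **r} for r in rows])


@st.composite
def random_tables(draw):
    n = draw(st.integers(min_value=0, max_value=40))
    rows = []
    for i in range(n):
        rows.append(
            dict(
                pos=100 + i,
                consequence=draw(st.sampled_from(CONSEQUENCE_CLASSES)),
                cadd_phred=draw(st.floats(0, 60, allow_nan=False)),
                pop_maf=draw(st.floats(0, 0.5, allow_nan=False)),
                gt_mother=draw(st.sampled_from(["0/0", "0/1", "1/1", "./."])),
                gt_father=draw(st.sampled_from(["0/0", "0/1", "1/1", "./."])),
            )
        )
    return toy_table(rows)


class TestStages:
    def test_exonic_splice_predicate(self):
        table = toy_table(
            [{"consequence": c} for c in
             ["intergenic", "exonic_nonsynonymous", "intronic", "splice_site",
              "UTR", "exonic_synonymous", "intergenic", "exonic_nonsynonymous",
              "intronic", "UTR"]]
        )
        out = stage_exonic_splice(table)
        assert len(out) == 4
        assert set(out["consequence"]) <= {
            "exonic_nonsynonymous", "exonic_synonymous", "splice_site"
        }

    def test_all_intergenic_removed(self):
        assert len(stage_exonic_splice(toy_table([{"consequence": "intergenic"}] * 5))) == 0

    def test_unknown_consequence_rejected(self):
        with pytest.raises(ValueError, match="unknown consequence"):
            stage_exonic_splice(toy_table([{"consequence": "weird"}]))

    def test_synonymous_removed_regardless_of_score(self):
        table = toy_table([{"consequence": "exonic_synonymous", "cadd_phred": 35.0}])
        assert len(stage_synonymous_cadd(table)) == 0

    def test_cadd_boundary_is_strict_less_than(self):
        table = toy_table([{"cadd_phred": 19.9}, {"cadd_phred": 20.0, "pos": 101}])
        out = stage_synonymous_cadd(table)
        assert out["cadd_phred"].tolist() == [20.0]

    def test_alternative_reading_keeps_low_cadd_nonsynonymous(self):
        table = toy_table([
            {"cadd_phred": 5.0},
            {"consequence": "exonic_synonymous", "cadd_phred": 5.0, "pos": 101},
            {"consequence": "exonic_synonymous", "cadd_phred": 30.0, "pos": 102},
        ])
        out = stage_synonymous_cadd(table, FilterConfig(synonymous_cadd_only=True))
        assert len(out) == 2  # only the low-score synonymous row removed

    def test_proband_like_nonsynonymous_row_kept(self):
        # score 22.8, non-synonymous: survives the deleteriousness stage
        table = toy_table([{"cadd_phred": 22.8}])
        assert len(stage_synonymous_cadd(table)) == 1

    def test_maf_boundary_and_novel_handling(self):
        table = toy_table([
            {"pop_maf": 0.001},            # exactly at threshold: kept
            {"pop_maf": 0.0004, "pos": 101},  # rare: kept
            {"pop_maf": 0.05, "pos": 102},    # common: removed
            {"pop_maf": np.nan, "pos": 103},  # no record: novel, kept
        ])
        out = stage_maf(table)
        assert out["pos"].tolist() == [100, 101, 103]

    def test_negative_maf_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            stage_maf(toy_table([{"pop_maf": -0.1}]))

    def test_parent_shared_semantics(self):
        table = toy_table([
            {"gt_mother": "0/1", "gt_father": "0/0"},             # kept: proband config
            {"gt_mother": "0/1", "gt_father": "0/1", "pos": 101},  # removed: shared
            {"gt_mother": "1/1", "gt_father": "0/1", "pos": 102},  # removed: shared
            {"gt_mother": "./.", "gt_father": "0/1", "pos": 103},  # retained + flagged
        ])
        out = stage_parent_shared(table)
        assert out["pos"].tolist() == [100, 103]
        assert out["parent_gt_missing"].tolist() == [False, True]


class TestFunnel:
    def test_empty_table(self):
        _, report = run_funnel(toy_table([]))
        assert report.n_input == 0 and report.n_candidates == 0
        assert all(s.n_removed == 0 for s in report.stages)

    def test_composition_equals_manual_stages(self):
        rng = np.random.default_rng(7)
        rows = [
            dict(
                pos=int(p),
                consequence=str(rng.choice(CONSEQUENCE_CLASSES)),
                cadd_phred=float(rng.uniform(0, 40)),
                pop_maf=float(rng.choice([0.0, 0.0005, 0.02, 0.3])),
                gt_mother=str(rng.choice(["0/0", "0/1", "1/1"])),
                gt_father=str(rng.choice(["0/0", "0/1", "1/1"])),
            )
            for p in range(200)
        ]
        table = toy_table(rows)
        candidates, report = run_funnel(table)
        manual = stage_parent_shared(
            stage_maf(stage_synonymous_cadd(stage_exonic_splice(table)))
        )
        assert candidates["pos"].tolist() == manual["pos"].tolist()
        assert report.n_candidates == len(manual)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(random_tables())
    def test_nesting_conservation_and_order_invariance(self, table):
        candidates, report = run_funnel(table)
        # conservation and chaining at every stage
        for s in report.stages:
            assert s.n_in == s.n_removed + s.n_out
        # nesting: monotone non-increasing survivor counts
        outs = [s.n_out for s in report.stages]
        assert all(a >= b for a, b in zip(outs, outs[1:]))
        # the final set equals the conjunction of per-row predicates, hence
        # is invariant to stage order
        assert sorted(candidates["pos"]) == sorted(table.loc[passes_funnel(table), "pos"])

    def test_fixture_funnel_yields_four_candidates(self, annotation_table):
        candidates, report = run_funnel(annotation_table)
        assert report.n_input == 90_000
        assert report.n_candidates == 4
        assert len(report.candidates_by_gene) == 4
        assert set(candidates["gene"]) == {"RAPGEF2", "ENPP1", "SRCIN1", "MRPH8"}


class TestGeneCutoffs:
    def test_enpp1_score_exceeds_gene_cutoff(self):
        exceeds, margin, fallback = exceeds_gene_cutoff(
            {"gene": "ENPP1", "cadd_phred": 22.8}, GeneCutoffMap()
        )
        assert exceeds and not fallback
        assert margin == pytest.approx(22.8 - 13.13)

    def test_equal_score_fails_strict_comparison(self):
        exceeds, margin, _ = exceeds_gene_cutoff(
            {"gene": "ENPP1", "cadd_phred": 13.13}, GeneCutoffMap()
        )
        assert not exceeds and margin == pytest.approx(0.0)

    def test_unknown_gene_uses_flagged_fallback(self):
        exceeds, _, fallback = exceeds_gene_cutoff(
            {"gene": "NOPE", "cadd_phred": 21.0}, GeneCutoffMap()
        )
        assert exceeds and fallback


class TestAnnotationFixture:
    def test_size_and_ground_truth(self, annotation_table):
        assert len(annotation_table) == 90_000
        assert int(annotation_table["engineered"].sum()) == 4
        survivors = annotation_table.loc[passes_funnel(annotation_table)]
        assert survivors["engineered"].all() and len(survivors) == 4

    def test_deterministic_under_seed(self):
        cfg = AnnotationSimConfig(n_variants=2000, seed=9)
        pd.testing.assert_frame_equal(
            simulate_annotated_variants(cfg), simulate_annotated_variants(cfg)
        )

    def test_empty_config(self):
        cfg = AnnotationSimConfig(n_variants=0, engineered_survivors=[])
        assert len(simulate_annotated_variants(cfg)) == 0

    def test_invalid_survivor_rejected(self):
        bad = EngineeredVariant("1", 10, "A", "G", "X", "intronic", 30.0, 0.0,
                                "0/1", "0/1", "0/0")
        with pytest.raises(ValueError, match="fail a funnel stage"):
            simulate_annotated_variants(
                AnnotationSimConfig(n_variants=10, engineered_survivors=[bad])
            )

    def test_table_round_trip(self, tmp_path, annotation_table):
        path = tmp_path / "variants.tsv"
        small = annotation_table.head(200)
        write_annotation_table(small, path)
        back = read_annotation_table(path)
        assert len(back) == 200
        assert back["gene"].tolist() == small["gene"].tolist()
        assert np.allclose(back["pop_maf"], small["pop_maf"])
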