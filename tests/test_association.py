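"""Association engine: counts, allele frequencies, HWE, genetic models,
odds ratios, likelihood-ratio tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncsnp import datasets
from lncsnp.association import (
    DegenerateTableError,
    GenotypeCounts,
    allele_frequency,
    build_model_table,
    count_genotypes,
    hwe_test,
    lr_test,
    odds_ratio,
    run_models,
    run_models_from_counts,
    two_by_two,
)
from lncsnp.io_formats import SnpDef, round_half_up
from lncsnp.synthetic import dataset_from_counts

SNP = SnpDef("rs_t", "chr1", 100, "C", "T")


def make_counts(c1, c2, groups=("case", "control"), snp=SNP):
    return GenotypeCounts.from_tuples(snp, groups[0], c1, groups[1], c2)


cells = st.integers(min_value=1, max_value=500)
count_triples = st.tuples(cells, cells, cells)


class TestCountGenotypes:
    def test_counts_from_dataset_match_construction(self):
        ds = dataset_from_counts(
            SNP, [("case", {}, (10, 20, 5)), ("control", {}, (30, 15, 2))]
        )
        counts = count_genotypes(ds, "rs_t", ("case", "control"))
        assert counts.counts["case"] == (10, 20, 5)
        assert counts.counts["control"] == (30, 15, 2)
        assert counts.minor == "T"

    def test_minor_allele_flips_with_pooled_frequency(self):
        # declared minor T is actually the common allele here
        ds = dataset_from_counts(SNP, [("case", {}, (1, 2, 20)), ("control", {}, (0, 3, 20))])
        counts = count_genotypes(ds, "rs_t", ("case", "control"))
        assert counts.minor == "C"
        assert counts.counts["case"] == (20, 2, 1)  # reordered to (hom-major, het, hom-minor)

    def test_all_missing_group_is_error(self):
        ds = dataset_from_counts(SNP, [("case", {}, (5, 5, 5)), ("control", {}, (0, 0, 0))])
        ds.genotypes["rs_t"] = [
            None if s.group == "control" else g
            for s, g in zip(ds.samples, ds.genotypes["rs_t"])
        ]
        with pytest.raises(DegenerateTableError, match="control"):
            count_genotypes(ds, "rs_t", ("case", "control"))


class TestAlleleFrequency:
    def test_equal_homozygotes(self):
        counts = make_counts((25, 50, 25), (25, 50, 25))
        assert allele_frequency(counts)["pooled"] == 0.5

    @pytest.mark.parametrize("snp_id", list(datasets.ALT_ALLELE_FREQS))
    def test_pooled_frequencies_round_to_published(self, snp_id, published_counts):
        """Pooled alt-allele frequencies reproduce the published cohort column."""
        info = datasets.ALT_ALLELE_FREQS[snp_id]
        freq = allele_frequency(
            published_counts[snp_id], allele=info["allele"], pooling="combined"
        )["pooled"]
        assert round_half_up(freq) == info["cohort"]

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError):
            allele_frequency(make_counts((1, 1, 1), (1, 1, 1)), allele="G")


class TestHwe:
    def test_exact_hwe_gives_zero_chi2(self):
        res = hwe_test(make_counts((25, 50, 25), (1, 1, 1)), "case")
        assert res.chi2 == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_all_heterozygotes(self):
        # expected (25, 50, 25) for n=100 at p=0.5 -> chi2 = 100
        res = hwe_test(make_counts((0, 100, 0), (1, 1, 1)), "case")
        assert res.chi2 == pytest.approx(100.0)

    def test_expected_counts_sum_to_total(self):
        res = hwe_test(make_counts((30, 40, 10), (1, 1, 1)), "case")
        assert sum(res.expected) == pytest.approx(80.0)

    def test_monomorphic_flagged_degenerate(self):
        res = hwe_test(make_counts((50, 0, 0), (1, 1, 1)), "case")
        assert res.degenerate and res.chi2 == 0.0

    @given(count_triples)
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_allele_relabeling(self, triple):
        a = hwe_test(make_counts(triple, (1, 1, 1)), "case")
        b = hwe_test(make_counts(triple[::-1], (1, 1, 1)), "case")
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-9)


class TestModelTables:
    def test_dominant_collapse(self, published_counts):
        table = build_model_table(published_counts["rs4415084"], "dominant")
        assert table.reference.cells == (104, 100)
        assert table.exposures[0].label == "CT/TT"
        assert table.exposures[0].cells == (181, 257)

    def test_recessive_collapse(self, published_counts):
        table = build_model_table(published_counts["rs7716600"], "recessive")
        assert table.reference.label == "CC/AC"
        assert table.reference.cells == (247, 314)
        assert table.exposures[0].cells == (7, 24)

    @given(count_triples, count_triples)
    @settings(max_examples=50, deadline=None)
    def test_cell_conservation(self, c1, c2):
        counts = make_counts(c1, c2)
        for model in ("codominant", "dominant", "recessive", "overdominant"):
            table = build_model_table(counts, model)
            assert table.cell_matrix().sum() == sum(c1) + sum(c2)


class TestOddsRatio:
    def test_null_table_is_symmetric_about_one(self):
        (res,) = odds_ratio(two_by_two(("a", "b"), "ref", (50, 50), "exp", (50, 50)))
        assert res.or_value == pytest.approx(1.0)
        assert res.ci_lo * res.ci_hi == pytest.approx(1.0)

    @given(cells, cells, cells, cells)
    @settings(max_examples=100, deadline=None)
    def test_orientation_reciprocity(self, a1, a2, b1, b2):
        table = two_by_two(("g1", "g2"), "ref", (a1, a2), "exp", (b1, b2))
        (paper,) = odds_ratio(table, "paper")
        (std,) = odds_ratio(table, "standard")
        assert paper.or_value * std.or_value == pytest.approx(1.0)

    @given(cells, cells, cells, cells)
    @settings(max_examples=100, deadline=None)
    def test_wald_ci_contains_point_estimate(self, a1, a2, b1, b2):
        table = two_by_two(("g1", "g2"), "ref", (a1, a2), "exp", (b1, b2))
        (res,) = odds_ratio(table)
        assert res.ci_lo <= res.or_value <= res.ci_hi

    def test_ci_width_shrinks_as_cells_scale(self):
        widths = []
        for k in (1, 10, 100):
            table = two_by_two(("a", "b"), "r", (10 * k, 20 * k), "e", (15 * k, 12 * k))
            (res,) = odds_ratio(table)
            widths.append(math.log(res.ci_hi) - math.log(res.ci_lo))
        assert widths[0] > widths[1] > widths[2]

    def test_haldane_correction_on_single_zero_cell(self):
        (res,) = odds_ratio(two_by_two(("a", "b"), "r", (10, 0), "e", (5, 8)))
        assert res.haldane
        assert math.isfinite(res.or_value) and res.or_value > 0

    def test_double_zero_margin_is_error(self):
        with pytest.raises(DegenerateTableError):
            odds_ratio(two_by_two(("a", "b"), "r", (0, 0), "e", (5, 8)))


class TestLrTest:
    def test_perfect_independence(self):
        res = lr_test(two_by_two(("a", "b"), "r", (10, 20), "e", (30, 60)))
        assert res.g_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_contributes_zero_and_flags(self):
        res = lr_test(two_by_two(("a", "b"), "r", (10, 0), "e", (5, 8)))
        assert res.zero_cells and math.isfinite(res.g_stat)

    def test_g_and_pearson_converge_under_root_n_alternatives(self):
        # with deviations of order sqrt(n) around independence both
        # statistics tend to the same noncentral limit, so their gap -> 0
        gaps = []
        for k in (1, 100, 10_000):
            d = round(5 * math.sqrt(k))
            res = lr_test(
                two_by_two(
                    ("a", "b"),
                    "r", (10 * k + d, 20 * k - d),
                    "e", (30 * k - d, 60 * k + d),
                )
            )
            gaps.append(abs(res.g_stat - res.pearson_chi2))
        assert gaps[-1] < gaps[0] and gaps[-1] < 1e-2


class TestRunModels:
    def test_published_null_snp_panel(self, published_counts):
        """rs3803662: no model significant, codominant ORs as published."""
        rep = run_models_from_counts(published_counts["rs3803662"])
        codom = rep.blocks["codominant"].results
        assert round_half_up(codom[0].or_value) == 0.91  # AG
        assert round_half_up(codom[1].or_value) == 1.18  # AA
        assert all(blk.lr.p_value > 0.05 for blk in rep.blocks.values())

    def test_group_swap_inverts_every_or(self, published_counts):
        rep = run_models_from_counts(published_counts["rs4415084"])
        swapped = run_models_from_counts(published_counts["rs4415084"].swapped())
        for model in rep.blocks:
            for r1, r2 in zip(rep.blocks[model].results, swapped.blocks[model].results):
                assert r1.or_value * r2.or_value == pytest.approx(1.0)

    def test_from_dataset_equals_from_counts(self, published_counts):
        counts = published_counts["rs4784227"]
        ds = dataset_from_counts(
            counts.snp,
            [("case", {}, counts.counts["case"]), ("control", {}, counts.counts["control"])],
        )
        rep_ds = run_models(ds, "rs4784227", ("case", "control"))
        rep_ct = run_models_from_counts(counts)
        for model in rep_ds.blocks:
            assert rep_ds.blocks[model].results == rep_ct.blocks[model].results

    def test_parameter_recovery_on_synthetic_cohort(self):
        """Estimated dominant OR converges to the analytic OR of the
        generating per-group genotype probabilities (2-SE tolerance, n=1e5)."""
        from lncsnp.synthetic import CohortSpec, SnpCohortSpec, gen_cohort

        case_p = np.array([104, 132, 49]) / 285
        ctrl_p = np.array([100, 182, 75]) / 357
        spec = CohortSpec(
            n_per_group={"case": 100_000, "control": 100_000},
            snp_specs=[
                SnpCohortSpec(
                    snp=datasets.SNP_DEFS["rs4415084"],
                    genotype_probs={"case": tuple(case_p), "control": tuple(ctrl_p)},
                )
            ],
            seed=7,
        )
        rep = run_models(gen_cohort(spec), "rs4415084", ("case", "control"))
        (res,) = rep.blocks["dominant"].results
        analytic = (ctrl_p[1:].sum() * case_p[0]) / (case_p[1:].sum() * ctrl_p[0])
        table = rep.blocks["dominant"].table.cell_matrix()
        se = math.sqrt((1.0 / table).sum())
        assert abs(math.log(res.or_value) - math.log(analytic)) < 2 * se
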