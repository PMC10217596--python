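"""Candidate screen: DE computation, the three filters, top-OR selection."""

import logging
import math

import numpy as np
import pytest

from lncsnp import datasets
from lncsnp.candidates import (
    CandidateRecord,
    DeResult,
    SelectionConfig,
    build_candidates,
    compute_de,
    compute_subtype_flags,
    de_test,
    filter_de,
    filter_maf,
    filter_subtype_de,
    intersect_snps_lncrnas,
    rank_select,
    run_selection,
)
from lncsnp.io_formats import GwasRecord, Interval
from lncsnp.synthetic import ExpressionSpec, gen_expression


def gwas(snp_id, chrom="chr1", pos=150, orv=1.2, maf=0.3):
    return GwasRecord(snp_id, chrom, pos, "breast carcinoma", orv, maf)


def candidate(gene="G1", snp_id="rs1", orv=1.2, maf=0.3, flags=None, log2fc=2.0, p=1e-9):
    iv = Interval("chr1", 100, 200, name=gene)
    de = DeResult(gene, log2fc, p, flags or {})
    return CandidateRecord(de, gwas(snp_id, orv=orv, maf=maf), iv)


class TestComputeDe:
    def _table(self, planted, noise=0.3, n=100, seed=8):
        spec = ExpressionSpec(
            n_genes=4, group_sizes={"tumor": n, "normal": n},
            planted_log2fc=planted, noise_sd=noise, seed=seed,
        )
        return gen_expression(spec)

    def test_identical_values_tie_convention(self):
        import pandas as pd

        values = pd.DataFrame(
            {f"s{i}": [7.0] for i in range(6)}, index=["G"]
        )
        groups = pd.Series({f"s{i}": "tumor" if i < 3 else "normal" for i in range(6)})
        (res,) = compute_de(values, groups, "tumor", "normal")
        assert res.log2fc == 0.0 and res.p_value == 1.0

    def test_planted_fold_change_recovered(self):
        table = self._table({"LNC_PLANT": {"tumor": 3.92}})
        results = {r.gene: r for r in compute_de(table.values, table.groups, "tumor", "normal")}
        se = 0.3 * math.sqrt(2 / 100)
        assert abs(results["LNC_PLANT"].log2fc - 3.92) < 2 * se + 0.05
        assert results["LNC_PLANT"].p_value < 1e-3

    def test_swapping_groups_negates_log2fc(self):
        table = self._table({"LNC_PLANT": {"tumor": 1.0}})
        fwd = compute_de(table.values, table.groups, "tumor", "normal")
        rev = compute_de(table.values, table.groups, "normal", "tumor")
        for a, b in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b.log2fc)
            assert a.p_value == pytest.approx(b.p_value)

    def test_small_group_is_error(self):
        import pandas as pd

        values = pd.DataFrame({"s0": [1.0], "s1": [2.0], "s2": [2.0]}, index=["G"])
        groups = pd.Series({"s0": "tumor", "s1": "normal", "s2": "normal"})
        with pytest.raises(ValueError):
            compute_de(values, groups, "tumor", "normal")

    def test_zero_variance_unequal_means(self):
        lfc, p = de_test(np.full(5, 3.0), np.full(5, 1.0))
        assert p == 0.0 and lfc == pytest.approx(1.0)

    def test_subtype_flags_direction(self):
        spec = ExpressionSpec(
            n_genes=2,
            group_sizes={"luminal A": 40, "luminal B": 40, "HER2-enriched": 40,
                         "basal-like": 40},
            planted_log2fc={"LNC_UP": {"luminal A": 2.5}},
            noise_sd=0.3, seed=2,
        )
        table = gen_expression(spec)
        de = [DeResult("LNC_UP", 2.0, 1e-9), DeResult("GENE0001", 2.0, 1e-9)]
        flagged = compute_subtype_flags(table.values, table.groups, de)
        assert flagged[0].subtype_flags["luminal A"] == "up"
        assert flagged[1].subtype_flags == {s: "ns" for s in flagged[1].subtype_flags}


class TestFilterDe:
    @pytest.mark.parametrize(
        "log2fc,p,kept",
        [
            (0.87, 9.37e-10, True),   # linear FC 1.83 > 1.5
            (0.50, 1e-10, False),     # linear FC 1.41 < 1.5
            (-1.93, 2.53e-47, True),  # down-regulation passes the absolute filter
            (2.00, 5e-3, False),      # p above threshold
        ],
    )
    def test_linear_fold_change_and_p_cut(self, log2fc, p, kept):
        results = [DeResult("G", log2fc, p)]
        assert bool(filter_de(results)) is kept


class TestIntersect:
    IV = Interval("chr1", 100, 200, name="LNC1")

    def test_half_open_boundaries(self):
        assert intersect_snps_lncrnas([gwas("rs1", pos=100)], [self.IV])
        assert not intersect_snps_lncrnas([gwas("rs2", pos=200)], [self.IV])

    def test_overlapping_intervals_yield_two_pairs(self):
        ivs = [self.IV, Interval("chr1", 150, 250, name="LNC2")]
        pairs = intersect_snps_lncrnas([gwas("rs1", pos=160)], ivs)
        assert {iv.name for _, iv in pairs} == {"LNC1", "LNC2"}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        ivs = [
            Interval("chr1", int(s), int(s) + 50, name=f"L{i}")
            for i, s in enumerate(rng.integers(0, 1000, size=6))
        ]
        recs = [gwas(f"rs{i}", pos=int(p)) for i, p in enumerate(rng.integers(0, 1100, size=10))]
        expected = {
            (r.snp_id, iv.name)
            for r in recs
            for iv in ivs
            if iv.chrom == r.chrom and iv.start <= r.pos < iv.end
        }
        got = {(r.snp_id, iv.name) for r, iv in intersect_snps_lncrnas(recs, ivs)}
        assert got == expected

    def test_build_mismatch(self):
        from lncsnp.io_formats import BuildMismatchError

        rec = GwasRecord("rs1", "chr1", 150, "t", 1.2, 0.3, build="GRCh38")
        iv = Interval("chr1", 100, 200, name="L", build="GRCh37")
        with pytest.raises(BuildMismatchError):
            intersect_snps_lncrnas([rec], [iv])


class TestFilterMaf:
    @pytest.mark.parametrize("maf,kept", [(0.27, True), (0.46, True), (0.20, False), (0.15, False)])
    def test_strict_threshold(self, maf, kept):
        pairs = [(gwas("rs1", maf=maf), Interval("chr1", 100, 200, name="L"))]
        assert bool(filter_maf(pairs)) is kept


class TestSubtypeFilter:
    def test_keeps_any_non_ns_flag(self):
        kept = candidate(flags={"ER+": "down", "HER2+": "up"})
        dropped = candidate(gene="G2", snp_id="rs2", flags={"ER+": "ns"})
        out = filter_subtype_de([kept, dropped])
        assert [c.de.gene for c in out] == ["G1"]
        assert "subtype_de" in out[0].passed_filters


class TestFilterAlgebra:
    def test_idempotent_and_order_commutative(self):
        cands = [
            candidate(gene=f"G{i}", snp_id=f"rs{i}", maf=m, flags=f)
            for i, (m, f) in enumerate(
                [(0.3, {"ER+": "up"}), (0.1, {"ER+": "up"}), (0.3, {})]
            )
        ]
        config = SelectionConfig()

        def maf_then_subtype(cs):
            pairs = filter_maf([(c.snp, c.interval) for c in cs], config)
            keep = {r.snp_id for r, _ in pairs}
            return filter_subtype_de([c for c in cs if c.snp.snp_id in keep])

        def subtype_then_maf(cs):
            kept = filter_subtype_de(cs)
            pairs = filter_maf([(c.snp, c.interval) for c in kept], config)
            keep = {r.snp_id for r, _ in pairs}
            return [c for c in kept if c.snp.snp_id in keep]

        a = {c.de.gene for c in maf_then_subtype(cands)}
        b = {c.de.gene for c in subtype_then_maf(cands)}
        assert a == b == {"G0"}
        once = filter_subtype_de(cands)
        assert [c.de.gene for c in filter_subtype_de(once)] == [c.de.gene for c in once]


class TestRankSelect:
    def test_row_with_two_snps_counts_both(self):
        cands = [
            candidate(snp_id="rs7716600", orv=1.24),
            candidate(gene="G2", snp_id="rs4784227/rs3803662", orv=1.23),
            candidate(gene="G3", snp_id="rs4415084", orv=1.17),
            candidate(gene="G4", snp_id="rs2594714", orv=1.04),
        ]
        assert rank_select(cands) == [
            "rs7716600", "rs4784227", "rs3803662", "rs4415084"
        ]

    def test_tie_broken_by_rsid(self):
        cands = [
            candidate(gene="G1", snp_id="rs9", orv=1.2),
            candidate(gene="G2", snp_id="rs1", orv=1.2),
        ]
        assert rank_select(cands, SelectionConfig(n_select=1)) == ["rs1"]

    def test_too_few_candidates_warns_and_returns_all(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = rank_select([candidate()], SelectionConfig(n_select=4))
        assert out == ["rs1"]
        assert any("4 requested" in r.message for r in caplog.records)


class TestFullScreen:
    def test_published_cardinality_and_selection(self):
        """23 candidates -> 14 with a subtype flag -> the 4 published SNPs."""
        de, gwas_recs, intervals = datasets.candidate_screen_inputs()
        survivors, selected = run_selection(de, gwas_recs, intervals)
        assert len(survivors) == 14
        assert set(selected) == datasets.SELECTED_SNPS
        for c in survivors:
            assert set(c.passed_filters) == {"de", "intersect", "maf", "subtype_de"}

    def test_join_respects_host_gene(self):
        de = [DeResult("LNC1", 2.0, 1e-9, {"ER+": "up"})]
        pairs = [(gwas("rs1"), Interval("chr1", 100, 200, name="OTHER"))]
        assert build_candidates(de, pairs) == []
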