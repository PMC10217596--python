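"""Published summary data of the Brazilian breast-cancer lncRNA-SNP study
this package reanalyzes.

A case-control study genotyped four lncRNA SNPs (rs3803662, rs4415084,
rs4784227, rs7716600) in 291 sporadic breast-cancer patients and 370
cancer-free women from southern Brazil, after a three-stage candidate
screen over TCGA differential expression and GWAS-catalog associations.
The study released only summary tables — per-SNP genotype counts, clinical
stratifications, haplotype frequencies and the candidate screen — which are
embedded here (statsmodels-datasets style) so that every association
statistic can be recomputed from them without external downloads.

Genomic positions on the :class:`~lncsnp.io_formats.SnpDef` objects are
synthetic placeholders consistent with the fixture intervals of
:func:`candidate_screen_inputs`; they are not genome coordinates.
"""

from __future__ import annotations

from .association import GenotypeCounts
from .candidates import DeResult
from .io_formats import GwasRecord, Interval, SnpDef

ENROLLED = {"case": 291, "control": 370}

#: Mean (sd) age at diagnosis used for the age dichotomization.
MEAN_AGE_AT_DIAGNOSIS = 57.90
SD_AGE_AT_DIAGNOSIS = 14.51

# the four genotyped SNPs; positions are fixture placeholders (see module
# docstring), placed inside their host-gene intervals below
SNP_DEFS = {
    "rs3803662": SnpDef("rs3803662", "chr16", 52_580_000, "G", "A", host_gene="CASC16"),
    "rs4784227": SnpDef("rs4784227", "chr16", 52_550_000, "C", "T", host_gene="CASC16"),
    "rs4415084": SnpDef("rs4415084", "chr5", 44_650_000, "C", "T", host_gene="LINC02224"),
    "rs7716600": SnpDef("rs7716600", "chr5", 44_800_000, "C", "A", host_gene="AC093297.2"),
}

#: Case-control genotype counts, (hom-major, het, hom-minor) per group,
#: complete-case (per-SNP n varies against the 291/370 enrolled).
CASE_CONTROL_COUNTS = {
    "rs3803662": {"case": (125, 121, 27), "control": (172, 151, 44)},
    "rs4415084": {"case": (104, 132, 49), "control": (100, 182, 75)},
    "rs4784227": {"case": (153, 94, 23), "control": (199, 130, 26)},
    "rs7716600": {"case": (153, 94, 7), "control": (196, 118, 24)},
}

#: Case-only clinical stratifications with published genotype counts:
#: (snp_id, negative-stratum counts, positive-stratum counts).
PR_STATUS_COUNTS = {  # rs4415084, PR-negative n=62 vs PR-positive n=166
    "rs4415084": {"negative": (19, 36, 7), "positive": (56, 72, 38)},
}
LYMPH_NODE_COUNTS = {  # rs7716600, node-negative n=125 vs node-positive n=90
    "rs7716600": {"negative": (68, 53, 4), "positive": (61, 27, 2)},
}

#: Published cohort alt-allele frequencies alongside 1000 Genomes estimates.
#: Note the "alt" allele is the major allele for rs7716600 and rs3803662.
ALT_ALLELE_FREQS = {
    "rs7716600": {"allele": "C", "cohort": 0.77, "eur": 0.79, "afr": 0.83},
    "rs4784227": {"allele": "T", "cohort": 0.26, "eur": 0.25, "afr": 0.04},
    "rs3803662": {"allele": "G", "cohort": 0.68, "eur": 0.70, "afr": 0.43},
    "rs4415084": {"allele": "T", "cohort": 0.44, "eur": 0.40, "afr": 0.65},
}

#: Published rs3803662/rs4784227 haplotype panel: pooled frequency and the
#: reported OR/CI/p per haplotype (reference GC).  Order of the frequency
#: vector is (A1B1, A1B2, A2B1, A2B2) = (GC, GT, AC, AT) with
#: A = rs3803662 (major G), B = rs4784227 (major C).
HAPLOTYPE_FREQS = (0.67, 0.0081, 0.0735, 0.25)
HAPLOTYPE_PANEL = {
    ("G", "C"): {"freq": 0.67, "or": None, "p": None},
    ("A", "T"): {"freq": 0.25, "or": 1.03, "ci": (0.80, 1.33), "p": 0.81},
    ("A", "C"): {"freq": 0.0735, "or": 0.99, "ci": (0.64, 1.52), "p": 0.96},
    ("G", "T"): {"freq": 0.0081, "or": 0.20, "ci": (0.04, 0.99), "p": 0.049},
}

#: CEU linkage disequilibrium reported for rs3803662/rs4784227.
CEU_LD = {"d_prime": 0.97, "r2": 0.91}


def reference_cohort_spec(seed: int = 0):
    """Cohort-generator spec mirroring the study's conditions.

    291 cases / 370 controls enrolled; per-SNP genotype probabilities equal
    to the published count fractions; per-SNP missing rates equal to
    1 - analyzed n / enrolled n, reproducing the varying complete-case
    sample sizes of the published tables in expectation.
    """
    from .synthetic import CohortSpec, SnpCohortSpec

    snp_specs = []
    for snp_id, per_group in CASE_CONTROL_COUNTS.items():
        probs = {}
        missing = {}
        for group, c in per_group.items():
            n = sum(c)
            probs[group] = tuple(x / n for x in c)
            missing[group] = 1 - n / ENROLLED[group]
        snp_specs.append(
            SnpCohortSpec(
                snp=SNP_DEFS[snp_id], genotype_probs=probs, missing_rate=missing
            )
        )
    return CohortSpec(n_per_group=dict(ENROLLED), snp_specs=snp_specs, seed=seed)


def counts(snp_id: str) -> GenotypeCounts:
    """Published case-control genotype counts as a :class:`GenotypeCounts`."""
    c = CASE_CONTROL_COUNTS[snp_id]
    return GenotypeCounts.from_tuples(
        SNP_DEFS[snp_id], "case", c["case"], "control", c["control"]
    )


def stratified_counts(snp_id: str, stratification: str) -> GenotypeCounts:
    """Published case-only stratified counts, columns (negative, positive)."""
    table = {"pr_status": PR_STATUS_COUNTS, "lymph_node": LYMPH_NODE_COUNTS}[
        stratification
    ][snp_id]
    return GenotypeCounts.from_tuples(
        SNP_DEFS[snp_id], "negative", table["negative"], "positive", table["positive"]
    )


# ---------------------------------------------------------------------------
# candidate screen
# ---------------------------------------------------------------------------

# The 14 candidates surviving the published three-stage screen:
# (lncRNA, log2FC tumor-vs-normal, DE p, subtype flags, SNP id(s),
#  GWAS OR, GWAS MAF).  Flags use {"up", "down"} per subtype; absent = ns.
CANDIDATE_ROWS = [
    ("AC020916.1", 1.99, 1.27e-147, {"ER+": "down"}, "rs2594714", 1.04, 0.42),
    ("AC093297.2", 1.86, 2.70e-15, {"ER+": "down", "HER2+": "up"}, "rs7716600", 1.24, 0.27),
    ("AL358075.2", 1.45, 3.39e-11, {"HER2+": "down"}, "rs1707302", 1.04, 0.37),
    ("AQP4-AS1", 0.87, 9.37e-10, {"ER+": "up"}, "rs527616", 1.03, 0.23),
    ("CASC16", 1.92, 9.57e-15, {"ER+": "up"}, "rs4784227/rs3803662", 1.23, 0.25),
    ("CRYZL2P-SEC16B-201", -0.80, 1.90e-12, {"HER2+": "up"}, "rs575908", 1.03, 0.35),
    ("LINC-PINT", -0.69, 1.14e-6, {"HER2-": "up"}, "rs68056147", 1.05, 0.24),
    ("LINC02224", 3.92, 3.14e-100, {"ER+": "down", "HER2+": "up"}, "rs4415084", 1.17, 0.46),
    ("LINC01977", 1.48, 5.16e-19, {"ER+": "down"}, "rs745570", 1.03, 0.38),
    ("LINC00511", 1.72, 2.70e-14, {"ER+": "up"}, "rs11652463", 1.04, 0.43),
    ("LINC00536", 1.05, 1.43e-5, {"ER+": "up"}, "rs13267382", 1.03, 0.34),
    ("LINC00578", 1.91, 2.70e-16, {"ER+": "down", "HER2+": "down"}, "rs7430456", 1.02, 0.44),
    ("MEG3", -1.93, 2.53e-47, {"ER+": "up"}, "rs2295389", 1.03, 0.27),
    ("MIR4435-2HG", 0.88, 6.77e-10, {"HER2+": "down"}, "rs200484318", 1.04, 0.36),
]

#: SNPs the published study took forward (the four highest GWAS ORs).
SELECTED_SNPS = {"rs7716600", "rs4784227", "rs3803662", "rs4415084"}


def candidate_screen_inputs(
    n_extra_no_subtype: int = 9,
) -> tuple[list[DeResult], list[GwasRecord], list[Interval]]:
    """Inputs reproducing the published screen's 23 -> 14 -> 4 cardinality.

    Returns differential-expression results, GWAS records and lncRNA
    intervals for the 14 published candidates plus ``n_extra_no_subtype``
    synthetic candidates that pass every filter except the subtype-DE one
    (all flags ns), mirroring the 23 candidates the study narrowed to 14.
    SNPs are placed inside their host intervals on a synthetic coordinate
    grid; two published SNPs share one row/interval (CASC16).
    """
    de_results: list[DeResult] = []
    gwas: list[GwasRecord] = []
    intervals: list[Interval] = []
    rows = list(CANDIDATE_ROWS) + [
        (f"LNC-NS{i:02d}", 2.0, 1e-8, {}, f"rs99{i:04d}", 1.01, 0.30)
        for i in range(n_extra_no_subtype)
    ]
    for k, (gene, log2fc, p, flags, snp_field, orv, maf) in enumerate(rows):
        chrom = f"chr{(k % 9) + 1}"
        start = 1_000_000 * (k + 1)
        intervals.append(Interval(chrom, start, start + 50_000, name=gene))
        de_results.append(
            DeResult(gene=gene, log2fc=log2fc, p_value=p, subtype_flags=dict(flags))
        )
        gwas.append(
            GwasRecord(
                snp_id=snp_field,
                chrom=chrom,
                pos=start + 10_000,
                trait="breast carcinoma",
                reported_or=orv,
                maf=maf,
            )
        )
    return de_results, gwas, intervals
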