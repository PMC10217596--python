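"""Case-control association statistics for single SNPs.

The analysis unit is a per-group genotype count triple (hom-major, het,
hom-minor).  From it the engine derives allele frequencies, the
Hardy–Weinberg chi-square, the four classical genetic-model contingency
tables (codominant, dominant, recessive, overdominant), odds ratios with
Wald 95% confidence intervals, and likelihood-ratio (G) association tests
with the Pearson chi-square co-reported.

Odds-ratio orientation
----------------------
Two conventions are supported.  With 2x2 cells ``n1(ref), n2(ref)`` and
``n1(exp), n2(exp)`` for column groups 1 and 2:

* ``"standard"`` — the epidemiological convention with group 1 (cases) as
  outcome: OR = [n1(exp) * n2(ref)] / [n2(exp) * n1(ref)].
* ``"paper"`` — the reciprocal, treating the column-2 group as outcome:
  OR = [n2(exp) * n1(ref)] / [n1(exp) * n2(ref)].  This is the convention
  under which the published Brazilian-cohort tables this package reproduces
  were computed, so it is the default.

The two orientations multiply to 1 on every table.

No continuity correction is applied to the G test; a single zero cell in a
2x2 odds-ratio table triggers the Haldane–Anscombe +0.5 correction (flagged
on the result), and two zero cells in one margin make the OR undefined.
No multiple-testing correction is applied; callers see the number of tests
run in the block result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .io_formats import GenotypeDataset, SnpDef

MODELS = ("codominant", "dominant", "recessive", "overdominant")
ORIENTATIONS = ("paper", "standard")


class DegenerateTableError(ValueError):
    """A contingency table too degenerate for the requested statistic."""


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-group (hom-major, het, hom-minor) counts for one SNP.

    ``groups`` fixes column order: groups[0] is column 1 of every
    downstream table, groups[1] column 2.  ``major``/``minor`` are the
    allele labels the count order refers to.
    """

    snp: SnpDef
    groups: tuple[str, str]
    counts: Mapping[str, tuple[int, int, int]]
    major: str
    minor: str

    def __post_init__(self) -> None:
        for g in self.groups:
            c = self.counts[g]
            if len(c) != 3 or any(x < 0 for x in c):
                raise ValueError(f"invalid counts for group {g}: {c}")

    def total(self, group: str) -> int:
        return sum(self.counts[group])

    def genotype_label(self, klass: str) -> str:
        """Printed label for a genotype class ('hom_major'|'het'|'hom_minor')."""
        if klass == "hom_major":
            return self.major * 2
        if klass == "hom_minor":
            return self.minor * 2
        a, b = sorted((self.major, self.minor))
        return a + b

    def swapped(self) -> "GenotypeCounts":
        """Same counts with column groups exchanged."""
        return GenotypeCounts(
            self.snp, (self.groups[1], self.groups[0]), dict(self.counts),
            self.major, self.minor,
        )

    @classmethod
    def from_tuples(
        cls,
        snp: SnpDef,
        group1: str,
        counts1: tuple[int, int, int],
        group2: str,
        counts2: tuple[int, int, int],
    ) -> "GenotypeCounts":
        """Build directly from printed (hom-major, het, hom-minor) rows."""
        return cls(
            snp, (group1, group2), {group1: counts1, group2: counts2},
            snp.major_allele, snp.minor_allele,
        )


def count_genotypes(
    dataset: GenotypeDataset,
    snp_id: str,
    group_pair: tuple[str, str],
    minor_allele: str | None = None,
) -> GenotypeCounts:
    """Complete-case genotype counts for one SNP over two groups.

    The minor allele is determined from the pooled (both groups) allele
    frequency unless overridden by ``minor_allele``; ties fall back to the
    SnpDef's declared minor allele.
    """
    snp = dataset.snp_def(snp_id)
    calls = {g: dataset.calls(snp_id, g, drop_missing=True) for g in group_pair}
    for g, cc in calls.items():
        if not cc:
            raise DegenerateTableError(
                f"{snp_id}: group {g!r} has zero non-missing samples"
            )
    if minor_allele is None:
        pooled = [a for g in group_pair for call in calls[g] for a in call]
        n_declared_minor = pooled.count(snp.minor_allele)
        if n_declared_minor * 2 == len(pooled):  # exact tie
            minor_allele = snp.minor_allele
        else:
            minor_allele = (
                snp.minor_allele
                if n_declared_minor * 2 < len(pooled)
                else snp.major_allele
            )
    major_allele = next(iter(snp.alleles - {minor_allele}))
    counts = {}
    for g in group_pair:
        hom_major = het = hom_minor = 0
        for call in calls[g]:
            n_minor = call.count(minor_allele)
            if n_minor == 0:
                hom_major += 1
            elif n_minor == 1:
                het += 1
            else:
                hom_minor += 1
        counts[g] = (hom_major, het, hom_minor)
    return GenotypeCounts(snp, tuple(group_pair), counts, major_allele, minor_allele)


# ---------------------------------------------------------------------------
# allele frequency
# ---------------------------------------------------------------------------


def allele_frequency(
    counts: GenotypeCounts, allele: str | None = None, pooling: str = "per-group"
) -> dict[str, float]:
    """Frequency of ``allele`` (default: the minor allele) per group or pooled.

    freq = (2*n_hom_allele + n_het) / (2*n_total).  ``pooling`` is
    ``"per-group"`` (one entry per group plus ``"pooled"``) or ``"combined"``
    (pooled only).
    """
    if allele is None:
        allele = counts.minor
    if allele not in (counts.major, counts.minor):
        raise ValueError(f"allele {allele!r} not in {{" f"{counts.major},{counts.minor}}}")

    def freq(c: tuple[int, int, int]) -> float:
        n = sum(c)
        if n == 0:
            raise DegenerateTableError("zero total in allele_frequency")
        n_allele = 2 * (c[2] if allele == counts.minor else c[0]) + c[1]
        return n_allele / (2 * n)

    pooled_counts = tuple(
        sum(counts.counts[g][i] for g in counts.groups) for i in range(3)
    )
    out = {"pooled": freq(pooled_counts)}
    if pooling == "per-group":
        for g in counts.groups:
            out[g] = freq(counts.counts[g])
    elif pooling != "combined":
        raise ValueError(f"unknown pooling {pooling!r}")
    return out


# ---------------------------------------------------------------------------
# Hardy–Weinberg
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HweResult:
    group: str
    chi2: float
    p_value: float
    expected: tuple[float, float, float]
    df: int = 1
    degenerate: bool = False


def hwe_test(counts: GenotypeCounts, group: str) -> HweResult:
    """Hardy–Weinberg chi-square for one group.

    Expected counts are n*(p^2, 2pq, q^2) with p the group's own major-allele
    frequency; the statistic has 1 df (3 classes, 1 estimated allele
    frequency).  A monomorphic group returns chi2=0 flagged degenerate.
    """
    obs = np.asarray(counts.counts[group], dtype=float)
    n = obs.sum()
    if n == 0:
        raise DegenerateTableError(f"group {group!r} has no samples")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    if p in (0.0, 1.0):
        return HweResult(group, 0.0, 1.0, tuple(expected), degenerate=True)
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return HweResult(group, chi2, float(_chi2_dist.sf(chi2, 1)), tuple(expected))


# ---------------------------------------------------------------------------
# model tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelRow:
    label: str
    cells: tuple[int, int]  # (group1, group2)
    is_reference: bool


@dataclass(frozen=True)
class ModelTable:
    """Contingency table for one genetic model; reference row first."""

    model: str
    groups: tuple[str, str]
    rows: tuple[ModelRow, ...]

    @property
    def reference(self) -> ModelRow:
        return next(r for r in self.rows if r.is_reference)

    @property
    def exposures(self) -> tuple[ModelRow, ...]:
        return tuple(r for r in self.rows if not r.is_reference)

    def cell_matrix(self) -> np.ndarray:
        return np.array([r.cells for r in self.rows], dtype=float)


def build_model_table(counts: GenotypeCounts, model: str) -> ModelTable:
    """Collapse genotype counts into a genetic-model contingency table.

    codominant: three rows, hom-major as reference; dominant: carriers
    (het + hom-minor) vs hom-major; recessive: hom-minor vs the rest;
    overdominant: het vs both homozygotes.  Cell totals are conserved.
    """
    g1, g2 = counts.groups
    c1, c2 = counts.counts[g1], counts.counts[g2]
    lab = counts.genotype_label
    if model == "codominant":
        rows = (
            ModelRow(lab("hom_major"), (c1[0], c2[0]), True),
            ModelRow(lab("het"), (c1[1], c2[1]), False),
            ModelRow(lab("hom_minor"), (c1[2], c2[2]), False),
        )
    elif model == "dominant":
        rows = (
            ModelRow(lab("hom_major"), (c1[0], c2[0]), True),
            ModelRow(
                f"{lab('het')}/{lab('hom_minor')}",
                (c1[1] + c1[2], c2[1] + c2[2]),
                False,
            ),
        )
    elif model == "recessive":
        rows = (
            ModelRow(
                f"{lab('hom_major')}/{lab('het')}",
                (c1[0] + c1[1], c2[0] + c2[1]),
                True,
            ),
            ModelRow(lab("hom_minor"), (c1[2], c2[2]), False),
        )
    elif model == "overdominant":
        rows = (
            ModelRow(
                f"{lab('hom_major')}/{lab('hom_minor')}",
                (c1[0] + c1[2], c2[0] + c2[2]),
                True,
            ),
            ModelRow(lab("het"), (c1[1], c2[1]), False),
        )
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return ModelTable(model, counts.groups, rows)


def two_by_two(
    groups: tuple[str, str],
    ref_label: str,
    ref_cells: tuple[int, int],
    exp_label: str,
    exp_cells: tuple[int, int],
    model: str = "2x2",
) -> ModelTable:
    """Convenience constructor for a bare reference-vs-exposure table."""
    return ModelTable(
        model,
        tuple(groups),
        (ModelRow(ref_label, ref_cells, True), ModelRow(exp_label, exp_cells, False)),
    )


# ---------------------------------------------------------------------------
# odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    model: str
    exposure: str
    or_value: float
    ci_lo: float
    ci_hi: float
    p_value: float | None  # block-level LR p, attached by run_models
    orientation: str
    haldane: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.or_value <= self.ci_hi):
            raise ValueError("CI must bracket the OR point estimate")


def _or_one(
    ref: tuple[int, int], exp: tuple[int, int], orientation: str
) -> tuple[float, float, float, bool]:
    a1, a2 = ref
    b1, b2 = exp
    if (a1 == 0 and a2 == 0) or (b1 == 0 and b2 == 0) or \
       (a1 == 0 and b1 == 0) or (a2 == 0 and b2 == 0):
        raise DegenerateTableError("two zero cells in one margin; OR undefined")
    haldane = 0 in (a1, a2, b1, b2)
    if haldane:
        a1, a2, b1, b2 = a1 + 0.5, a2 + 0.5, b1 + 0.5, b2 + 0.5
    if orientation == "paper":
        orv = (b2 * a1) / (b1 * a2)
    elif orientation == "standard":
        orv = (b1 * a2) / (b2 * a1)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    se = math.sqrt(1 / a1 + 1 / a2 + 1 / b1 + 1 / b2)
    lo = math.exp(math.log(orv) - 1.96 * se)
    hi = math.exp(math.log(orv) + 1.96 * se)
    return orv, lo, hi, haldane


def odds_ratio(table: ModelTable, orientation: str = "paper") -> list[AssociationResult]:
    """Odds ratio and Wald 95% CI for each exposure row vs the reference row.

    Returns one :class:`AssociationResult` per non-reference row (one for the
    2x2 models, two for codominant).  A single zero cell triggers the
    Haldane–Anscombe +0.5 correction on all four cells (flagged); two zero
    cells in a margin raise :class:`DegenerateTableError`.
    """
    ref = table.reference
    out = []
    for exp in table.exposures:
        orv, lo, hi, hald = _or_one(ref.cells, exp.cells, orientation)
        out.append(
            AssociationResult(
                table.model, exp.label, orv, lo, hi, None, orientation, hald
            )
        )
    return out


# ---------------------------------------------------------------------------
# likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LrTestResult:
    g_stat: float
    df: int
    p_value: float
    pearson_chi2: float
    pearson_p: float
    zero_cells: bool = False


def lr_test(table: ModelTable) -> LrTestResult:
    """Likelihood-ratio (G) test of independence, Pearson co-reported.

    G = 2 * sum obs*ln(obs/exp) over all cells with expectations from the
    independence margins; a zero observed cell contributes 0 (lim x ln x = 0)
    and flags the result.  df = rows - 1 (tables here always have 2 columns).
    """
    obs = table.cell_matrix()
    n = obs.sum()
    row_m, col_m = obs.sum(axis=1), obs.sum(axis=0)
    if n == 0 or (row_m == 0).any() or (col_m == 0).any():
        raise DegenerateTableError("degenerate margins in lr_test")
    exp = np.outer(row_m, col_m) / n
    nz = obs > 0
    g = 2.0 * float((obs[nz] * np.log(obs[nz] / exp[nz])).sum())
    pearson = float(((obs - exp) ** 2 / exp).sum())
    df = obs.shape[0] - 1
    return LrTestResult(
        g_stat=g,
        df=df,
        p_value=float(_chi2_dist.sf(g, df)),
        pearson_chi2=pearson,
        pearson_p=float(_chi2_dist.sf(pearson, df)),
        zero_cells=bool((~nz).any()),
    )


# ---------------------------------------------------------------------------
# full per-SNP run
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelBlock:
    """One genetic model's panel: the table, OR results and LR test."""

    table: ModelTable
    results: tuple[AssociationResult, ...]
    lr: LrTestResult


@dataclass(frozen=True)
class SnpReport:
    """All model panels for one SNP plus per-group HWE; mirrors a published panel."""

    counts: GenotypeCounts
    blocks: Mapping[str, ModelBlock]
    hwe: Mapping[str, HweResult]
    orientation: str
    n_tests: int = field(default=0)


def run_models_from_counts(
    counts: GenotypeCounts, orientation: str = "paper"
) -> SnpReport:
    """Run all four genetic models and HWE directly from genotype counts."""
    blocks = {}
    for model in MODELS:
        table = build_model_table(counts, model)
        lr = lr_test(table)
        results = tuple(
            AssociationResult(
                r.model, r.exposure, r.or_value, r.ci_lo, r.ci_hi,
                lr.p_value, r.orientation, r.haldane,
            )
            for r in odds_ratio(table, orientation)
        )
        blocks[model] = ModelBlock(table, results, lr)
    hwe = {g: hwe_test(counts, g) for g in counts.groups}
    return SnpReport(counts, blocks, hwe, orientation, n_tests=len(MODELS))


def run_models(
    dataset: GenotypeDataset,
    snp_id: str,
    group_pair: tuple[str, str],
    orientation: str = "paper",
) -> SnpReport:
    """Complete-case genetic-model association for one SNP in a dataset."""
    counts = count_genotypes(dataset, snp_id, group_pair)
    return run_models_from_counts(counts, orientation)
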