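"""Three-stage lncRNA-SNP candidate selection.

Stage 1: tumor-vs-normal differential expression of lncRNAs, filtered at a
linear fold change above 1.5 (|log2FC| > log2 1.5) and p < 0.001.  Stage 2:
intersection of GWAS-catalog breast-cancer SNPs with lncRNA genomic
intervals, keeping SNPs with minor allele frequency strictly above 0.20.
Stage 3: the host lncRNA must be differentially expressed in at least one
molecular-subtype contrast.  Survivors are ranked by the GWAS-reported odds
ratio and the top rows taken until the requested number of distinct SNPs is
collected (a single row may carry two SNPs in strong LD).

The DE test here is a Welch (unequal-variance) two-sample t on log2(x+1)
values, isolated behind :func:`de_test` so it can be swapped; no
multiple-testing correction is applied — the raw p < 0.001 cut is part of
the screen's definition.  Filters have set-intersection semantics: they are
idempotent and order-commutative, and each survivor carries its flag trail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BuildMismatchError, GwasRecord, Interval

logger = logging.getLogger(__name__)

SUBTYPES = ("luminal A", "luminal B", "HER2-enriched", "basal-like")


@dataclass(frozen=True)
class DeResult:
    """Differential expression of one gene: tumor-minus-normal log2FC, p,
    and per-subtype DE flags ('up' / 'down'; absent or 'ns' = not DE)."""

    gene: str
    log2fc: float
    p_value: float
    subtype_flags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"{self.gene}: p_value outside [0, 1]")

    def has_subtype_de(self) -> bool:
        return any(v in ("up", "down") for v in self.subtype_flags.values())


@dataclass(frozen=True)
class SelectionConfig:
    fc_threshold: float = 1.5  # LINEAR fold change
    de_p_threshold: float = 1e-3
    maf_threshold: float = 0.20
    n_select: int = 4

    def __post_init__(self) -> None:
        if min(self.fc_threshold, self.de_p_threshold, self.maf_threshold) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CandidateRecord:
    """An lncRNA/SNP pairing with its DE stats, GWAS record, host interval
    and the ordered trail of filters it has passed."""

    de: DeResult
    snp: GwasRecord
    interval: Interval
    passed_filters: tuple[str, ...] = ()

    def flag(self, name: str) -> "CandidateRecord":
        if name in self.passed_filters:
            return self
        return replace(self, passed_filters=self.passed_filters + (name,))


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def de_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t test on log2(x+1) values; returns (log2fc, p).

    log2fc = mean(A) - mean(B) on the log2(x+1) scale.  Degenerate
    zero-variance comparisons follow the tie convention: equal means give
    p = 1, unequal means with zero variance give p = 0.
    """
    la, lb = np.log2(np.asarray(a, float) + 1), np.log2(np.asarray(b, float) + 1)
    if la.size < 2 or lb.size < 2:
        raise ValueError("each group needs at least 2 samples")
    log2fc = float(la.mean() - lb.mean())
    if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
        return log2fc, 1.0 if math.isclose(la.mean(), lb.mean()) else 0.0
    p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
    return log2fc, p


def compute_de(
    values: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> list[DeResult]:
    """Per-gene DE between two sample groups of an expression matrix.

    ``values`` is genes x samples with non-negative expression; ``groups``
    maps sample id -> group label.  log2fc is group_a minus group_b, so
    swapping the groups negates log2fc and leaves p unchanged.
    """
    cols_a = [s for s in values.columns if groups.get(s) == group_a]
    cols_b = [s for s in values.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    out = []
    for gene in values.index:
        log2fc, p = de_test(values.loc[gene, cols_a].values, values.loc[gene, cols_b].values)
        out.append(DeResult(gene=gene, log2fc=log2fc, p_value=p))
    return out


def compute_subtype_flags(
    values: pd.DataFrame,
    groups: pd.Series,
    de_results: Sequence[DeResult],
    subtypes: Sequence[str] = SUBTYPES,
    config: SelectionConfig = SelectionConfig(),
) -> list[DeResult]:
    """Attach subtype-vs-rest DE flags (same test, same thresholds).

    For each subtype, samples of that subtype are contrasted against all
    other subtype-labeled samples; a gene is flagged 'up'/'down' when it
    clears the fold-change and p thresholds, else 'ns'.
    """
    log2_fc_cut = math.log2(config.fc_threshold)
    subtype_cols = {
        st: [s for s in values.columns if groups.get(s) == st] for st in subtypes
    }
    out = []
    for de in de_results:
        flags: dict[str, str] = {}
        for st in subtypes:
            cols_in = subtype_cols[st]
            cols_rest = [
                c for other, cc in subtype_cols.items() if other != st for c in cc
            ]
            if len(cols_in) < 2 or len(cols_rest) < 2:
                flags[st] = "ns"
                continue
            log2fc, p = de_test(
                values.loc[de.gene, cols_in].values,
                values.loc[de.gene, cols_rest].values,
            )
            if abs(log2fc) > log2_fc_cut and p < config.de_p_threshold:
                flags[st] = "up" if log2fc > 0 else "down"
            else:
                flags[st] = "ns"
        out.append(replace(de, subtype_flags=flags))
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_de(
    results: Iterable[DeResult], config: SelectionConfig = SelectionConfig()
) -> list[DeResult]:
    """Keep genes with linear |FC| > fc_threshold AND p < de_p_threshold."""
    cut = math.log2(config.fc_threshold)
    return [r for r in results if abs(r.log2fc) > cut and r.p_value < config.de_p_threshold]


def intersect_snps_lncrnas(
    gwas_records: Iterable[GwasRecord], intervals: Sequence[Interval]
) -> list[tuple[GwasRecord, Interval]]:
    """Pair every SNP whose 0-based position falls in [start, end) of an
    interval; a SNP inside two overlapping lncRNAs yields two pairs."""
    pairs = []
    for rec in gwas_records:
        for iv in intervals:
            if rec.build and iv.build and rec.build != iv.build:
                raise BuildMismatchError(
                    f"{rec.snp_id} ({rec.build}) vs interval {iv.name} ({iv.build})"
                )
            if iv.chrom == rec.chrom and iv.contains(rec.pos):
                pairs.append((rec, iv))
    return pairs


def filter_maf(
    pairs: Iterable[tuple[GwasRecord, Interval]],
    config: SelectionConfig = SelectionConfig(),
) -> list[tuple[GwasRecord, Interval]]:
    """Keep SNPs with MAF strictly above the threshold (rare-allele cut)."""
    return [(rec, iv) for rec, iv in pairs if rec.maf > config.maf_threshold]


def build_candidates(
    de_results: Iterable[DeResult], pairs: Iterable[tuple[GwasRecord, Interval]]
) -> list[CandidateRecord]:
    """Join DE results with SNP/interval pairs on the host-gene name."""
    by_gene = {r.gene: r for r in de_results}
    out = []
    for rec, iv in pairs:
        de = by_gene.get(iv.name)
        if de is not None:
            out.append(
                CandidateRecord(de, rec, iv, ("de", "intersect", "maf"))
            )
    return out


def filter_subtype_de(candidates: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    """Keep candidates whose host lncRNA is DE in at least one subtype."""
    return [c.flag("subtype_de") for c in candidates if c.de.has_subtype_de()]


def rank_select(
    candidates: Sequence[CandidateRecord],
    config: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Top-OR pick: rows sorted by reported OR descending, taken until
    ``n_select`` distinct SNPs are collected.

    A row's ``snp_id`` may carry several slash-separated rsIDs (SNPs in
    strong LD reported together); all of them count.  OR ties are broken by
    rsID lexicographic order and the tie-break is logged.  If fewer SNPs are
    available than requested, all are returned with a warning.
    """
    rows = sorted(candidates, key=lambda c: (-c.snp.reported_or, c.snp.snp_id))
    for a, b in zip(rows, rows[1:]):
        if a.snp.reported_or == b.snp.reported_or:
            logger.info(
                "rank_select: OR tie at %.4g broken by rsID order (%s before %s)",
                a.snp.reported_or, a.snp.snp_id, b.snp.snp_id,
            )
    selected: list[str] = []
    for row in rows:
        if len(selected) >= config.n_select:
            break
        for snp_id in row.snp.snp_id.split("/"):
            if snp_id not in selected:
                selected.append(snp_id)
    if len(selected) < config.n_select:
        logger.warning(
            "rank_select: only %d SNPs available, %d requested",
            len(selected), config.n_select,
        )
    return selected


def run_selection(
    de_results: Sequence[DeResult],
    gwas_records: Sequence[GwasRecord],
    intervals: Sequence[Interval],
    config: SelectionConfig = SelectionConfig(),
) -> tuple[list[CandidateRecord], list[str]]:
    """Full screen: DE filter, interval intersection, MAF filter, subtype
    filter, then top-OR selection.  Returns (surviving candidates, SNP ids)."""
    de_kept = filter_de(de_results, config)
    pairs = filter_maf(intersect_snps_lncrnas(gwas_records, intervals), config)
    candidates = filter_subtype_de(build_candidates(de_kept, pairs))
    return candidates, rank_select(candidates, config)
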