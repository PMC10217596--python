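"""Clinical stratification of cases and published-style table rendering.

Case samples are partitioned by a clinical variable — age dichotomized at
the cohort mean, a binary receptor/node status, or an ordinal grade — and
the genetic-model association engine is re-run with the strata as the two
columns (negative stratum first, positive second, so the paper-orientation
odds ratio reads off the published stratified tables unchanged).  Controls
never enter a stratified run.

Boundary convention: an age exactly equal to the cutoff goes to the
"higher" stratum.  Samples with a missing clinical value are dropped and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .association import SnpReport, run_models
from .io_formats import GenotypeDataset, round_half_up

logger = logging.getLogger(__name__)

RULES = ("dichotomize_at_mean", "binary_status", "ordinal_levels")


@dataclass(frozen=True)
class StratumRule:
    """How to split cases on one clinical variable.

    ``dichotomize_at_mean`` needs ``cutoff`` (values >= cutoff go to the
    "higher" stratum); ``binary_status`` maps values via ``status_map``
    (default: "negative"/"positive" pass through); ``ordinal_levels`` keeps
    the declared ``levels`` in order.
    """

    variable: str
    rule: str
    cutoff: float | None = None
    status_map: Mapping[str, str] | None = None
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.rule == "dichotomize_at_mean" and self.cutoff is None:
            raise ValueError("dichotomize_at_mean requires a cutoff")
        if self.rule == "ordinal_levels" and len(self.levels) < 2:
            raise ValueError("ordinal_levels requires >= 2 levels")

    def stratum_order(self) -> tuple[str, ...]:
        if self.rule == "dichotomize_at_mean":
            return ("lower", "higher")
        if self.rule == "binary_status":
            return ("negative", "positive")
        return self.levels

    def assign(self, value) -> str | None:
        """Stratum label for one clinical value; None = missing/unmappable."""
        if value is None or value == "":
            return None
        if self.rule == "dichotomize_at_mean":
            try:
                v = float(value)
            except (TypeError, ValueError):
                return None
            return "higher" if v >= self.cutoff else "lower"
        if self.rule == "binary_status":
            v = str(value)
            if self.status_map is not None:
                return self.status_map.get(v)
            return v if v in ("negative", "positive") else None
        v = str(value)
        return v if v in self.levels else None


def stratify(
    dataset: GenotypeDataset, rule: StratumRule, case_group: str = "case"
) -> GenotypeDataset:
    """Partition case samples into strata; controls are excluded.

    Group labels in the returned dataset are the stratum labels.  Cases with
    a missing or unmappable clinical value are dropped with the count
    logged; an empty stratum is an error naming the stratum.
    """
    cases = dataset.subset(lambda s: s.group == case_group)
    if not cases.samples:
        raise ValueError(f"no samples in case group {case_group!r}")
    assigned = {
        s.sample_id: rule.assign(s.clinical.get(rule.variable)) for s in cases.samples
    }
    n_missing = sum(1 for v in assigned.values() if v is None)
    if n_missing:
        logger.info(
            "stratify(%s): dropped %d cases with missing %s",
            rule.variable, n_missing, rule.variable,
        )
    kept = cases.subset(lambda s: assigned[s.sample_id] is not None)
    out = kept.relabel(lambda s: assigned[s.sample_id])
    sizes = {g: out.group_size(g) for g in rule.stratum_order()}
    for stratum, n in sizes.items():
        if n == 0:
            raise ValueError(f"stratum {stratum!r} of {rule.variable} is empty")
    return out


def run_stratified(
    dataset: GenotypeDataset,
    snp_id: str,
    rule: StratumRule,
    orientation: str = "paper",
    case_group: str = "case",
    strata: tuple[str, str] | None = None,
) -> SnpReport:
    """Genetic-model association between two strata of the cases.

    Column order is the rule's declared stratum order (negative, positive)
    unless ``strata`` overrides it (needed for ordinal rules with more than
    two levels, where one pair is contrasted at a time).
    """
    stratified = stratify(dataset, rule, case_group)
    pair = strata if strata is not None else tuple(rule.stratum_order())[:2]
    return run_models(stratified, snp_id, pair, orientation)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportTable:
    title: str
    lines: tuple[str, ...]

    @property
    def text(self) -> str:
        return "\n".join((self.title, *self.lines))


def _fmt(x: float) -> str:
    return f"{round_half_up(x):.2f}"


def render_table(report: SnpReport | None, title: str = "") -> ReportTable:
    """Render a SnpReport as a published-style text panel.

    Codominant rows first, then the dominant/recessive/overdominant blocks;
    each exposure row shows counts, OR (95% CI) rounded half-up to 2 dp and
    the block p; reference rows print "1.00".  Deterministic: identical
    input gives byte-identical text.
    """
    if report is None:
        return ReportTable(title, ())
    lines: list[str] = []
    g1, g2 = report.counts.groups
    n1, n2 = report.counts.total(g1), report.counts.total(g2)
    lines.append(
        f"{report.counts.snp.snp_id}\t{g1} (n = {n1})\t{g2} (n = {n2})\tOR (95%)\tp-Value"
    )

    def block(model: str, header: bool) -> None:
        blk = report.blocks[model]
        if header:
            lines.append(model.capitalize())
        p_txt = f"{blk.lr.p_value:.3g}"
        by_label = {r.exposure: r for r in blk.results}
        for i, row in enumerate(blk.table.rows):
            cells = f"{row.label}\t{row.cells[0]}\t{row.cells[1]}"
            if row.is_reference:
                lines.append(f"{cells}\t1.00" + (f"\t{p_txt}" if i == 0 else ""))
            else:
                r = by_label[row.label]
                orci = f"{_fmt(r.or_value)} ({_fmt(r.ci_lo)}–{_fmt(r.ci_hi)})"
                lines.append(f"{cells}\t{orci}" + (f"\t{p_txt}" if i == 0 else ""))

    block("codominant", header=False)
    lines.append("Models")
    for model in ("dominant", "recessive", "overdominant"):
        block(model, header=True)
    for g in report.counts.groups:
        hwe = report.hwe[g]
        lines.append(f"HWE {g}: chi2 = {hwe.chi2:.3f}, p = {hwe.p_value:.3g}")
    return ReportTable(title, tuple(lines))


def render_strata_tables(
    dataset: GenotypeDataset,
    snp_ids: Sequence[str],
    rules: Sequence[StratumRule],
    orientation: str = "paper",
    case_group: str = "case",
) -> list[ReportTable]:
    """Stratified panels for every SNP x rule combination."""
    out = []
    for snp_id in snp_ids:
        for rule in rules:
            report = run_stratified(dataset, snp_id, rule, orientation, case_group)
            out.append(render_table(report, title=f"{snp_id} by {rule.variable}"))
    return out
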