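"""Two-locus haplotype frequency estimation (EM), LD statistics and
haplotype-level case-control association.

With unphased diploid genotypes at two biallelic SNPs, every two-locus
genotype class determines its haplotype pair except the double heterozygote,
which is compatible with two phase resolutions (cis: A1B1/A2B2, trans:
A1B2/A2B1).  The EM algorithm iterates between splitting double
heterozygotes across the two resolutions in proportion to the current
haplotype-frequency products (E-step) and renormalizing haplotype counts
(M-step).  The observed-data log-likelihood is non-decreasing at every
iteration and is asserted as such on every run.

Haplotype order is fixed as (A1B1, A1B2, A2B1, A2B2) where A1/B1 are the
major alleles of the two SNPs; all frequency vectors use this order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .association import DegenerateTableError, lr_test, odds_ratio, two_by_two
from .io_formats import GenotypeDataset

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000


@dataclass(frozen=True)
class HaplotypeEstimate:
    """EM-estimated haplotype frequencies for one group (or pooled)."""

    haplotypes: tuple[tuple[str, str], ...]  # 4 (allele_a, allele_b) labels
    freqs: tuple[float, float, float, float]
    n_samples: int
    loglik_trace: tuple[float, ...]
    n_iter: int
    converged: bool
    group: str | None = None
    phase_symmetric: bool = False


@dataclass(frozen=True)
class LdStats:
    d: float
    d_prime: float
    r2: float


def _genotype_class_counts(
    dataset: GenotypeDataset, snp_a: str, snp_b: str, group: str | None
) -> np.ndarray:
    """3x3 counts n[i, j]: i/j = copies of the minor allele at SNP a/b.

    Samples missing either genotype are excluded (complete-case)."""
    da, db = dataset.snp_def(snp_a), dataset.snp_def(snp_b)
    n = np.zeros((3, 3), dtype=float)
    calls_a = dataset.calls(snp_a, group)
    calls_b = dataset.calls(snp_b, group)
    for ca, cb in zip(calls_a, calls_b):
        if ca is None or cb is None:
            continue
        n[ca.count(da.minor_allele), cb.count(db.minor_allele)] += 1
    return n


def _loglik(n: np.ndarray, f: np.ndarray) -> float:
    """Observed-data log-likelihood of the 3x3 class counts.

    f in order (f11, f12, f21, f22) = (A1B1, A1B2, A2B1, A2B2); class (i, j)
    counts copies of the MINOR allele (A2/B2)."""
    f11, f12, f21, f22 = f
    # P[i][j]: probability of i copies of A2 and j copies of B2
    p = np.empty((3, 3))
    p[0, 0] = f11 ** 2
    p[0, 1] = 2 * f11 * f12
    p[0, 2] = f12 ** 2
    p[1, 0] = 2 * f11 * f21
    p[1, 1] = 2 * f11 * f22 + 2 * f12 * f21
    p[1, 2] = 2 * f12 * f22
    p[2, 0] = f21 ** 2
    p[2, 1] = 2 * f21 * f22
    p[2, 2] = f22 ** 2
    nz = n > 0
    if (p[nz] <= 0).any():
        return -math.inf
    return float((n[nz] * np.log(p[nz])).sum())


def em_haplotypes(
    dataset: GenotypeDataset,
    snp_a: str,
    snp_b: str,
    group: str | None = None,
    tol: float = _EM_TOL,
    max_iter: int = _EM_MAX_ITER,
) -> HaplotypeEstimate:
    """EM haplotype-frequency estimation from unphased two-locus genotypes.

    ``group=None`` pools all samples.  Initialization is at linkage
    equilibrium (products of observed allele frequencies), which makes the
    outcome deterministic; when the two phase resolutions of the double
    heterozygotes are exactly equally likely the estimate stays at the
    symmetric point and the result is flagged ``phase_symmetric``.
    Convergence: max |change in any frequency| < ``tol``, cap ``max_iter``
    iterations; non-convergence flags the result rather than raising.
    """
    da, db = dataset.snp_def(snp_a), dataset.snp_def(snp_b)
    n = _genotype_class_counts(dataset, snp_a, snp_b, group)
    n_samples = int(n.sum())
    if n_samples == 0:
        raise DegenerateTableError("no samples with both genotypes observed")

    # allele frequencies of the MINOR alleles (index-2 direction)
    qa = (n.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n_samples)
    qb = (n.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n_samples)
    pa, pb = 1 - qa, 1 - qb
    f = np.array([pa * pb, pa * qb, qa * pb, qa * qb], dtype=float)

    # haplotype copies contributed by the 8 unambiguous classes
    # (i, j) -> vector of haplotype counts per individual
    contrib = {
        (0, 0): (2, 0, 0, 0), (0, 1): (1, 1, 0, 0), (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0), (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0), (2, 1): (0, 0, 1, 1), (2, 2): (0, 0, 0, 2),
    }
    base = np.zeros(4)
    for (i, j), vec in contrib.items():
        base += n[i, j] * np.asarray(vec, dtype=float)
    n_dh = n[1, 1]

    trace = [_loglik(n, f)]
    converged = False
    n_iter = 0
    phase_symmetric = False
    for n_iter in range(1, max_iter + 1):
        p_cis = f[0] * f[3]
        p_trans = f[1] * f[2]
        w = 0.5 if p_cis + p_trans == 0 else p_cis / (p_cis + p_trans)
        expected = base.copy()
        expected += n_dh * np.array([w, 1 - w, 1 - w, w])
        f_new = expected / (2 * n_samples)
        delta = float(np.abs(f_new - f).max())
        f = f_new
        ll = _loglik(n, f)
        assert ll >= trace[-1] - 1e-9, "EM log-likelihood decreased"
        trace.append(ll)
        if delta < tol:
            converged = True
            if n_dh > 0 and abs(w - 0.5) < 1e-12:
                phase_symmetric = True
            break

    labels = (
        (da.major_allele, db.major_allele),
        (da.major_allele, db.minor_allele),
        (da.minor_allele, db.major_allele),
        (da.minor_allele, db.minor_allele),
    )
    return HaplotypeEstimate(
        haplotypes=labels,
        freqs=tuple(float(x) for x in f),
        n_samples=n_samples,
        loglik_trace=tuple(trace),
        n_iter=n_iter,
        converged=converged,
        group=group,
        phase_symmetric=phase_symmetric,
    )


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------


def ld_from_haplotypes(freqs: Sequence[float]) -> LdStats:
    """D, D' and r^2 from a 4-vector of haplotype frequencies.

    Frequencies in order (A1B1, A1B2, A2B1, A2B2), summing to 1.
    D = f(A1B1) - f(A1)f(B1); D' = D / Dmax with
    Dmax = min(f(A1)f(B2), f(A2)f(B1)) for D > 0 and
    Dmax = min(f(A1)f(B1), f(A2)f(B2)) for D < 0;
    r^2 = D^2 / [f(A1)f(A2)f(B1)f(B2)].  A monomorphic locus is an error.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
        raise ValueError("freqs must be 4 non-negative reals summing to 1")
    pa = f[0] + f[1]  # f(A1)
    pb = f[0] + f[2]  # f(B1)
    qa, qb = 1 - pa, 1 - pb
    denom = pa * qa * pb * qb
    if denom == 0:
        raise DegenerateTableError("monomorphic locus: LD undefined")
    d = f[0] - pa * pb
    if d > 0:
        dmax = min(pa * qb, qa * pb)
    elif d < 0:
        dmax = min(pa * pb, qa * qb)
    else:
        return LdStats(0.0, 0.0, 0.0)
    return LdStats(float(d), float(d / dmax), float(d * d / denom))


def haplotype_freqs_for_ld(
    d_prime: float, r2: float, pb: float = 0.75
) -> tuple[float, float, float, float]:
    """Construct haplotype frequencies realizing given positive D' and r^2.

    The pair (D', r^2) underdetermines the 3-parameter frequency simplex, so
    the B1 allele frequency ``pb`` is fixed and the A1 frequency solved for.
    Only the D > 0, Dmax = f(A1)f(B2) branch is searched; raises if the
    target is infeasible on that branch.
    """
    if not (0 < d_prime <= 1 and 0 < r2 <= 1 and 0 < pb < 1):
        raise ValueError("d_prime, r2 in (0,1], pb in (0,1)")
    qb = 1 - pb

    def gap(pa: float) -> float:
        qa = 1 - pa
        # on this branch r2 = d_prime^2 * (pa*qb)/(qa*pb)
        return d_prime ** 2 * (pa * qb) / (qa * pb) - r2

    pa = brentq(gap, 1e-9, 1 - 1e-9)
    qa = 1 - pa
    if pa * qb > qa * pb:  # wrong branch: Dmax would be qa*pb
        raise ValueError("target (d_prime, r2, pb) infeasible on searched branch")
    d = d_prime * (pa * qb)
    f = (pa * pb + d, pa * qb - d, qa * pb - d, qa * qb + d)
    if any(x < -1e-12 for x in f):
        raise ValueError("target (d_prime, r2, pb) yields negative frequency")
    return tuple(max(x, 0.0) for x in f)


# ---------------------------------------------------------------------------
# haplotype association
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypeAssociation:
    """Per-haplotype vs reference OR/CI/p; reference OR is 1 by construction."""

    haplotypes: tuple[tuple[str, str], ...]
    reference: tuple[str, str]
    pooled_freqs: tuple[float, ...]
    or_values: tuple[float | None, ...]  # None for the reference haplotype
    ci_lo: tuple[float | None, ...]
    ci_hi: tuple[float | None, ...]
    p_values: tuple[float | None, ...]
    counts: dict[str, tuple[int, ...]]  # estimated 2N*freq per group
    orientation: str


def haplotype_association(
    est_case: HaplotypeEstimate,
    est_ctrl: HaplotypeEstimate,
    n_case: int | None = None,
    n_ctrl: int | None = None,
    orientation: str = "paper",
    group_labels: tuple[str, str] = ("case", "control"),
) -> HaplotypeAssociation:
    """Haplotype-level association from per-group EM estimates.

    Haplotype counts are taken as round(2N * freq) per group (estimated, not
    observed — double-heterozygote phase is resolved statistically).  Each
    haplotype forms a 2x2 table against the reference haplotype (the most
    frequent pooled) which is fed to the engine's odds-ratio and
    likelihood-ratio test under the given orientation.
    """
    if est_case.haplotypes != est_ctrl.haplotypes:
        raise ValueError("estimates use different haplotype labelings")
    n_case = est_case.n_samples if n_case is None else n_case
    n_ctrl = est_ctrl.n_samples if n_ctrl is None else n_ctrl
    counts_case = [round(2 * n_case * f) for f in est_case.freqs]
    counts_ctrl = [round(2 * n_ctrl * f) for f in est_ctrl.freqs]
    total = 2 * (n_case + n_ctrl)
    pooled = tuple(
        (2 * n_case * fc + 2 * n_ctrl * ff) / total
        for fc, ff in zip(est_case.freqs, est_ctrl.freqs)
    )
    ref_idx = int(np.argmax(pooled))
    if counts_case[ref_idx] == 0 or counts_ctrl[ref_idx] == 0:
        raise DegenerateTableError("reference haplotype absent in one group")

    ors: list[float | None] = []
    los: list[float | None] = []
    his: list[float | None] = []
    ps: list[float | None] = []
    ref_cells = (counts_case[ref_idx], counts_ctrl[ref_idx])
    ref_label = "".join(est_case.haplotypes[ref_idx])
    for i, hap in enumerate(est_case.haplotypes):
        if i == ref_idx:
            ors.append(None)
            los.append(None)
            his.append(None)
            ps.append(None)
            continue
        table = two_by_two(
            group_labels, ref_label, ref_cells,
            "".join(hap), (counts_case[i], counts_ctrl[i]),
            model="haplotype",
        )
        res = odds_ratio(table, orientation)[0]
        lr = lr_test(table)
        ors.append(res.or_value)
        los.append(res.ci_lo)
        his.append(res.ci_hi)
        ps.append(lr.p_value)
    return HaplotypeAssociation(
        haplotypes=est_case.haplotypes,
        reference=est_case.haplotypes[ref_idx],
        pooled_freqs=pooled,
        or_values=tuple(ors),
        ci_lo=tuple(los),
        ci_hi=tuple(his),
        p_values=tuple(ps),
        counts={
            group_labels[0]: tuple(counts_case),
            group_labels[1]: tuple(counts_ctrl),
        },
        orientation=orientation,
    )
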