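"""Synthetic cohorts, two-locus haplotype data, expression matrices and
GWAS-catalog-like records with known ground truth.

Every downstream stage of the pipeline can be exercised on data generated
here, with planted parameters serving as exact oracles:

* :func:`gen_cohort` draws per-sample genotypes either under Hardy–Weinberg
  equilibrium at a given MAF or from explicit per-group genotype
  probabilities.  Disease effects are specified via per-group genotype
  probabilities (not a logistic model) so the expected odds ratio of any
  genetic model is analytic.
* :func:`gen_two_locus` draws two haplotypes i.i.d. per individual from a
  group-specific haplotype distribution and exposes only the unphased
  genotypes; the true phase is retained in a hidden audit channel
  (``dataset.audit_haplotypes``) for tests.
* :func:`gen_expression` produces log-normal expression with planted
  per-group log2 offsets.
* :func:`gen_gwas_records` builds GWAS-catalog-style records positioned
  inside or outside given lncRNA intervals.

Seeding: one global integer seed, split deterministically per sub-generator
via ``numpy.random.SeedSequence(seed, spawn_key=(tag,))`` so adding a
generator never shifts existing streams.  A fixed seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GwasRecord, GenotypeDataset, Interval, Sample, SnpDef

# stable per-generator stream tags
_STREAM = {"cohort": 1, "twolocus": 2, "expression": 3, "gwas": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM[stream],))
    )


def hwe_genotype_probs(maf: float) -> tuple[float, float, float]:
    """(hom-major, het, hom-minor) probabilities under HWE at minor freq q."""
    if not (0 < maf <= 0.5):
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    q = maf
    p = 1 - q
    return (p * p, 2 * p * q, q * q)


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpCohortSpec:
    """Genotype distribution for one SNP: HWE at ``maf`` (shared across
    groups) or explicit per-group (hom-major, het, hom-minor) probabilities.
    ``missing_rate`` may be a scalar or a per-group mapping."""

    snp: SnpDef
    maf: float | None = None
    genotype_probs: Mapping[str, tuple[float, float, float]] | None = None
    missing_rate: float | Mapping[str, float] = 0.0

    def probs_for(self, group: str) -> tuple[float, float, float]:
        if self.genotype_probs is not None:
            probs = tuple(self.genotype_probs[group])
            if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(
                    f"{self.snp.snp_id}/{group}: genotype probs must be a distribution"
                )
            return probs
        if self.maf is None:
            raise ValueError(f"{self.snp.snp_id}: need maf or genotype_probs")
        return hwe_genotype_probs(self.maf)

    def missing_for(self, group: str) -> float:
        r = self.missing_rate
        rate = float(r if isinstance(r, (int, float)) else r[group])
        if not (0 <= rate < 1):
            raise ValueError(f"missing_rate must be in [0, 1), got {rate}")
        return rate


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: Mapping[str, int]
    snp_specs: Sequence[SnpCohortSpec]
    seed: int = 0
    clinical: Mapping[str, Mapping[str, Sequence[object]]] = field(
        default_factory=dict
    )  # group -> variable -> per-sample values


def gen_cohort(spec: CohortSpec) -> GenotypeDataset:
    """Draw a case-control genotype cohort from a :class:`CohortSpec`.

    Genotypes are drawn independently per sample; missingness is applied
    after the draw.  Reproducible and byte-identical under a fixed seed.
    """
    rng = _rng(spec.seed, "cohort")
    samples: list[Sample] = []
    group_slices: dict[str, slice] = {}
    offset = 0
    for group, n in spec.n_per_group.items():
        clin = spec.clinical.get(group, {})
        for i in range(n):
            clinical = {k: v[i] for k, v in clin.items()}
            samples.append(Sample(f"{group}_{i:05d}", group, clinical))
        group_slices[group] = slice(offset, offset + n)
        offset += n

    genotypes: dict[str, list[tuple[str, str] | None]] = {}
    for snp_spec in spec.snp_specs:
        snp = snp_spec.snp
        geno_strings = (
            (snp.major_allele, snp.major_allele),
            tuple(sorted((snp.major_allele, snp.minor_allele))),
            (snp.minor_allele, snp.minor_allele),
        )
        column: list[tuple[str, str] | None] = []
        for group, n in spec.n_per_group.items():
            probs = snp_spec.probs_for(group)
            idx = rng.choice(3, size=n, p=probs)
            miss = rng.random(n) < snp_spec.missing_for(group)
            column.extend(
                None if m else geno_strings[k] for k, m in zip(idx, miss)
            )
        genotypes[snp.snp_id] = column
    return GenotypeDataset(
        samples=samples, snp_defs=[s.snp for s in spec.snp_specs], genotypes=genotypes
    )


# ---------------------------------------------------------------------------
# two-locus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoLocusSpec:
    """Per-group haplotype frequencies over (A1B1, A1B2, A2B1, A2B2).

    Vectors summing to 1 within 2e-3 are renormalized, so published
    frequency columns rounded to a few decimals can serve directly as
    simulation truth.
    """

    snp_a: SnpDef
    snp_b: SnpDef
    haplotype_freqs: Mapping[str, Sequence[float]]
    n_per_group: Mapping[str, int]
    seed: int = 0

    def freqs_for(self, group: str) -> np.ndarray:
        f = np.asarray(self.haplotype_freqs[group], dtype=float)
        if f.shape != (4,) or (f < 0).any():
            raise ValueError(f"{group}: need 4 non-negative frequencies")
        s = f.sum()
        if abs(s - 1) > 2e-3:
            raise ValueError(f"{group}: haplotype frequencies sum to {s}, not 1")
        return f / s


def gen_two_locus(spec: TwoLocusSpec) -> GenotypeDataset:
    """Draw unphased two-locus genotypes; true phase kept for auditing.

    Each individual receives two haplotypes drawn i.i.d. from the group's
    haplotype distribution.  The returned dataset exposes only unphased
    genotype pairs; ``dataset.audit_haplotypes`` maps sample_id to the true
    (h1, h2) haplotype indices into (A1B1, A1B2, A2B1, A2B2).
    """
    rng = _rng(spec.seed, "twolocus")
    a, b = spec.snp_a, spec.snp_b
    # haplotype index -> (allele at A, allele at B)
    hap_alleles = (
        (a.major_allele, b.major_allele),
        (a.major_allele, b.minor_allele),
        (a.minor_allele, b.major_allele),
        (a.minor_allele, b.minor_allele),
    )
    samples: list[Sample] = []
    col_a: list[tuple[str, str] | None] = []
    col_b: list[tuple[str, str] | None] = []
    audit: dict[str, tuple[int, int]] = {}
    for group, n in spec.n_per_group.items():
        f = spec.freqs_for(group)
        haps = rng.choice(4, size=(n, 2), p=f)
        for i, (h1, h2) in enumerate(haps):
            sid = f"{group}_{i:05d}"
            samples.append(Sample(sid, group))
            audit[sid] = (int(h1), int(h2))
            aa = tuple(sorted((hap_alleles[h1][0], hap_alleles[h2][0])))
            bb = tuple(sorted((hap_alleles[h1][1], hap_alleles[h2][1])))
            col_a.append(aa)
            col_b.append(bb)
    ds = GenotypeDataset(
        samples=samples,
        snp_defs=[a, b],
        genotypes={a.snp_id: col_a, b.snp_id: col_b},
    )
    ds.audit_haplotypes = audit  # hidden audit channel for tests
    return ds


def dataset_from_counts(
    snp: SnpDef,
    blocks: Sequence[tuple[str, Mapping[str, object], tuple[int, int, int]]],
) -> GenotypeDataset:
    """Deterministically expand genotype counts into a single-SNP dataset.

    ``blocks`` is a sequence of (group_label, clinical_map, (n_hom_major,
    n_het, n_hom_minor)); the returned dataset reproduces those counts
    exactly, making printed tables usable as dataset-level fixtures.
    """
    geno = (
        (snp.major_allele, snp.major_allele),
        tuple(sorted((snp.major_allele, snp.minor_allele))),
        (snp.minor_allele, snp.minor_allele),
    )
    samples: list[Sample] = []
    column: list[tuple[str, str] | None] = []
    sid = 0
    for group, clinical, counts in blocks:
        for k, n in enumerate(counts):
            for _ in range(n):
                samples.append(Sample(f"S{sid:05d}", group, dict(clinical)))
                column.append(geno[k])
                sid += 1
    return GenotypeDataset(
        samples=samples, snp_defs=[snp], genotypes={snp.snp_id: column}
    )


# ---------------------------------------------------------------------------
# expression generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSpec:
    """Log-normal expression with planted per-group log2 offsets.

    ``planted_log2fc[gene][group]`` is added to the baseline on the log2
    scale for samples of that group; the tumor-vs-normal log2 fold change of
    a gene is therefore offset[tumor] - offset[normal], analytically.
    Groups may include molecular-subtype labels alongside tumor/normal.
    """

    n_genes: int
    group_sizes: Mapping[str, int]
    planted_log2fc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.3
    baseline: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class ExpressionTable:
    values: pd.DataFrame  # genes x samples, non-negative FPKM-like
    groups: pd.Series  # sample -> group label
    truth: Mapping[str, Mapping[str, float]]  # planted per-group log2 offsets


def gen_expression(spec: ExpressionSpec) -> ExpressionTable:
    """Generate an FPKM-like matrix: value = 2**(baseline + offset + noise)."""
    rng = _rng(spec.seed, "expression")
    genes = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    gene_names = list(spec.planted_log2fc)
    for i, g in enumerate(gene_names):
        if i < len(genes):
            genes[i] = g
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for group, n in spec.group_sizes.items():
        offsets = np.array(
            [spec.planted_log2fc.get(g, {}).get(group, 0.0) for g in genes]
        )
        for i in range(n):
            sid = f"{group}_{i:04d}"
            noise = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            cols[sid] = np.exp2(spec.baseline + offsets + noise)
            groups[sid] = group
    values = pd.DataFrame(cols, index=genes)
    return ExpressionTable(values=values, groups=pd.Series(groups), truth=spec.planted_log2fc)


# ---------------------------------------------------------------------------
# GWAS-record generator
# ---------------------------------------------------------------------------


def gen_gwas_records(
    snp_defs: Sequence[SnpDef],
    or_values: Sequence[float],
    mafs: Sequence[float],
    seed: int = 0,
    intervals: Sequence[Interval] = (),
    placement: Sequence[str] | None = None,
    trait: str = "breast carcinoma",
) -> list[GwasRecord]:
    """GWAS-catalog-style records with stated ORs/MAFs, placed relative to
    intervals.

    ``placement[i]`` is ``"inside"`` (position drawn uniformly within the
    interval matching the SNP's host gene, or the first interval on its
    chromosome), ``"outside"`` (position guaranteed not to overlap any
    interval) or ``"keep"`` (use the SnpDef position).  Default: keep.
    """
    if not (len(snp_defs) == len(or_values) == len(mafs)):
        raise ValueError("snp_defs, or_values and mafs must have equal length")
    if placement is not None and len(placement) != len(snp_defs):
        raise ValueError("placement length mismatch")
    rng = _rng(seed, "gwas")
    records = []
    for i, (snp, orv, maf) in enumerate(zip(snp_defs, or_values, mafs)):
        mode = placement[i] if placement is not None else "keep"
        pos0 = snp.pos - 1
        chrom = snp.chrom
        if mode == "inside":
            host = next(
                (
                    iv
                    for iv in intervals
                    if iv.name == snp.host_gene or (not snp.host_gene and iv.chrom == chrom)
                ),
                None,
            )
            if host is None:
                raise ValueError(f"{snp.snp_id}: no interval to place inside")
            pos0 = int(rng.integers(host.start, host.end))
            chrom = host.chrom
        elif mode == "outside":
            span = [iv for iv in intervals if iv.chrom == chrom]
            limit = max((iv.end for iv in span), default=0) + 10_000
            for _ in range(1000):
                cand = int(rng.integers(limit, limit + 1_000_000))
                if not any(iv.contains(cand) for iv in span):
                    pos0 = cand
                    break
        elif mode != "keep":
            raise ValueError(f"unknown placement {mode!r}")
        records.append(
            GwasRecord(
                snp_id=snp.snp_id,
                chrom=chrom,
                pos=pos0,
                trait=trait,
                reported_or=float(orv),
                maf=float(maf),
                build=snp.build,
            )
        )
    return records
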