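"""Readers and writers for the external formats the pipeline touches.

Everything is normalized into a small internal data model: :class:`SnpDef`
describes a biallelic SNP, :class:`GenotypeDataset` holds per-sample unphased
diploid genotypes plus group labels and clinical covariates, and
:class:`GwasRecord` / :class:`Interval` carry the GWAS-catalog and lncRNA
annotation inputs of the candidate-selection stage.

Conventions
-----------
* Genotypes are unordered allele pairs stored as alphabetically sorted
  2-tuples; missing genotypes are ``None``.
* BED intervals are 0-based half-open.  GWAS-catalog positions arrive 1-based
  and are converted to 0-based point coordinates on read, so overlap tests
  never mix conventions.
* Strand is read but ignored for overlap; SNP-in-lncRNA membership is purely
  positional.
* Genome build is carried as metadata on both :class:`SnpDef` and
  :class:`Interval`; operations that combine the two raise on a mismatch
  rather than lifting over.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING = None


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


class BuildMismatchError(ValueError):
    """Two genomic inputs carry different genome-build metadata."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP: identity, location and its two allele labels.

    ``major_allele``/``minor_allele`` are the population-level labels used to
    orient genotype counts; which of the two is actually rarer in a given
    dataset is decided from the data unless explicitly overridden.
    """

    snp_id: str
    chrom: str
    pos: int  # 1-based
    major_allele: str
    minor_allele: str
    host_gene: str = ""
    build: str = ""

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be nonempty")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.major_allele == self.minor_allele:
            raise ValidationError(f"{self.snp_id}: alleles must differ")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.major_allele, self.minor_allele))


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str
    clinical: Mapping[str, object] = field(default_factory=dict)


def normalize_genotype(pair: Sequence[str] | None) -> tuple[str, str] | None:
    """Sort an allele pair alphabetically; idempotent and order-insensitive."""
    if pair is None:
        return None
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeDataset:
    """Unphased diploid genotypes for a set of samples at a set of SNPs.

    ``genotypes`` maps snp_id -> list parallel to ``samples`` of normalized
    allele pairs (or ``None`` for missing).  Complete-case analysis is the
    rule downstream: each SNP is analyzed on its non-missing samples.
    """

    samples: list[Sample]
    snp_defs: list[SnpDef]
    genotypes: dict[str, list[tuple[str, str] | None]]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_ids must be unique")
        defs = {d.snp_id: d for d in self.snp_defs}
        for snp_id, calls in self.genotypes.items():
            if snp_id not in defs:
                raise ValidationError(f"genotypes for undeclared SNP {snp_id}")
            if len(calls) != len(self.samples):
                raise ValidationError(f"{snp_id}: genotype column length mismatch")
            allowed = defs[snp_id].alleles
            for sample, call in zip(self.samples, calls):
                if call is None:
                    continue
                if not set(call) <= allowed:
                    raise ValidationError(
                        f"SNP {snp_id}, sample {sample.sample_id}: "
                        f"allele(s) {set(call) - allowed} not in {{"
                        f"{defs[snp_id].major_allele},{defs[snp_id].minor_allele}}}"
                    )

    # -- convenience accessors -------------------------------------------

    def snp_def(self, snp_id: str) -> SnpDef:
        for d in self.snp_defs:
            if d.snp_id == snp_id:
                return d
        raise KeyError(snp_id)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.group, None)
        return list(seen)

    def group_size(self, group: str) -> int:
        return sum(1 for s in self.samples if s.group == group)

    def calls(
        self, snp_id: str, group: str | None = None, drop_missing: bool = False
    ) -> list[tuple[str, str] | None]:
        out = [
            call
            for sample, call in zip(self.samples, self.genotypes[snp_id])
            if group is None or sample.group == group
        ]
        if drop_missing:
            out = [c for c in out if c is not None]
        return out

    def n_missing(self, snp_id: str, group: str | None = None) -> int:
        return sum(1 for c in self.calls(snp_id, group) if c is None)

    def subset(self, keep) -> "GenotypeDataset":
        """New dataset with samples for which ``keep(sample)`` is truthy."""
        mask = [bool(keep(s)) for s in self.samples]
        return GenotypeDataset(
            samples=[s for s, m in zip(self.samples, mask) if m],
            snp_defs=list(self.snp_defs),
            genotypes={
                snp: [c for c, m in zip(col, mask) if m]
                for snp, col in self.genotypes.items()
            },
        )

    def relabel(self, label_for) -> "GenotypeDataset":
        """New dataset with each sample's group replaced by ``label_for(sample)``."""
        return GenotypeDataset(
            samples=[replace(s, group=label_for(s)) for s in self.samples],
            snp_defs=list(self.snp_defs),
            genotypes={snp: list(col) for snp, col in self.genotypes.items()},
        )


@dataclass(frozen=True)
class GwasRecord:
    """One GWAS-catalog association: SNP, trait, reported OR and risk-allele MAF."""

    snp_id: str
    chrom: str
    pos: int  # 0-based point coordinate (converted from the catalog's 1-based)
    trait: str
    reported_or: float
    maf: float
    ci_lo: float | None = None
    ci_hi: float | None = None
    build: str = ""

    def __post_init__(self) -> None:
        if self.reported_or <= 0:
            raise ValidationError(f"{self.snp_id}: OR must be positive")
        if not (0 < self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: MAF must be in (0, 0.5]")
        if self.ci_lo is not None and self.ci_hi is not None:
            if not (self.ci_lo <= self.reported_or <= self.ci_hi):
                raise ValidationError(f"{self.snp_id}: CI does not bracket OR")


@dataclass(frozen=True)
class Interval:
    """Genomic interval of an lncRNA gene, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."
    build: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.name or self.chrom}: start {self.start} >= end {self.end}"
            )
        if self.start < 0:
            raise ValidationError(f"interval {self.name}: negative start")

    def contains(self, pos0: int) -> bool:
        """Membership of a 0-based point position (half-open on the right)."""
        return self.start <= pos0 < self.end


# ---------------------------------------------------------------------------
# delimited genotype tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeDialect:
    """How a delimited genotype table is laid out."""

    delimiter: str = ","
    sample_col: str = "sample_id"
    group_col: str = "group"
    missing_token: str = "NA"
    clinical_cols: tuple[str, ...] = ()


def _parse_call(token: str, dialect: GenotypeDialect) -> tuple[str, str] | None:
    token = token.strip()
    if token == dialect.missing_token or token == "":
        return None
    if len(token) != 2:
        raise ValueError(f"genotype token {token!r} is not a two-allele string")
    return normalize_genotype((token[0], token[1]))


def read_genotype_table(
    path,
    snp_defs: Sequence[SnpDef],
    dialect: GenotypeDialect = GenotypeDialect(),
) -> GenotypeDataset:
    """Read a delimited genotype table into a :class:`GenotypeDataset`.

    Genotype columns are named by snp_id and hold two-character allele strings
    ("CT"); allele order in the file is irrelevant.  Raises :class:`FormatError`
    with the offending line number on malformed rows and
    :class:`ValidationError` when an allele is not among the SNP's declared
    pair.
    """
    defs = {d.snp_id: d for d in snp_defs}
    samples: list[Sample] = []
    columns: dict[str, list[tuple[str, str] | None]] = {d.snp_id: [] for d in snp_defs}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header")
        for col in (dialect.sample_col, dialect.group_col, *defs):
            if col not in reader.fieldnames:
                raise FormatError(f"{path}: missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(k) is None for k in (dialect.sample_col, dialect.group_col)):
                raise FormatError(f"{path}:{lineno}: short row")
            clinical = {c: row[c] for c in dialect.clinical_cols if c in row}
            samples.append(
                Sample(row[dialect.sample_col], row[dialect.group_col], clinical)
            )
            for snp_id in defs:
                try:
                    columns[snp_id].append(_parse_call(row[snp_id], dialect))
                except (ValueError, TypeError) as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return GenotypeDataset(samples=samples, snp_defs=list(snp_defs), genotypes=columns)


def write_genotype_table(
    dataset: GenotypeDataset, path, dialect: GenotypeDialect = GenotypeDialect()
) -> None:
    """Inverse of :func:`read_genotype_table` (round-trip safe)."""
    clin_cols = list(dialect.clinical_cols)
    header = [dialect.sample_col, dialect.group_col, *clin_cols] + [
        d.snp_id for d in dataset.snp_defs
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for i, sample in enumerate(dataset.samples):
            row = [sample.sample_id, sample.group]
            row += [str(sample.clinical.get(c, "")) for c in clin_cols]
            for d in dataset.snp_defs:
                call = dataset.genotypes[d.snp_id][i]
                row.append(dialect.missing_token if call is None else "".join(call))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_genotypes(
    path, sample_group_map: Mapping[str, str], build: str = ""
) -> GenotypeDataset:
    """Read biallelic GT calls from a VCF into a :class:`GenotypeDataset`.

    Phase separators are ignored (``|`` treated as ``/``); half-missing calls
    become missing; multi-allelic records are skipped with a warning.  Every
    VCF sample must appear in ``sample_group_map``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    for sid in vcf.samples:
        if sid not in sample_group_map:
            raise ValidationError(f"VCF sample {sid} absent from sample_group_map")
    samples = [Sample(sid, sample_group_map[sid]) for sid in vcf.samples]
    snp_defs: list[SnpDef] = []
    columns: dict[str, list[tuple[str, str] | None]] = {}
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multi-allelic record %s at %s:%d",
                variant.ID, variant.CHROM, variant.POS,
            )
            continue
        ref, alt = variant.REF, variant.ALT[0]
        snp = SnpDef(
            snp_id=variant.ID or f"{variant.CHROM}:{variant.POS}",
            chrom=variant.CHROM,
            pos=variant.POS,
            major_allele=ref,
            minor_allele=alt,
            build=build,
        )
        alleles = (ref, alt)
        calls: list[tuple[str, str] | None] = []
        for gt in variant.genotypes:  # [allele_a, allele_b, phased]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:  # includes half-missing
                calls.append(None)
            else:
                calls.append(normalize_genotype((alleles[a], alleles[b])))
        snp_defs.append(snp)
        columns[snp.snp_id] = calls
    if n_skipped:
        logger.info("skipped %d multi-allelic records", n_skipped)
    return GenotypeDataset(samples=samples, snp_defs=snp_defs, genotypes=columns)


# ---------------------------------------------------------------------------
# GWAS catalog
# ---------------------------------------------------------------------------

#: Default mapping from GWAS-catalog column names to GwasRecord fields.
GWAS_CATALOG_COLUMNS = {
    "snp_id": "SNPS",
    "chrom": "CHR_ID",
    "pos": "CHR_POS",
    "or": "OR or BETA",
    "maf": "RISK ALLELE FREQUENCY",
    "trait": "DISEASE/TRAIT",
}


def read_gwas_catalog(
    path, columns: Mapping[str, str] = GWAS_CATALOG_COLUMNS, build: str = ""
) -> list[GwasRecord]:
    """Parse a GWAS-catalog-style TSV into :class:`GwasRecord` objects.

    Rows whose position, OR or frequency fail to parse are dropped and the
    drop count logged; a missing mandatory column raises :class:`FormatError`.
    Catalog positions are 1-based and converted to 0-based points.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    records: list[GwasRecord] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            pos1 = int(str(row[columns["pos"]]))
            rec = GwasRecord(
                snp_id=str(row[columns["snp_id"]]),
                chrom=str(row[columns["chrom"]]),
                pos=pos1 - 1,
                trait=str(row[columns["trait"]]),
                reported_or=float(row[columns["or"]]),
                maf=float(row[columns["maf"]]),
                build=build,
            )
        except (ValueError, ValidationError):
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.info("read_gwas_catalog: dropped %d unparseable rows", n_dropped)
    return records


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_lncrna_bed(path, build: str = "") -> list[Interval]:
    """Read BED3/BED4(+) lncRNA intervals (0-based half-open, name optional)."""
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    Interval(fields[0], start, end, name=name, strand=strand, build=build)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return intervals


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

#: Result fields that receive a published-style 2 dp display column.
_DISPLAY_2DP = ("or_value", "ci_lo", "ci_hi")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (1.475 -> 1.48), matching printed table cells."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def write_results_tsv(results: Iterable, path) -> None:
    """Write a result collection as TSV with deterministic column order.

    Floats are written at full precision; OR/CI fields additionally get a
    ``*_display`` column rounded half-up to 2 dp to match printed tables.
    Accepts dataclass instances or mappings; an empty collection yields a
    header-only file when the element type is unknown (no columns).
    """
    import dataclasses

    rows = []
    for item in results:
        if dataclasses.is_dataclass(item):
            rows.append(dataclasses.asdict(item))
        else:
            rows.append(dict(item))
    df = pd.DataFrame(rows)
    for col in _DISPLAY_2DP:
        if col in df.columns:
            df[f"{col}_display"] = df[col].map(
                lambda v: f"{round_half_up(v):.2f}" if pd.notna(v) else ""
            )
    df.to_csv(path, sep="\t", index=False)
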