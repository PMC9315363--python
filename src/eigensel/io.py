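"""Genotype I/O and quality control.

Reads a multi-sample biallelic-SNP VCF plus a sample-metadata table into the
package's in-memory genotype model (a samples x variants dosage matrix), and
applies the marker QC used throughout: missingness, mapping to one of the 21
hexaploid wheat chromosomes, minor-allele frequency, and observed
heterozygosity. Variants are named ``chrom_pos`` (e.g. ``1A_555961328``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel

#: The 21 chromosomes of hexaploid bread wheat (AABBDD).
WHEAT_CHROMOSOMES = tuple(f"{i}{g}" for i in range(1, 8) for g in "ABD")

_CHROM_RE = re.compile(r"^[1-7][ABD]$")

#: Canonical sort rank: wheat chromosomes first in 1A..7D order, others after.
_CHROM_RANK = {c: i for i, c in enumerate(WHEAT_CHROMOSOMES)}

UNASSIGNED = "UNASSIGNED"


def genome_of(chrom: str) -> str:
    """Return the wheat subgenome label ("A", "B" or "D") of a chromosome.

    Any name not matching ``[1-7][ABD]`` (e.g. "Un", scaffolds) is
    ``"UNMAPPED"``.
    """
    if _CHROM_RE.match(chrom):
        return chrom[-1]
    return "UNMAPPED"


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_RANK.get(chrom, len(_CHROM_RANK)), chrom)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: chromosome, 1-based position, ref/alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise InputError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InputError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")

    @property
    def name(self) -> str:
        return f"{self.chrom}_{self.pos}"


VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "name"]


def variant_frame(records) -> pd.DataFrame:
    """Build the canonical variant table from VariantRecords or tuples."""
    rows = []
    for r in records:
        if isinstance(r, VariantRecord):
            rows.append((r.chrom, r.pos, r.ref, r.alt, r.name))
        else:
            chrom, pos, ref, alt = r
            rows.append((chrom, int(pos), ref, alt, f"{chrom}_{int(pos)}"))
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    return df


@dataclass
class GenotypeMatrix:
    """Samples x variants alt-allele dosage matrix with sample metadata.

    dosages take values 0/1/2 with ``MISSING`` (-1) for no-calls; variants are
    kept sorted by (chromosome, position); ``groups`` maps every sample to a
    subpopulation label (``UNASSIGNED`` permitted).
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    groups: pd.Series = field(default=None)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise InputError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.groups is None:
            self.groups = pd.Series(UNASSIGNED, index=self.samples)
        else:
            self.groups = pd.Series(self.groups).reindex(self.samples).fillna(UNASSIGNED)
        self.variants = self.variants.reset_index(drop=True)
        if "name" not in self.variants.columns:
            self.variants = self.variants.assign(
                name=[f"{c}_{p}" for c, p in zip(self.variants.chrom, self.variants.pos)]
            )
        if not self._is_sorted():
            logger.warning("variants not sorted by (chrom, pos); sorting")
            self._sort_variants()

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def _is_sorted(self) -> bool:
        ranks = [chrom_sort_key(c) for c in self.variants.chrom]
        keys = list(zip(ranks, self.variants.pos.tolist()))
        return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))

    def _sort_variants(self) -> None:
        order = sorted(
            range(self.n_variants),
            key=lambda i: (chrom_sort_key(self.variants.chrom.iloc[i]), self.variants.pos.iloc[i]),
        )
        self.variants = self.variants.iloc[order].reset_index(drop=True)
        self.dosages = self.dosages[:, order]

    # -- masks and frequencies ------------------------------------------

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls (samples x variants)."""
        return self.dosages != MISSING

    def n_called(self) -> np.ndarray:
        return self.called().sum(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Per-variant alt-allele frequency over non-missing calls (NaN if none)."""
        called = self.called()
        n = called.sum(axis=0)
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def het_fractions(self) -> np.ndarray:
        """Per-variant heterozygote fraction among non-missing calls."""
        called = self.called()
        n = called.sum(axis=0)
        het = (self.dosages == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, het / n, np.nan)

    # -- subsetting ------------------------------------------------------

    def take_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[index],
            dosages=self.dosages[:, index],
            groups=self.groups,
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=self.samples[index],
            variants=self.variants,
            dosages=self.dosages[index, :],
            groups=self.groups.iloc[index],
        )

    def subpopulation(self, label: str) -> "GenotypeMatrix":
        mask = (self.groups == label).to_numpy()
        if not mask.any():
            raise InputError(f"no samples in subpopulation {label!r}")
        return self.take_samples(mask)

    def subpopulations(self) -> list[str]:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_indices(self) -> dict[str, np.ndarray]:
        return {g: np.flatnonzero((self.groups == g).to_numpy()) for g in self.subpopulations()}


@dataclass
class QCReport:
    """Per-rule removal counts; each variant is attributed to the first
    failing rule in the order missingness -> unmapped -> MAF -> heterozygosity."""

    n_input: int
    removed_missing: int
    removed_unmapped: int
    removed_maf: int
    removed_het: int
    retained: int

    def __post_init__(self):
        removed = (
            self.removed_missing + self.removed_unmapped + self.removed_maf + self.removed_het
        )
        assert removed + self.retained == self.n_input, "QC bookkeeping must conserve variants"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["missingness", "unmapped", "maf", "heterozygosity", "retained"],
                "count": [
                    self.removed_missing,
                    self.removed_unmapped,
                    self.removed_maf,
                    self.removed_het,
                    self.retained,
                ],
            }
        )


def read_metadata(path) -> pd.Series:
    """Read a sample metadata TSV with columns ``sample_id`` and ``subpop``."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "subpop"):
        if col not in meta.columns:
            raise InputError(f"metadata {path} lacks required column {col!r}")
    return pd.Series(meta.subpop.values, index=meta.sample_id.values)


def read_vcf(path, metadata_path=None) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix.

    Only biallelic single-nucleotide records are kept (multiallelic sites and
    indels are dropped with a logged count). GT is converted to the alt-allele
    dosage; half-calls and non-diploid genotypes become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    if samples.size == 0:
        raise InputError(f"VCF {path} contains no samples")

    records, rows = [], []
    n_dropped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        dos = np.full(samples.size, MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue
            dos[i] = int(alleles[0] != 0) + int(alleles[1] != 0)
        records.append((var.CHROM, var.POS, var.REF, alts[0]))
        rows.append(dos)
    vcf.close()
    if n_dropped:
        logger.info("dropped %d multiallelic/indel records", n_dropped)
    if not records:
        raise InputError(f"VCF {path} contains no biallelic SNP records")

    variants = variant_frame(records)
    dosages = np.stack(rows, axis=1)

    groups = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        overlap = set(samples) & set(meta.index)
        if not overlap:
            raise InputError("no overlapping samples between VCF and metadata")
        groups = meta
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages, groups=groups)


def qc_filter(
    matrix: GenotypeMatrix,
    max_missing: float = 0.50,
    min_maf: float = 0.05,
    max_het: float = 0.20,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the marker QC filters and report per-rule removals.

    A variant is retained when its missing fraction is <= ``max_missing``, it
    maps to one of the 21 wheat chromosomes, its MAF strictly exceeds
    ``min_maf`` and its observed heterozygosity is strictly below ``max_het``
    (both computed on non-missing calls only). Removals are attributed to the
    first failing rule in that order.
    """
    for v, nm in ((max_missing, "max_missing"), (min_maf, "min_maf"), (max_het, "max_het")):
        if not 0.0 <= v <= 1.0:
            raise InputError(f"{nm} must be in [0, 1], got {v}")

    called = matrix.called()
    n = matrix.n_samples
    miss_frac = 1.0 - called.sum(axis=0) / n
    p = matrix.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    het = matrix.het_fractions()
    mapped = np.array([genome_of(c) != "UNMAPPED" for c in matrix.variants.chrom])

    fail_missing = miss_frac > max_missing
    fail_unmapped = ~mapped & ~fail_missing
    # NaN comparisons are False, so an all-missing variant falls to the
    # missingness rule (its missing fraction is 1) and never reaches MAF.
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf > min_maf) & ~fail_missing & ~fail_unmapped
        fail_het = ~(het < max_het) & ~fail_missing & ~fail_unmapped & ~fail_maf
    keep = ~(fail_missing | fail_unmapped | fail_maf | fail_het)

    report = QCReport(
        n_input=matrix.n_variants,
        removed_missing=int(fail_missing.sum()),
        removed_unmapped=int(fail_unmapped.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_het=int(fail_het.sum()),
        retained=int(keep.sum()),
    )
    if report.retained == 0:
        logger.warning("QC removed every variant")
    return matrix.take_variants(keep), report
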