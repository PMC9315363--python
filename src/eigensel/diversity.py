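"""Per-marker and grouped diversity statistics.

Minor allele frequency, observed heterozygosity, Nei gene diversity,
polymorphism information content (Botstein biallelic form), transition /
transversion accounting, and chromosome / genome / subpopulation summary
tables (marker counts, spans, densities, mean diversity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import GenotypeMatrix, chrom_sort_key, genome_of

logger = logging.getLogger(__name__)

TRANSITIONS = (("A", "G"), ("C", "T"))
TRANSVERSIONS = (("A", "T"), ("A", "C"), ("G", "T"), ("C", "G"))
SUBSTITUTION_CLASSES = TRANSITIONS + TRANSVERSIONS


def allele_frequency(column: np.ndarray) -> float:
    """Alt-allele frequency of one dosage column (missing = -1 excluded)."""
    column = np.asarray(column)
    called = column >= 0
    n = int(called.sum())
    if n == 0:
        logger.warning("allele_frequency: no non-missing calls")
        return float("nan")
    return float(column[called].sum() / (2.0 * n))


def gene_diversity(p):
    """Nei gene diversity (expected heterozygosity) 1 - p^2 - q^2 = 2pq."""
    p = np.asarray(p, dtype=float)
    return 1.0 - p**2 - (1.0 - p) ** 2


def pic(p):
    """Polymorphism information content, biallelic Botstein form.

    PIC = 1 - p^2 - q^2 - 2 p^2 q^2; maximal 0.375 at p = 0.5, and ~0.09 at
    the common 0.05 MAF filter floor.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2


def marker_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant statistics: p, MAF, observed het, GD, PIC, n_called."""
    p = matrix.allele_frequencies()
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {
                "name": matrix.variants.name,
                "chrom": matrix.variants.chrom,
                "pos": matrix.variants.pos,
                "p": p,
                "maf": np.minimum(p, 1.0 - p),
                "he_obs": matrix.het_fractions(),
                "gd": gene_diversity(p),
                "pic": pic(p),
                "n_called": matrix.n_called(),
            }
        )
    return out


def classify_substitution(ref: str, alt: str) -> str:
    """Map an unordered ref/alt pair to one of the six substitution classes.

    A/C and G/T are kept distinct (no strand-complement collapsing).
    """
    pair = tuple(sorted((ref, alt)))
    for a, b in SUBSTITUTION_CLASSES:
        if pair == tuple(sorted((a, b))):
            return f"{a}/{b}"
    raise InputError(f"cannot classify substitution {ref!r}/{alt!r}")


@dataclass
class SubstitutionSummary:
    """Counts and frequencies of the six substitution classes."""

    counts: dict  # class label -> count
    transitions: int
    transversions: int
    ts_tv_ratio: float  # NaN when no transversions

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    @property
    def transition_fraction(self) -> float:
        return self.transitions / self.total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": lab,
                "kind": "transition" if lab in ("A/G", "C/T") else "transversion",
                "count": c,
                "frequency": c / self.total,
            }
            for lab, c in self.counts.items()
        ]
        return pd.DataFrame(rows)


def substitution_summary(variants: pd.DataFrame) -> SubstitutionSummary:
    """Tally transition/transversion classes over a variant table."""
    if len(variants) == 0:
        raise InputError("substitution_summary requires at least one variant")
    labels = [f"{a}/{b}" for a, b in SUBSTITUTION_CLASSES]
    counts = dict.fromkeys(labels, 0)
    for ref, alt in zip(variants.ref, variants.alt):
        counts[classify_substitution(ref, alt)] += 1
    ts = counts["A/G"] + counts["C/T"]
    tv = sum(counts[lab] for lab in labels[2:])
    if tv == 0:
        logger.warning("no transversions observed; Ts/Tv ratio undefined")
        ratio = float("nan")
    else:
        ratio = ts / tv
    return SubstitutionSummary(counts=counts, transitions=ts, transversions=tv, ts_tv_ratio=ratio)


def _span_rows(stats: pd.DataFrame, total: int) -> dict:
    n = len(stats)
    start = int(stats.pos.min())
    end = int(stats.pos.max())
    length_mb = end / 1e6
    return {
        "n_markers": n,
        "pct_snps": 100.0 * n / total,
        "start_pos": start,
        "end_pos": end,
        "length_mb": length_mb,
        "density": n / length_mb,
        "mean_maf": stats.maf.mean(),
        "mean_he": stats.he_obs.mean(),
        "mean_gd": stats.gd.mean(),
        "mean_pic": stats.pic.mean(),
    }


def grouped_summary(matrix: GenotypeMatrix, by: str = "chromosome") -> pd.DataFrame:
    """Summary table per chromosome, per genome, or per subpopulation.

    Chromosome mode mirrors the standard marker-summary table: count, % of
    total, start/end positions, length (Mb) taken as the largest observed
    marker position / 1e6, density in markers per Mb, and mean diversity
    statistics. Genome rows and the whole-genome row aggregate member
    chromosomes; their length is the sum of chromosome lengths and their
    density the unweighted mean of per-chromosome densities.

    Subpopulation mode recomputes the diversity statistics from subgroup
    allele frequencies (so subgroup MAF may fall below any panel-wide
    filter floor).
    """
    if matrix.n_variants == 0:
        raise InputError("grouped_summary requires a non-empty matrix")

    if by == "subpopulation":
        rows = []
        for label in matrix.subpopulations():
            sub = matrix.subpopulation(label)
            stats = marker_stats(sub)
            rows.append(
                {
                    "subpopulation": label,
                    "n_samples": sub.n_samples,
                    "n_markers": sub.n_variants,
                    "mean_maf": stats.maf.mean(),
                    "mean_he": stats.he_obs.mean(),
                    "mean_gd": stats.gd.mean(),
                    "mean_pic": stats.pic.mean(),
                }
            )
        return pd.DataFrame(rows)

    if by not in ("chromosome", "genome"):
        raise InputError(f"unknown grouping {by!r}")

    stats = marker_stats(matrix)
    total = len(stats)
    chrom_rows = {}
    for chrom, sub in stats.groupby("chrom", sort=False):
        chrom_rows[chrom] = _span_rows(sub, total)
    order = sorted(chrom_rows, key=chrom_sort_key)
    per_chrom = pd.DataFrame(
        [{"group": c, **chrom_rows[c]} for c in order]
    )
    if by == "chromosome":
        return per_chrom

    rows = []
    for g in ("A", "B", "D"):
        member = per_chrom[[genome_of(c) == g for c in per_chrom.group]]
        if member.empty:
            logger.warning("genome %s has no markers; omitted", g)
            continue
        rows.append(_aggregate(member, g))
    rows.append(_aggregate(per_chrom, "whole_genome"))
    return pd.DataFrame(rows)


def _aggregate(per_chrom: pd.DataFrame, label: str) -> dict:
    n = int(per_chrom.n_markers.sum())
    weights = per_chrom.n_markers / n
    return {
        "group": label,
        "n_markers": n,
        "pct_snps": float(per_chrom.pct_snps.sum()),
        "start_pos": int(per_chrom.start_pos.min()),
        "end_pos": int(per_chrom.end_pos.max()),
        "length_mb": float(per_chrom.length_mb.sum()),
        "density": float(per_chrom.density.mean()),
        "mean_maf": float((per_chrom.mean_maf * weights).sum()),
        "mean_he": float((per_chrom.mean_he * weights).sum()),
        "mean_gd": float((per_chrom.mean_gd * weights).sum()),
        "mean_pic": float((per_chrom.mean_pic * weights).sum()),
    }


def frequency_histogram(values, bins) -> pd.DataFrame:
    """Bin a statistic into a replotting-ready histogram table."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    counts, edges = np.histogram(values, bins=bins)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
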