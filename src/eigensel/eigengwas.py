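"""EigenGWAS selection-signature scan.

Each GRM eigenvector (EV) is treated as a phenotype and regressed on every
SNP dosage by ordinary least squares; the per-SNP Wald statistic
chi = (beta / se)^2 is referred to chi-square with 1 df. Because genetic
drift alone inflates these statistics, p-values are deflated with the
genomic-control factor lambda_GC = median(chi) / median(chi^2_1), giving
P_GC. Loci passing a -log10(P_GC) cutoff (default 5.0, optionally a
permutation-derived threshold) are merged into selection regions by joining
SNPs whose +/- 5 Mb windows overlap; each region is represented by its most
significant SNP, annotated with that SNP's per-SNP F_ST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import InputError, ParameterError
from .io import MISSING, GenotypeMatrix, chrom_sort_key
from .relatedness import PCAResult, RelationshipMatrix

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))


def _ols_scan(X: np.ndarray, called: np.ndarray, y: np.ndarray):
    """Vectorized per-SNP simple OLS of y on each dosage column.

    Complete-case per SNP. Returns (beta, se, chi) with NaN where the SNP
    has zero variance on its called samples or fewer than 3 calls.
    """
    Xf = np.where(called, X, 0.0)
    M = called.astype(float)
    yv = y[:, None]
    n = M.sum(axis=0)
    sx = Xf.sum(axis=0)
    sy = (yv * M).sum(axis=0)
    sxx = (Xf**2).sum(axis=0)
    sxy = (Xf * yv).sum(axis=0)
    syy = ((yv**2) * M).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vxx = sxx - sx**2 / n
        vyy = syy - sy**2 / n
        vxy = sxy - sx * sy / n
        beta = vxy / vxx
        rss = np.maximum(vyy - beta * vxy, 0.0)  # guard float cancellation
        sigma2 = rss / (n - 2.0)
        se = np.sqrt(sigma2 / vxx)
        chi_stat = (beta / se) ** 2
    bad = (n < 3) | ~(vxx > 0)
    for arr in (beta, se, chi_stat):
        arr[bad] = np.nan
    return beta, se, chi_stat


def eigengwas_scan(
    matrix: GenotypeMatrix,
    pca_result: PCAResult,
    k_list=None,
    apply_gc: bool = True,
) -> pd.DataFrame:
    """Scan every SNP against the requested eigenvectors.

    Returns one row per SNP per EV with beta, se, chi, p_raw and (if
    ``apply_gc``) the within-EV lambda_GC-adjusted p_gc and its -log10.
    SNPs with zero dosage variance are skipped with a log entry.
    """
    if list(pca_result.samples) != list(matrix.samples):
        raise InputError("eigenvectors were computed for a different sample set")
    n_ev = pca_result.eigenvectors.shape[1]
    if k_list is None:
        k_list = list(range(1, n_ev + 1))
    if any(k < 1 or k > n_ev for k in k_list):
        raise ParameterError(f"requested EVs {k_list} outside available 1..{n_ev}")

    X = matrix.dosages.astype(float)
    called = matrix.dosages != MISSING
    frames = []
    for k in k_list:
        y = pca_result.eigenvectors[:, k - 1]
        beta, se, chi_stat = _ols_scan(X, called, y)
        n_skip = int(np.isnan(chi_stat).sum())
        if n_skip:
            logger.info("EV%d: skipped %d zero-variance/undersized SNPs", k, n_skip)
        p_raw = chi2.sf(chi_stat, df=1)
        df = pd.DataFrame(
            {
                "name": matrix.variants.name,
                "chrom": matrix.variants.chrom,
                "pos": matrix.variants.pos,
                "ev": k,
                "beta": beta,
                "se": se,
                "chi": chi_stat,
                "p_raw": p_raw,
            }
        )
        if apply_gc:
            lam = lambda_gc(chi_stat)
            if lam <= 0:
                logger.warning("EV%d: degenerate lambda_GC %.3g; p_gc left unadjusted", k, lam)
                lam = 1.0
            df["lambda_gc"] = lam
            df["p_gc"] = adjust_p(chi_stat, lam)
            with np.errstate(divide="ignore"):
                df["minus_log10_p_gc"] = -np.log10(df["p_gc"])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def lambda_gc(chi_values) -> float:
    """Genomic-control inflation factor: median(chi) / 0.4549364."""
    chi_values = np.asarray(chi_values, dtype=float)
    finite = chi_values[np.isfinite(chi_values)]
    if finite.size == 0:
        raise InputError("lambda_gc requires at least one finite chi-square value")
    return float(np.median(finite) / CHI2_1_MEDIAN)


def adjust_p(chi_values, lam: float):
    """Genomic-control adjusted p: upper tail of chi^2_1 at chi / lambda."""
    if not lam > 0:
        raise ParameterError("lambda_GC must be positive")
    return chi2.sf(np.asarray(chi_values, dtype=float) / lam, df=1)


def permutation_threshold(
    matrix: GenotypeMatrix,
    pca_result: PCAResult,
    ev: int = 1,
    n_perm: int = 1000,
    quantile: float = 0.95,
    rng=None,
) -> float:
    """Permutation -log10(P_GC) threshold for one eigenvector.

    The EV is reshuffled across samples ``n_perm`` times; each permutation
    reruns the scan, recomputes lambda_GC within the permutation and records
    the most significant P_GC. The threshold is -log10 of the
    (1 - quantile) quantile of those minima — i.e. the P_GC that only
    (1 - quantile) of null genomes beat.
    """
    if n_perm < 100:
        raise ParameterError("use at least 100 permutations")
    rng = np.random.default_rng(rng)
    y = pca_result.eigenvectors[:, ev - 1]
    X = matrix.dosages.astype(float)
    called = matrix.dosages != MISSING
    minima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        _, _, chi_stat = _ols_scan(X, called, yp)
        lam = lambda_gc(chi_stat)
        p_gc = adjust_p(chi_stat, lam)
        minima[b] = np.nanmin(p_gc)
    return float(-np.log10(np.quantile(minima, 1.0 - quantile)))


def select_significant(records: pd.DataFrame, minus_log10_cutoff: float = 5.0) -> pd.DataFrame:
    """Records with -log10(P_GC) at or above the cutoff."""
    return records[records.minus_log10_p_gc >= minus_log10_cutoff].reset_index(drop=True)


@dataclass
class SelectionRegion:
    chrom: str
    start_mb: float
    end_mb: float
    top_snp: str
    ev: int
    minus_log10_p_gc: float
    fst: float
    n_snps: int


def merge_regions(
    significant: pd.DataFrame,
    flank_bp: int = 5_000_000,
    per_snp_fst: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge significant SNPs into selection regions per EV and chromosome.

    SNPs whose +/- ``flank_bp`` windows overlap are merged transitively; a
    region spans [min pos - flank (floored at 0), max pos + flank], reported
    in Mb to two decimals. The representative SNP is the one with the
    largest -log10(P_GC) (ties: smaller position); its per-SNP F_ST is
    attached when a per-SNP table (columns name, theta) is supplied.
    Regions from different EVs are kept separate.
    """
    fst_map = {}
    if per_snp_fst is not None:
        fst_map = dict(zip(per_snp_fst.name, per_snp_fst.theta))

    rows = []
    for (ev, chrom), sub in significant.groupby(["ev", "chrom"], sort=False):
        sub = sub.sort_values("pos")
        pos = sub.pos.to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > 2 * flank_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            block = sub.iloc[s : e + 1]
            best = block.sort_values(
                ["minus_log10_p_gc", "pos"], ascending=[False, True]
            ).iloc[0]
            start_mb = max(0.0, (block.pos.min() - flank_bp) / 1e6)
            end_mb = (block.pos.max() + flank_bp) / 1e6
            rows.append(
                {
                    "top_snp": best["name"],
                    "ev": int(ev),
                    "chrom": chrom,
                    "start_mb": round(start_mb, 2),
                    "end_mb": round(end_mb, 2),
                    "minus_log10_p_gc": float(best.minus_log10_p_gc),
                    "fst": fst_map.get(best["name"], float("nan")),
                    "n_snps": len(block),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "top_snp", "ev", "chrom", "start_mb", "end_mb",
            "minus_log10_p_gc", "fst", "n_snps",
        ],
    )
    if out.empty:
        return out
    return out.sort_values(
        ["ev", "chrom", "start_mb"],
        key=lambda s: s.map(lambda c: chrom_sort_key(c)[0]) if s.name == "chrom" else s,
    ).reset_index(drop=True)


def count_unique_regions(regions: pd.DataFrame) -> int:
    """Panel-level region count with cross-EV overlaps collapsed.

    Regions on the same chromosome whose spans overlap (regardless of EV)
    are counted once.
    """
    if regions.empty:
        return 0
    count = 0
    for chrom, sub in regions.groupby("chrom"):
        ivals = sub.sort_values("start_mb")[["start_mb", "end_mb"]].to_numpy()
        cur_end = -np.inf
        for start, end in ivals:
            if start > cur_end:
                count += 1
                cur_end = end
            else:
                cur_end = max(cur_end, end)
    return count


def effective_stats(grm: RelationshipMatrix) -> dict:
    """Panel-level GRM diagnostics.

    Mean off-diagonal relatedness g; the effective sample size n_e = -1/g
    (NaN-flagged when g >= 0), and the effective number of independent
    genome segments m_e = 1 / var(off-diagonal).
    """
    n = grm.values.shape[0]
    if n < 3:
        raise InputError("effective_stats requires at least 3 samples")
    off = grm.off_diagonal()
    g = float(off.mean())
    if g >= 0:
        logger.warning("mean off-diagonal relatedness %.3g >= 0; n_e undefined", g)
        n_e = float("nan")
    else:
        n_e = -1.0 / g
    var = float(off.var())
    m_e = 1.0 / var if var > 0 else float("nan")
    return {"mean_relatedness": g, "n_e": n_e, "m_e": m_e}


def scan_diagnostics(
    pca_result: PCAResult, records: pd.DataFrame, grm: RelationshipMatrix
) -> pd.DataFrame:
    """Per-EV eigenvalue and lambda_GC table (panel stats in attrs)."""
    rows = []
    for k, sub in records.groupby("ev"):
        rows.append(
            {
                "ev": int(k),
                "eigenvalue": float(pca_result.eigenvalues[int(k) - 1]),
                "lambda_gc": float(sub.lambda_gc.iloc[0]),
            }
        )
    out = pd.DataFrame(rows).sort_values("ev").reset_index(drop=True)
    out.attrs.update(effective_stats(grm))
    return out
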