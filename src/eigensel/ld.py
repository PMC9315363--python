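"""Linkage-disequilibrium estimation and decay fitting.

Pairwise LD is the squared Pearson correlation of genotype dosages
(composite r^2, no phasing). The decay of expected r^2 with physical
distance d is fitted with the Hill–Weir drift-sampling expectation in
Remington's parameterization, with C = beta * d:

    E[r^2] = (10 + C) / ((2 + C)(11 + C))
             * [1 + (3 + C)(12 + 12C + C^2) / (n (2 + C)(11 + C))]

The decay distance at a threshold (default r^2 = 0.1) is found by bisection
on the fitted (monotone decreasing) curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InputError, ParameterError
from .io import MISSING, GenotypeMatrix, chrom_sort_key

logger = logging.getLogger(__name__)


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over the samples
    called in both; NaN when fewer than two shared calls or either SNP is
    monomorphic on the shared samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _chrom_r2_matrix(D: np.ndarray) -> np.ndarray:
    """All-pairs r^2 for the dosage columns of one chromosome, complete-case
    per pair, via masked cross-product algebra."""
    M = (D != MISSING).astype(float)
    X = np.where(D == MISSING, 0, D).astype(float)
    n = M.T @ M
    sx = X.T @ M
    sy = sx.T
    sxy = X.T @ X
    sxx = (X**2).T @ M
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        r2 = cov**2 / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def ld_scan(
    matrix: GenotypeMatrix,
    max_distance_bp: int = 50_000_000,
    group: str | None = None,
) -> pd.DataFrame:
    """All intra-chromosomal SNP pairs within ``max_distance_bp``.

    Returns (chrom, pos1, pos2, dist_bp, r2) ordered by (chrom, pos1, pos2);
    pairs with undefined r^2 are dropped.
    """
    if max_distance_bp <= 0:
        raise ParameterError("max_distance_bp must be positive")
    panel = matrix if group is None else matrix.subpopulation(group)
    chrom_arr = panel.variants.chrom.to_numpy()
    pos_arr = panel.variants.pos.to_numpy()
    frames = []
    for chrom in sorted(set(chrom_arr), key=chrom_sort_key):
        idx = np.flatnonzero(chrom_arr == chrom)
        if idx.size < 2:
            continue
        pos = pos_arr[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        r2 = _chrom_r2_matrix(panel.dosages[:, idx])
        ii, jj = np.triu_indices(idx.size, k=1)
        dist = pos[jj] - pos[ii]
        keep = (dist <= max_distance_bp) & (dist > 0) & ~np.isnan(r2[ii, jj])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos1": pos[ii[keep]],
                    "pos2": pos[jj[keep]],
                    "dist_bp": dist[keep],
                    "r2": r2[ii[keep], jj[keep]],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos1", "pos2", "dist_bp", "r2"])
    # frames were built in canonical chromosome order, pairs sorted within
    return pd.concat(frames, ignore_index=True)


def expected_r2(d, beta: float, n: int):
    """Hill–Weir expected r^2 at distance d for sample size n."""
    C = beta * np.asarray(d, dtype=float)
    lead = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    corr = 1.0 + (3.0 + C) * (12.0 + 12.0 * C + C**2) / (n * (2.0 + C) * (11.0 + C))
    return lead * corr


@dataclass
class LDDecayFit:
    """Fitted Hill–Weir decay: per-bp coefficient beta, the sample size used,
    and the distance at which the fitted curve crosses the r^2 threshold
    (None when the curve never reaches it over 10x the observed range)."""

    beta: float
    n_samples: int
    threshold: float
    decay_bp: float | None
    n_pairs: int

    @property
    def decay_mb(self) -> float | None:
        return None if self.decay_bp is None else self.decay_bp / 1e6


def fit_ld_decay(
    pairs: pd.DataFrame, n_samples: int, threshold: float = 0.1
) -> LDDecayFit:
    """Nonlinear least-squares fit of expected r^2 against distance.

    Initial beta puts C = 1 at the median pair distance. Requires >= 50
    pairs and n_samples >= 4.
    """
    if len(pairs) < 50:
        raise InputError(f"need >= 50 LD pairs to fit decay, got {len(pairs)}")
    if n_samples < 4:
        raise InputError("need n_samples >= 4")
    d = pairs.dist_bp.to_numpy(dtype=float)
    r2 = pairs.r2.to_numpy(dtype=float)
    beta0 = 1.0 / np.median(d)
    try:
        popt, _ = curve_fit(
            lambda dd, beta: expected_r2(dd, beta, n_samples),
            d,
            r2,
            p0=[beta0],
            bounds=(1e-300, np.inf),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"LD decay fit did not converge (beta0={beta0:.3g}): {exc}") from exc
    beta = float(popt[0])

    lo, hi = 1.0, float(d.max()) * 10.0
    f = lambda x: expected_r2(x, beta, n_samples) - threshold
    if f(lo) < 0 or f(hi) > 0:
        logger.info("fitted LD curve does not cross r^2=%.3g over the range", threshold)
        decay = None
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        decay = 0.5 * (lo + hi)
    return LDDecayFit(
        beta=beta,
        n_samples=n_samples,
        threshold=threshold,
        decay_bp=decay,
        n_pairs=len(pairs),
    )
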