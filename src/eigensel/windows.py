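"""Sliding-window nucleotide diversity and Tajima's D.

Windows tile each chromosome from position 1 to its last SNP (default 1 Mb
windows, 100 kb step). Per-window nucleotide diversity is the sum of
per-site pairwise diversity divided by the full window length in bp (the
VCFtools ``--window-pi`` convention), so sparse marker panels yield values
on the 1e-7..1e-6 per-bp scale. Tajima's D standardizes the difference
between that pairwise diversity (count scale) and Watterson's estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import GenotypeMatrix, chrom_sort_key


def site_pi(column: np.ndarray) -> float:
    """Per-site nucleotide diversity of one dosage column.

    With n = 2 * (non-missing calls) haplotypes and j alt alleles,
    pi = 2 j (n - j) / (n (n - 1)); undefined (NaN) below 2 diploid calls.
    """
    column = np.asarray(column)
    called = column >= 0
    n = 2 * int(called.sum())
    if n < 4:
        return float("nan")
    j = int(column[called].sum())
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def site_pi_array(matrix: GenotypeMatrix) -> np.ndarray:
    """Vectorized per-variant site pi (NaN below 2 diploid calls)."""
    called = matrix.called()
    n = 2.0 * called.sum(axis=0)
    j = np.where(called, matrix.dosages, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 4, pi, np.nan)


def _harmonic_sums(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, n_max, dtype=float)
    return np.concatenate([[0.0], np.cumsum(1.0 / i)]), np.concatenate(
        [[0.0], np.cumsum(1.0 / i**2)]
    )


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants for a sample of n haplotypes."""
    if n < 4:
        raise ParameterError("Tajima's D requires at least 4 haplotypes")
    i = np.arange(1, n, dtype=float)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(pi_sum: float, n_segregating: int, n_haplotypes: int) -> float:
    """Tajima's D from the summed site pi (count scale), the number of
    segregating sites and the haplotype sample size; NaN when S = 0 or the
    variance term is non-positive."""
    if n_segregating < 1:
        return float("nan")
    k = tajima_constants(n_haplotypes)
    s = float(n_segregating)
    var = k["e1"] * s + k["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (pi_sum - s / k["a1"]) / np.sqrt(var)


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    subpop: str
    n_snps: int
    pi: float
    tajima_d: float


def _window_table(
    pos: np.ndarray,
    pis: np.ndarray,
    n_called: np.ndarray,
    segregating: np.ndarray,
    window: int,
    step: int,
) -> list[tuple[int, int, int, float, float]]:
    """Window scan on one chromosome via cumulative sums.

    Returns (start, end, n_snps, pi_per_bp, tajima_d) tuples; Tajima's D uses
    n = 2 * round(mean non-missing diploid calls over window SNPs).
    """
    max_pos = int(pos.max())
    starts = np.arange(1, max_pos + 1, step, dtype=np.int64)
    ends = starts + window - 1

    order = np.argsort(pos, kind="stable")
    pos, pis, n_called, segregating = pos[order], pis[order], n_called[order], segregating[order]
    pis_f = np.nan_to_num(pis, nan=0.0)

    cum_pi = np.concatenate([[0.0], np.cumsum(pis_f)])
    cum_n = np.concatenate([[0.0], np.cumsum(n_called.astype(float))])
    cum_s = np.concatenate([[0], np.cumsum(segregating.astype(np.int64))])
    cum_cnt = np.arange(len(pos) + 1)

    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")

    n_snps = (cum_cnt[hi] - cum_cnt[lo]).astype(int)
    pi_sum = cum_pi[hi] - cum_pi[lo]
    s_win = (cum_s[hi] - cum_s[lo]).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_called = np.where(n_snps > 0, (cum_n[hi] - cum_n[lo]) / np.maximum(n_snps, 1), 0.0)
    n_hap = 2 * np.round(mean_called).astype(int)

    rows = []
    for k in range(len(starts)):
        if s_win[k] >= 1 and n_hap[k] >= 4:
            d = tajimas_d(pi_sum[k], s_win[k], n_hap[k])
        else:
            d = float("nan")
        rows.append((int(starts[k]), int(ends[k]), int(n_snps[k]), pi_sum[k] / window, d))
    return rows


def windowed_pi(
    matrix: GenotypeMatrix,
    window: int = 1_000_000,
    step: int = 100_000,
    by_subpop: bool = False,
) -> pd.DataFrame:
    """Sliding-window pi and Tajima's D, whole panel and optionally per
    subpopulation.

    Every window has the full nominal length (the trailing windows extend
    past the last SNP); empty windows report pi = 0 and undefined Tajima's D.
    """
    if not (window >= step > 0):
        raise ParameterError("need window >= step > 0")

    panels = [("WP", matrix)]
    if by_subpop:
        panels += [(label, matrix.subpopulation(label)) for label in matrix.subpopulations()]

    out = []
    for label, panel in panels:
        pis = site_pi_array(panel)
        n_called = panel.n_called()
        freqs = panel.allele_frequencies()
        with np.errstate(invalid="ignore"):
            segregating = (freqs > 0) & (freqs < 1)
        chrom_arr = panel.variants.chrom.to_numpy()
        pos_arr = panel.variants.pos.to_numpy()
        for chrom in sorted(set(chrom_arr), key=chrom_sort_key):
            mask = chrom_arr == chrom
            for start, end, n_snps, pi, d in _window_table(
                pos_arr[mask], pis[mask], n_called[mask], segregating[mask], window, step
            ):
                out.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "subpop": label,
                        "n_snps": n_snps,
                        "pi": pi,
                        "tajima_d": d,
                    }
                )
    return pd.DataFrame(out)
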