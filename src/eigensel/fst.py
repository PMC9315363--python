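"""Genetic differentiation: Weir–Cockerham F_ST and three-level AMOVA.

Per-SNP variance components (a, b, c) follow the Weir & Cockerham (1984)
moment estimator with the observed-heterozygosity term; multi-locus and
pairwise F_ST use the ratio-of-sums form sum(a) / sum(a+b+c). AMOVA
decomposes allele-level squared distances into among-subpopulation,
among-individual-within and within-individual components with permutation
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import MISSING, GenotypeMatrix

__all__ = [
    "wc_variance_components",
    "wc_fst_per_snp",
    "pairwise_fst",
    "pairwise_fst_matrix",
    "amova",
    "AMOVAResult",
]


def _group_summaries(matrix: GenotypeMatrix, group_idx: dict[str, np.ndarray]):
    """Per group x SNP: called counts, alt frequencies, het fractions."""
    D = matrix.dosages
    ns, ps, hs = [], [], []
    for idx in group_idx.values():
        sub = D[idx, :]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, sub, 0).sum(axis=0)
        het = (sub == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ps.append(np.where(n > 0, alt / (2.0 * n), np.nan))
            hs.append(np.where(n > 0, het / n, np.nan))
        ns.append(n)
    return np.stack(ns), np.stack(ps), np.stack(hs)


def wc_variance_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) per-SNP components from per-group summaries.

    ``n``, ``p``, ``h`` are (groups x SNPs) arrays of called sample counts,
    allele frequencies and heterozygote fractions. SNPs lacking >= 2 groups
    with >= 2 called individuals yield NaN components.
    """
    valid = (n >= 2) & ~np.isnan(p)
    r = valid.sum(axis=0).astype(float)
    usable = r >= 2

    nv = np.where(valid, n, 0.0)
    pv = np.where(valid, p, 0.0)
    hv = np.where(valid, h, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = nv.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (nv**2).sum(axis=0) / n_tot) / (r - 1.0)
        pbar = (nv * pv).sum(axis=0) / n_tot
        s2 = (nv * (pv - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (nv * hv).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0

    bad = ~usable
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst_per_snp(matrix: GenotypeMatrix, groups: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP W&C variance components and theta = a / (a + b + c).

    SNPs monomorphic across all usable groups have an undefined theta
    (a + b + c = 0), emitted as NaN rather than zero; negative estimates are
    reported raw.
    """
    group_idx = matrix.group_indices()
    if groups is not None:
        group_idx = {g: group_idx[g] for g in groups}
    if len(group_idx) < 2:
        raise InputError("per-SNP F_ST requires at least two groups")
    n, p, h = _group_summaries(matrix, group_idx)
    a, b, c = wc_variance_components(n, p, h)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame(
        {
            "name": matrix.variants.name,
            "chrom": matrix.variants.chrom,
            "pos": matrix.variants.pos,
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )


def _multilocus_theta(n, p, h) -> float:
    a, b, c = wc_variance_components(n, p, h)
    denom = a + b + c
    ok = ~np.isnan(denom)
    total = np.nansum(denom[ok])
    if total == 0:
        return float("nan")
    return float(np.nansum(a[ok]) / total)


def pairwise_fst(
    matrix: GenotypeMatrix,
    group_a: str,
    group_b: str,
    n_perm: int = 0,
    rng=None,
) -> tuple[float, float]:
    """Multi-locus W&C F_ST between two subpopulations (ratio of sums).

    With ``n_perm`` > 0, a permutation p-value is computed by shuffling the
    two groups' sample labels; p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    idx = matrix.group_indices()
    for g in (group_a, group_b):
        if g not in idx:
            raise InputError(f"unknown subpopulation {g!r}")
    ia, ib = idx[group_a], idx[group_b]
    n, p, h = _group_summaries(matrix, {group_a: ia, group_b: ib})
    theta = _multilocus_theta(n, p, h)
    if n_perm <= 0:
        return theta, float("nan")

    rng = np.random.default_rng(rng)
    pool = np.concatenate([ia, ib])
    na = len(ia)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        n_, p_, h_ = _group_summaries(matrix, {"a": perm[:na], "b": perm[na:]})
        if _multilocus_theta(n_, p_, h_) >= theta:
            count += 1
    return theta, (1.0 + count) / (1.0 + n_perm)


def pairwise_fst_matrix(matrix: GenotypeMatrix, n_perm: int = 0, rng=None) -> pd.DataFrame:
    """All pairwise F_ST values (long format: group_a, group_b, fst, p)."""
    labels = matrix.subpopulations()
    rng = np.random.default_rng(rng)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            fst, pval = pairwise_fst(matrix, labels[i], labels[j], n_perm=n_perm, rng=rng)
            rows.append({"group_a": labels[i], "group_b": labels[j], "fst": fst, "p": pval})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# AMOVA
# --------------------------------------------------------------------------


@dataclass
class AMOVAResult:
    """Three-level AMOVA table: among subpopulations (Va), among individuals
    within subpopulations (Vb), within individuals (Vc)."""

    table: pd.DataFrame  # source, df, ss, variance, pct_variation, p

    @property
    def df(self) -> tuple[int, int, int]:
        return tuple(int(x) for x in self.table.df.iloc[:3])


def _amova_ss(dosages: np.ndarray, group_idx: dict[str, np.ndarray]):
    """Sums of squares from per-locus allele counts.

    For biallelic loci, the squared Euclidean distance between allele
    indicator vectors equals the number of differing loci, so all pairwise
    distance sums reduce to per-locus count algebra:
    within a set of C alleles with x alt, sum over pairs of d^2 is x(C - x).
    """
    called = dosages != MISSING
    # total level
    C = 2.0 * called.sum(axis=0)
    x = np.where(called, dosages, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_total = float(np.nansum(np.where(C > 0, x * (C - x) / C, 0.0)))
    # within populations
    ss_wp = 0.0
    for idx in group_idx.values():
        sub = dosages[idx, :]
        sc = sub != MISSING
        Cp = 2.0 * sc.sum(axis=0)
        xp = np.where(sc, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ss_wp += float(np.nansum(np.where(Cp > 0, xp * (Cp - xp) / Cp, 0.0)))
    # within individuals: each heterozygous call contributes 1/2
    ss_wi = float((dosages == 1).sum()) / 2.0
    return ss_total, ss_wp, ss_wi


def _amova_components(dosages, group_idx):
    G = len(group_idx)
    sizes = np.array([len(idx) for idx in group_idx.values()], dtype=float)
    N = int(sizes.sum())
    ss_total, ss_wp, ss_wi = _amova_ss(dosages, group_idx)
    ss_ap = ss_total - ss_wp
    ss_ai = ss_wp - ss_wi

    df_ap, df_ai, df_wi = G - 1, N - G, N
    ms_ap, ms_ai, ms_wi = ss_ap / df_ap, ss_ai / df_ai, ss_wi / df_wi

    c_p = 2.0 * sizes  # allele counts per subpopulation
    C = c_p.sum()
    n_prime = (C - (c_p**2).sum() / C) / (G - 1.0)

    vc = ms_wi
    vb = (ms_ai - vc) / 2.0
    va = (ms_ap - ms_ai) / n_prime
    return (df_ap, df_ai, df_wi), (ss_ap, ss_ai, ss_wi), (va, vb, vc)


def amova(matrix: GenotypeMatrix, n_perm: int = 1000, rng=None) -> AMOVAResult:
    """Excoffier-style AMOVA on allele-level squared distances.

    Degrees of freedom are (G-1, N-G, N): each diploid individual
    contributes two allele vectors, so the within-individual stratum has one
    df per individual. Permutation p-values: Va by shuffling individuals
    among subpopulations; Vb and Vc by shuffling pseudo-haplotype vectors
    among individuals within each subpopulation.
    """
    group_idx = matrix.group_indices()
    if len(group_idx) < 2:
        raise InputError("AMOVA requires at least two subpopulations")
    if n_perm and n_perm < 99:
        raise InputError("use at least 99 permutations (or 0 to skip)")
    D = matrix.dosages
    (df3, ss3, comps) = _amova_components(D, group_idx)
    va, vb, vc = comps
    total = va + vb + vc
    if total == 0:
        pct = (0.0, 0.0, 0.0)
    else:
        pct = tuple(100.0 * v / total for v in comps)

    p_va = p_vb = p_vc = float("nan")
    if n_perm:
        rng = np.random.default_rng(rng)
        labels = list(group_idx)
        sizes = [len(group_idx[g]) for g in labels]
        all_idx = np.concatenate([group_idx[g] for g in labels])
        cva = cvb = cvc = 0

        # pseudo-haplotype split: per het call, one haplotype carries the alt
        hap1 = np.where(D == MISSING, -1, (D >= 1).astype(np.int8))
        hap2 = np.where(D == MISSING, -1, (D == 2).astype(np.int8))
        swap = rng.random(D.shape) < 0.5
        h1 = np.where(swap, hap2, hap1)
        h2 = np.where(swap, hap1, hap2)

        for _ in range(n_perm):
            # Va: permute individuals among groups
            perm = rng.permutation(all_idx)
            gi, start = {}, 0
            for g, s in zip(labels, sizes):
                gi[g] = perm[start : start + s]
                start += s
            _, _, (va_p, _, _) = _amova_components(D, gi)
            if va_p >= va:
                cva += 1

            # Vb/Vc: permute haplotype vectors among individuals within groups
            Dp = np.empty_like(D)
            for g in labels:
                idx = group_idx[g]
                stack = np.concatenate([h1[idx], h2[idx]])  # (2n_g, m)
                order = rng.permutation(stack.shape[0])
                stack = stack[order]
                ng = len(idx)
                a_, b_ = stack[:ng], stack[ng:]
                miss = (a_ == -1) | (b_ == -1)
                Dp[idx] = np.where(miss, MISSING, a_ + b_)
            _, _, (_, vb_p, vc_p) = _amova_components(Dp, group_idx)
            if vb_p >= vb:
                cvb += 1
            if vc_p >= vc:
                cvc += 1
        p_va = (1.0 + cva) / (1.0 + n_perm)
        p_vb = (1.0 + cvb) / (1.0 + n_perm)
        p_vc = (1.0 + cvc) / (1.0 + n_perm)

    table = pd.DataFrame(
        {
            "source": [
                "Among subpopulations",
                "Among individuals within subpopulations",
                "Within individuals",
                "Total",
            ],
            "df": [df3[0], df3[1], df3[2], sum(df3)],
            "ss": [ss3[0], ss3[1], ss3[2], sum(ss3)],
            "variance": [va, vb, vc, total],
            "pct_variation": [pct[0], pct[1], pct[2], 100.0 if total else 0.0],
            "p": [p_va, p_vb, p_vc, float("nan")],
        }
    )
    return AMOVAResult(table=table)
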