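"""Relatedness and population-structure machinery.

VanRaden kinship, the standardized genomic relationship matrix (GRM) that
feeds both PCA and the eigenvector-regression selection scan, Rogers'
genetic distance between individuals, and a Saitou–Nei neighbor-joining
tree builder with Newick output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .errors import InputError
from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Square symmetric matrix over samples (kinship, GRM or distance)."""

    samples: np.ndarray
    values: np.ndarray
    flavor: str  # vanraden_kinship | standardized_grm | rogers_distance

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise InputError("relationship matrix shape must match sample count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)

    def off_diagonal(self) -> np.ndarray:
        n = self.values.shape[0]
        return self.values[~np.eye(n, dtype=bool)]


def _centered_dosages(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dosages with missing imputed to 2p, centered by 2p; returns (Z, p)."""
    p = matrix.allele_frequencies()
    if np.isnan(p).any():
        raise InputError("variants with no called genotypes; run QC first")
    X = matrix.dosages.astype(float)
    X[matrix.dosages == MISSING] = np.nan
    X = np.where(np.isnan(X), 2.0 * p, X)
    return X - 2.0 * p, p


def vanraden_kinship(matrix: GenotypeMatrix, clamp_negative: bool = True) -> RelationshipMatrix:
    """VanRaden (method 1) kinship: K = ZZ' / (2 sum p(1-p)).

    Missing dosages contribute their frequency expectation (zero after
    centering). Negative entries — pairs less related than random — are set
    to zero in the reported matrix; the GRM used for eigen-decomposition is
    computed separately and never clamped.
    """
    if matrix.n_samples < 2:
        raise InputError("kinship requires at least 2 samples")
    Z, p = _centered_dosages(matrix)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom == 0:
        raise InputError("all variants monomorphic; kinship denominator is zero")
    K = (Z @ Z.T) / denom
    if clamp_negative:
        n_neg = int((K < 0).sum())
        if n_neg:
            logger.info("clamped %d negative kinship entries to zero", n_neg)
        K = np.maximum(K, 0.0)
    return RelationshipMatrix(samples=matrix.samples, values=K, flavor="vanraden_kinship")


def standardized_grm(matrix: GenotypeMatrix) -> RelationshipMatrix:
    """Standardized GRM: A_ij = (1/M) sum_k z_ik z_jk / (2 p_k (1-p_k)).

    Every SNP must be polymorphic (monomorphic markers are a QC failure
    here, not a silent skip). No clamping is applied.
    """
    Z, p = _centered_dosages(matrix)
    poly = (p > 0) & (p < 1)
    if not poly.all():
        raise InputError(
            f"{int((~poly).sum())} monomorphic SNPs; filter them before building the GRM"
        )
    W = Z / np.sqrt(2.0 * p * (1.0 - p))
    A = (W @ W.T) / matrix.n_variants
    return RelationshipMatrix(samples=matrix.samples, values=A, flavor="standardized_grm")


@dataclass
class PCAResult:
    """Top eigenpairs of a relationship matrix, eigenvalues descending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # samples x k, unit norm
    variance_explained: np.ndarray  # eigenvalue / trace
    samples: np.ndarray

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"EV{i + 1}": self.eigenvectors[:, i] for i in range(self.eigenvectors.shape[1])}
        return pd.DataFrame({"sample_id": self.samples, **cols})


def pca(grm: RelationshipMatrix, k: int = 10) -> PCAResult:
    """Top-k eigen-decomposition of a (symmetric) relationship matrix.

    Sign convention: each eigenvector's largest-magnitude loading is made
    positive, so repeated runs and downstream regressions are reproducible.
    """
    A = grm.values
    if not np.allclose(A, A.T, atol=1e-8):
        raise InputError("relationship matrix must be symmetric")
    n = A.shape[0]
    if k > n:
        logger.warning("requested %d components from %d samples; truncating", k, n)
        k = n
    vals, vecs = eigh(A, subset_by_index=(n - k, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    trace = float(np.trace(A))
    return PCAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        variance_explained=vals / trace if trace != 0 else np.full(k, np.nan),
        samples=grm.samples,
    )


def rogers_distance(matrix: GenotypeMatrix) -> RelationshipMatrix:
    """Rogers (1972) genetic distance between individuals.

    At a biallelic locus with individual allele frequencies in {0, 1/2, 1},
    the per-locus Rogers distance reduces to |g_i - g_j| / 2 on dosages; the
    pairwise distance is its mean over loci where both individuals are
    called. Pairs with no shared loci are NaN (flagged).
    """
    D = matrix.dosages
    called = (D != MISSING).astype(np.float64)
    ind = [(D == v).astype(np.float64) for v in (0, 1, 2)]
    # sum over loci of |a-b| accumulated from co-occurrence counts
    s = (
        ind[0] @ ind[1].T
        + ind[1] @ ind[0].T
        + ind[1] @ ind[2].T
        + ind[2] @ ind[1].T
        + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
    )
    shared = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, s / (2.0 * shared), np.nan)
    if np.isnan(dist).any():
        logger.warning("sample pairs with no shared called loci: distance undefined")
    dist = np.where(np.isnan(dist), np.nan, np.maximum(dist, 0.0))
    np.fill_diagonal(dist, 0.0)
    return RelationshipMatrix(samples=matrix.samples, values=dist, flavor="rogers_distance")


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an (unrooted, trifurcating-root) NJ tree."""

    name: str | None = None
    length: float = 0.0
    children: list = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return f"{self._newick()};"

    def _newick(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick() for c in self.children)
        if self.length or self.name:
            return f"({inner}){self.name or ''}:{self.length:.10g}"
        return f"({inner})"


def _clamp_length(x: float) -> float:
    if x < 0:
        logger.info("negative NJ branch length %.3g clamped to 0", x)
        return 0.0
    return x


def neighbor_joining(dist, labels=None) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Accepts a RelationshipMatrix (rogers_distance flavor) or a square array
    plus labels. Ties in Q are broken deterministically by the smallest
    (i, j) index pair; negative branch lengths are clamped to zero. For an
    additive distance matrix the tree's path lengths reproduce the input
    exactly (up to floating error).
    """
    if isinstance(dist, RelationshipMatrix):
        labels = list(dist.samples)
        D = np.array(dist.values, dtype=float)
    else:
        D = np.array(dist, dtype=float)
        if labels is None:
            labels = [f"T{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise InputError("NJ requires a square symmetric distance matrix")
    if np.any(np.diag(D) != 0):
        raise InputError("NJ requires a zero diagonal")

    nodes = [TreeNode(name=str(lab)) for lab in labels]
    if n == 1:
        return nodes[0]
    if n == 2:
        root = TreeNode()
        nodes[0].length = _clamp_length(D[0, 1] / 2.0)
        nodes[1].length = _clamp_length(D[0, 1] / 2.0)
        root.children = nodes
        return root

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        Q = (r - 2.0) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: smallest flat index == smallest (i, j)
        flat = int(np.argmin(np.round(Q, 12)))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        dij = D[i, j]
        li = dij / 2.0 + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2.0))
        lj = dij - li
        new = TreeNode()
        nodes[i].length = _clamp_length(li)
        nodes[j].length = _clamp_length(lj)
        new.children = [nodes[i], nodes[j]]

        # distances from the new node to the remaining actives
        new_row = np.zeros(D.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.vstack([D, new_row[None, :]])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [D.shape[0] - 1]

    # resolve the final 3 nodes around an unrooted center
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in zip((nodes[a], nodes[b], nodes[c]), (la, lb, lc)):
        node.length = _clamp_length(ln)
    root.children = [nodes[a], nodes[b], nodes[c]]
    return root


def tree_path_lengths(root: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path lengths of a tree, for round-trip verification."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf():
            dists[node.name] = acc
        for ch in node.children:
            walk(ch, acc + ch.length)

    # path length through the (unrooted) root: depth_i + depth_j
    leaves = [leaf.name for leaf in root.leaves()]
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)

    def pairwise(node):
        # distances of all leaves below each child to the node, combined
        below = []
        for ch in node.children:
            d = {}
            stack = [(ch, ch.length)]
            while stack:
                cur, acc = stack.pop()
                if cur.is_leaf():
                    d[cur.name] = acc
                for g in cur.children:
                    stack.append((g, acc + g.length))
            below.append(d)
            if not ch.is_leaf():
                pairwise(ch)
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for lx, dx in below[x].items():
                    for ly, dy in below[y].items():
                        out.loc[lx, ly] = out.loc[ly, lx] = dx + dy

    pairwise(root)
    return out
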