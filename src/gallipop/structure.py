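"""Population structure: GRM-based PCA and neighbor-joining trees.

The genomic relationship matrix follows the standard array convention
G_jk = mean_l (x_jl - 2 p_l)(x_kl - 2 p_l) / (2 p_l (1 - p_l)) over
polymorphic autosomal SNPs, with missing data handled by per-pair complete
SNP sets.  PCA is the eigendecomposition of G.  Trees are built by
Saitou-Nei neighbor joining on 1 - IBS allele-sharing distances, either
between individuals or between populations (mean inter-population
distance), with a deterministic lowest-label tie-break and newick output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class GRM:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("GRM must be symmetric")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")


class TreeNode:
    """Unrooted/rooted tree node; children carry branch lengths."""

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[tuple["TreeNode", float]] = []

    def add(self, child: "TreeNode", length: float) -> None:
        self.children.append((child, float(length)))

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out += c.leaves()
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{ln!r}" for c, ln in self.children)
        return f"({inner})" + (self.name or "")


def compute_grm(matrix: GenotypeMatrix) -> GRM:
    """GCTA-style GRM over polymorphic autosomal SNPs (pairwise-complete)."""
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    calls = matrix.calls[:, ~matrix.sex_linked_mask].astype(float)
    ok = calls != MISSING
    x = np.where(ok, calls, 0.0)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, x.sum(axis=0) / (2 * n), np.nan)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic autosomal SNPs")
    x, ok, p = x[:, poly], ok[:, poly], p[poly]
    denom = np.sqrt(2 * p * (1 - p))
    z = np.where(ok, (x - 2 * p) / denom, 0.0)
    counts = ok.astype(float) @ ok.T.astype(float)
    g = (z @ z.T) / np.maximum(counts, 1)
    if (counts == 0).any():
        raise ValueError("a sample pair shares no non-missing SNPs")
    return GRM(sample_ids=matrix.sample_ids, values=g)


def pca_from_grm(grm: GRM, n_components: int = 2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Top principal components of the GRM.

    Returns (coordinates (n, k), variance proportions (k,)).  Coordinates
    are eigenvectors scaled by sqrt(eigenvalue); the sign convention makes
    the largest-magnitude loading of each component positive.
    """
    v = grm.values
    if not np.isfinite(v).all():
        raise ValueError("GRM contains non-finite values")
    evals, evecs = np.linalg.eigh(v)
    order = np.argsort(evals)[::-1][:n_components]
    evals_top = evals[order]
    evecs_top = evecs[:, order]
    for k in range(evecs_top.shape[1]):
        j = np.argmax(np.abs(evecs_top[:, k]))
        if evecs_top[j, k] < 0:
            evecs_top[:, k] *= -1
    coords = evecs_top * np.sqrt(np.maximum(evals_top, 0.0))
    varprop = evals_top / evals.clip(min=0).sum()
    return coords, varprop


def allele_sharing_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS between individuals; IBS = 1 - |x_j - x_k| / 2 averaged."""
    calls = matrix.calls.astype(float)
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least two samples")
    ok = calls != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        shared = ok[i] & ok
        diff = np.abs(calls[i] - calls) / 2.0
        num = np.where(shared, diff, 0.0).sum(axis=1)
        cnt = shared.sum(axis=1)
        if (cnt == 0).any():
            raise ValueError("a sample pair shares no non-missing SNPs")
        d[i] = num / cnt
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=matrix.sample_ids, values=d)


def population_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Mean inter-population allele-sharing distance (population-level tree)."""
    ind = allele_sharing_distance(matrix)
    pops = matrix.populations
    idx = {p: matrix.pop_indices(p) for p in pops}
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = ind.values[np.ix_(idx[pops[i]], idx[pops[j]])].mean()
    return DistanceMatrix(labels=pops, values=d)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken by the lexicographically lowest (label, label)
    pair, making the topology deterministic.  Negative branch lengths are
    preserved (flagged with a warning), as classic NJ produces them on
    non-additive input.  Exactly recovers additive distance matrices.
    """
    labels = list(distances.labels)
    if len(labels) < 3:
        raise ValueError("need at least three labels")
    d = {a: {b: float(distances.values[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    nodes: dict[str, TreeNode] = {a: TreeNode(a) for a in labels}
    active = list(labels)
    negative = False
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        negative |= (la < 0) or (lb < 0)
        new = TreeNode()
        new.add(nodes[a], la)
        new.add(nodes[b], lb)
        uname = f"__internal_{counter}"
        counter += 1
        nodes[uname] = new
        d[uname] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[uname][c] = dc
            d[c][uname] = dc
        active = [c for c in active if c not in (a, b)] + [uname]
    # resolve the final three nodes on one internal vertex (closed form)
    a, b, c = sorted(active, key=lambda x: (x.startswith("__"), x))
    root = TreeNode()
    root.add(nodes[a], 0.5 * (d[a][b] + d[a][c] - d[b][c]))
    root.add(nodes[b], 0.5 * (d[a][b] + d[b][c] - d[a][c]))
    root.add(nodes[c], 0.5 * (d[a][c] + d[b][c] - d[a][b]))
    for _, ln in root.children:
        negative |= ln < 0
    if negative:
        warnings.warn("NJ produced negative branch length(s); preserved as computed")
    return root


def pca_table(matrix: GenotypeMatrix, n_components: int = 2) -> pd.DataFrame:
    grm = compute_grm(matrix)
    coords, varprop = pca_from_grm(grm, n_components)
    df = pd.DataFrame(coords, columns=[f"PC{k + 1}" for k in range(coords.shape[1])])
    df.insert(0, "sample_id", matrix.sample_ids)
    df.insert(1, "population", [s.population for s in matrix.samples])
    df.attrs["variance_proportions"] = varprop
    return df
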