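"""Pleiotropy discovery (pipeline Phase 3).

Each rSNP kept by the association step gets a binary profile over the
phenotypes (membership in the phenotype's optimal rSNP set) and the TFs
(recorded Gain/Loss consequence).  Profiles are compared with the
Proportional Similarity Index, A_kl = 2 sum_j min(M_kj, M_lj) /
sum_j (M_kj + M_lj), and the resulting association matrix is clustered
with the Markov clustering algorithm (MCL).  rSNPs associated with fewer
than two phenotypes are then pruned: a pleiotropic signature needs at
least two traits (TF columns never confer pleiotropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regulatory import GAIN, LOSS, RegulatoryConsequence
from .util import logger

PHENO_PREFIX = "phenotype:"
TF_PREFIX = "tf:"

DEFAULT_INFLATION = 2.0
DEFAULT_EXPANSION = 2
DEFAULT_MAX_ITER = 200
DEFAULT_TOL = 1e-8
DEFAULT_PRUNE_EPS = 1e-6


@dataclass
class ProfileMatrix:
    """Binary rSNP x (phenotype ∪ TF) matrix; column labels are disjoint
    by prefixing ('phenotype:' / 'tf:')."""

    data: pd.DataFrame

    @property
    def rsnp_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def phenotype_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(PHENO_PREFIX)]

    @property
    def tf_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(TF_PREFIX)]

    def phenotypes_of(self, snp_id: str) -> list[str]:
        row = self.data.loc[snp_id, self.phenotype_columns]
        return [c[len(PHENO_PREFIX):] for c in row.index[row > 0]]


@dataclass
class ClusterSet:
    """Disjoint rSNP-id clusters, ordered by size (desc) then smallest id."""

    clusters: list[list[str]] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.clusters = sorted(
            (sorted(c) for c in self.clusters), key=lambda c: (-len(c), c[0] if c else "")
        )

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def labels(self) -> dict[str, int]:
        return {m: i for i, c in enumerate(self.clusters) for m in c}


def build_profile_matrix(
    optimal_sets: dict[str, list[str]],
    consequences: Iterable[RegulatoryConsequence],
) -> ProfileMatrix:
    """Profile rows for every rSNP appearing in at least one optimal set.

    Phenotype entry = optimal-set membership; TF entry = any Gain or Loss
    consequence of that rSNP for that TF.  Columns are phenotypes then TFs,
    each lexicographic.
    """
    rsnps = sorted({s for members in optimal_sets.values() for s in members})
    phenos = sorted(optimal_sets)
    gainloss = [c for c in consequences if c.effect in (GAIN, LOSS) and c.snp_id in set(rsnps)]
    tfs = sorted({c.pwm_name for c in gainloss})
    cols = [PHENO_PREFIX + p for p in phenos] + [TF_PREFIX + t for t in tfs]
    M = pd.DataFrame(0, index=pd.Index(rsnps, name="rsnp"), columns=cols, dtype=int)
    for p, members in optimal_sets.items():
        for s in members:
            M.loc[s, PHENO_PREFIX + p] = 1
    for c in gainloss:
        M.loc[c.snp_id, TF_PREFIX + c.pwm_name] = 1
    return ProfileMatrix(M)


def psi(row_k: Sequence[float], row_l: Sequence[float]) -> float:
    """Proportional Similarity Index of two equal-length profiles.

    2 sum min / sum (k + l); two all-zero rows share nothing, so the 0/0
    case is defined as 0.
    """
    a = np.asarray(row_k, dtype=float)
    b = np.asarray(row_l, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    denom = float((a + b).sum())
    if denom == 0:
        return 0.0
    return 2.0 * float(np.minimum(a, b).sum()) / denom


def psi_matrix(M: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise PSI over rows: symmetric, in [0, 1], diagonal 1 for any row
    with at least one nonzero entry (0 for all-zero rows)."""
    A = np.asarray(M.data if isinstance(M, ProfileMatrix) else M, dtype=float)
    n = A.shape[0]
    rowsums = A.sum(axis=1)
    # sum_j min(a_j, b_j) pairwise; profiles are small, broadcast in blocks
    mins = np.empty((n, n))
    block = max(1, int(2e7 // max(A.size, 1)))
    for i0 in range(0, n, block):
        i1 = min(n, i0 + block)
        mins[i0:i1] = np.minimum(A[i0:i1, None, :], A[None, :, :]).sum(axis=2)
    denom = rowsums[:, None] + rowsums[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, 2.0 * mins / np.where(denom > 0, denom, 1.0), 0.0)
    return out


# ---------------------------------------------------------------------------
# Markov clustering


def _column_normalize(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    sums[sums == 0] = 1.0
    return M / sums


def mcl_matrix(
    A: np.ndarray,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = DEFAULT_EXPANSION,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    prune_eps: float = DEFAULT_PRUNE_EPS,
) -> tuple[list[set[int]], bool]:
    """Markov clustering of a nonnegative symmetric similarity matrix.

    Adds self-loops equal to each row's maximum (1 for all-zero rows),
    column-normalizes to a stochastic matrix, then iterates expansion
    (matrix power), inflation (entrywise power + renormalization) and
    pruning of entries below ``prune_eps`` until the maximum entry change
    falls below ``tol``.  Attractors (rows with positive diagonal mass) are
    grouped into clusters; overlapping attractor systems are merged and
    every other node joins the attractor holding its largest limit weight,
    ties resolved toward the smallest attractor index.

    Returns (clusters over row indices, converged flag).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("MCL input must be a square matrix")
    if np.any(A < 0):
        raise ValueError("MCL input must be nonnegative")
    n = A.shape[0]
    if n == 0:
        return [], True
    M = A.copy()
    loop = M.max(axis=1)
    loop[loop == 0] = 1.0
    np.fill_diagonal(M, loop)
    M = _column_normalize(M)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune_eps] = 0.0
        M = _column_normalize(M)
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge within %d iterations", max_iter)

    attractors = [i for i in range(n) if M[i, i] > prune_eps]
    if not attractors:  # fully degenerate limit: everything is one cluster
        return [set(range(n))], converged
    # merge attractor systems that support each other
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > prune_eps or M[j, i] > prune_eps):
                union(i, j)
    clusters: dict[int, set[int]] = {}
    for i in attractors:
        clusters.setdefault(find(i), set()).add(i)
    attractor_arr = np.array(attractors)
    for v in range(n):
        if v in set(attractors):
            continue
        weights = M[attractor_arr, v]
        if weights.max() <= prune_eps:
            clusters.setdefault(v, set()).add(v)  # isolated node: singleton
            continue
        best = int(attractor_arr[int(np.argmax(weights))])  # first max: smallest index
        clusters[find(best)].add(v)
    return list(clusters.values()), converged


def mcl(
    A: np.ndarray,
    ids: Sequence[str] | None = None,
    inflation: float = DEFAULT_INFLATION,
    expansion: int = DEFAULT_EXPANSION,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    prune_eps: float = DEFAULT_PRUNE_EPS,
) -> ClusterSet:
    """MCL over an association matrix, reporting clusters of row ids."""
    index_clusters, converged = mcl_matrix(
        A, inflation=inflation, expansion=expansion, max_iter=max_iter,
        tol=tol, prune_eps=prune_eps,
    )
    if ids is None:
        ids = [str(i) for i in range(np.asarray(A).shape[0])]
    return ClusterSet([[ids[i] for i in c] for c in index_clusters], converged=converged)


def prune_non_pleiotropic(clusters: ClusterSet, profile: ProfileMatrix) -> ClusterSet:
    """Drop rSNPs associated with fewer than two phenotypes (TF columns do
    not count), and drop clusters emptied by the rule."""
    pheno = profile.data[profile.phenotype_columns]
    keep = set(pheno.index[(pheno > 0).sum(axis=1) >= 2])
    pruned = [[m for m in c if m in keep] for c in clusters]
    return ClusterSet([c for c in pruned if c], converged=clusters.converged)


def cluster_summary(
    clusters: ClusterSet,
    profile: ProfileMatrix,
    gene_map: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-cluster counts of rSNPs and genes plus the union of associated
    phenotypes, ordered by cluster size descending."""
    rows = []
    for i, members in enumerate(clusters):
        phenos: set[str] = set()
        genes: set[str] = set()
        for m in members:
            phenos.update(profile.phenotypes_of(m))
            if gene_map:
                genes.update(gene_map.get(m, set()))
        rows.append(
            {
                "cluster": f"Cluster-{i + 1}",
                "n_rsnps": len(members),
                "n_genes": len(genes) if gene_map else pd.NA,
                "phenotypes": ", ".join(sorted(phenos)),
            }
        )
    return pd.DataFrame(rows, columns=["cluster", "n_rsnps", "n_genes", "phenotypes"])


def gene_map_from_consequences(consequences: Iterable[RegulatoryConsequence]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for c in consequences:
        out.setdefault(c.snp_id, set()).add(c.gene_id)
    return out
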