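"""Hierarchical network models and expression validation (pipeline Phase 4).

For each pleiotropy cluster a three-layer directed graph is built:
TF -> rSNP(gene) -> phenotype, with TF edges labeled Gain or Loss.  Each
pleiotropic rSNP is then validated against expression: lines are split by
allele (reference homozygotes vs alternate homozygotes; heterozygotes
excluded by default on an inbred panel), and the normalized expression of
the rSNP's gene is compared between the groups with a Wilcoxon rank-sum
test.  rSNPs without a significant expression shift are pruned from the
network together with any TF or phenotype node left unconnected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .pleio import ClusterSet
from .regulatory import GAIN, LOSS, RegulatoryConsequence, SNPRecord
from .util import logger

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GROUP = 3
# exact rank-sum enumeration whenever C(n1+n2, n1) is at most this budget
# (covers both samples up to 10 each, and any split of 12 or fewer values)
EXACT_ENUMERATION_BUDGET = 184_756


# ---------------------------------------------------------------------------
# Normalization


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized genes x lines matrix.

    Per line: the median, over genes with all-positive counts, of the
    count divided by the gene's geometric mean across lines; genes
    containing any zero are excluded from the median.
    """
    C = counts.to_numpy(dtype=float)
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    positive = np.all(C > 0, axis=1)
    if not positive.any():
        raise ValueError("median-of-ratios undefined: no gene with all-positive counts")
    logC = np.log(C[positive])
    log_geomean = logC.mean(axis=1, keepdims=True)
    ratios = np.exp(logC - log_geomean)
    factors = pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")
    normalized = counts / factors
    return factors, normalized


# ---------------------------------------------------------------------------
# Allele split and rank-sum test


def split_lines_by_allele(
    dosages: Sequence[float],
    line_ids: Sequence[str],
    het: str = "exclude",
    min_group: int = DEFAULT_MIN_GROUP,
) -> tuple[list[str], list[str]] | None:
    """Reference-homozygote vs alternate-allele line groups.

    Dosage 0 -> reference group, dosage 2 -> alternate group; heterozygotes
    (dosage 1) and missing calls are excluded unless ``het='alt'`` pools
    heterozygotes with the alternate group.  Returns None (with a warning
    upstream) when either group is smaller than ``min_group``.
    """
    d = np.asarray(dosages, dtype=float)
    ref = [line_ids[i] for i in range(len(line_ids)) if d[i] == 0]
    if het == "alt":
        alt = [line_ids[i] for i in range(len(line_ids)) if d[i] in (1, 2)]
    elif het == "exclude":
        alt = [line_ids[i] for i in range(len(line_ids)) if d[i] == 2]
    else:
        raise ValueError(f"unknown heterozygote policy {het!r}")
    if len(ref) < min_group or len(alt) < min_group:
        return None
    return ref, alt


def _rank_sum(x: np.ndarray, pooled_sorted: np.ndarray, midranks: np.ndarray) -> float:
    idx = np.searchsorted(pooled_sorted, x)
    return float(midranks[idx].sum())


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum statistic and two-sided p-value.

    The statistic is the mid-rank sum of the first sample in the pooled
    ranking.  When the pooled data has no ties and the C(n1+n2, n1) rank
    assignments fit the enumeration budget (true whenever both samples have
    at most 10 observations), the p-value is exact by enumeration; otherwise
    a tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks
    W = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and math.comb(n1 + n2, n1) <= EXACT_ENUMERATION_BUDGET:
        total = math.comb(n1 + n2, n1)
        count_le = count_ge = 0
        for combo in itertools.combinations(range(1, n1 + n2 + 1), n1):
            s = sum(combo)
            if s <= W + 1e-9:
                count_le += 1
            if s >= W - 1e-9:
                count_ge += 1
        p = 2.0 * min(count_le, count_ge) / total
        return W, float(min(p, 1.0))

    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return W, 1.0
    diff = W - mean
    z = (abs(diff) - 0.5) / math.sqrt(var)  # continuity correction toward the mean
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return W, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Expression validation


@dataclass
class ExpressionValidation:
    snp_id: str
    gene_id: str
    n_ref: int
    n_alt: int
    statistic: float
    p_value: float
    direction: str  # 'up' | 'down': alt-group median relative to ref
    significant: bool = False


def validate_expression(
    clusters: ClusterSet,
    consequences: Iterable[RegulatoryConsequence],
    snps: Mapping[str, SNPRecord],
    normalized: pd.DataFrame,
    line_ids: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    het: str = "exclude",
    min_group: int = DEFAULT_MIN_GROUP,
    bh_correct: bool = False,
) -> list[ExpressionValidation]:
    """Allele-split Wilcoxon test for every (pleiotropic rSNP, gene) pair.

    Significance is raw p < alpha, or Benjamini-Hochberg-adjusted across
    all records when ``bh_correct`` is set.
    """
    member_ids = {m for c in clusters for m in c}
    pairs = sorted(
        {(c.snp_id, c.gene_id) for c in consequences if c.snp_id in member_ids}
    )
    out: list[ExpressionValidation] = []
    for snp_id, gene_id in pairs:
        if gene_id not in normalized.index:
            logger.warning("gene %s absent from expression matrix, skipped", gene_id)
            continue
        snp = snps[snp_id]
        groups = split_lines_by_allele(snp.dosages, list(line_ids), het=het, min_group=min_group)
        if groups is None:
            logger.warning("rSNP %s: allele group below %d lines, validation skipped", snp_id, min_group)
            continue
        ref_lines, alt_lines = groups
        expr = normalized.loc[gene_id]
        xs = expr[ref_lines].to_numpy(dtype=float)
        ys = expr[alt_lines].to_numpy(dtype=float)
        W, p = wilcoxon_rank_sum(xs, ys)
        direction = "up" if float(np.median(ys)) >= float(np.median(xs)) else "down"
        out.append(
            ExpressionValidation(
                snp_id=snp_id, gene_id=gene_id, n_ref=len(ref_lines), n_alt=len(alt_lines),
                statistic=W, p_value=p, direction=direction,
            )
        )
    if bh_correct and out:
        from statsmodels.stats.multitest import multipletests

        rej, _, _, _ = multipletests([v.p_value for v in out], alpha=alpha, method="fdr_bh")
        for v, r in zip(out, rej):
            v.significant = bool(r)
    else:
        for v in out:
            v.significant = v.p_value < alpha
    return out


# ---------------------------------------------------------------------------
# Hierarchical networks


def build_hierarchical_network(
    cluster_id: str,
    members: Sequence[str],
    consequences: Iterable[RegulatoryConsequence],
    optimal_sets: Mapping[str, Sequence[str]],
) -> nx.DiGraph:
    """Three-layer TF -> rSNP(gene) -> phenotype graph for one cluster.

    Layer-1 TF edges carry the Gain/Loss label; layer-2 rSNP nodes carry
    their gene id; rSNPs with no recorded TF consequence cannot occupy
    layer 2 and are excluded with a warning.
    """
    G = nx.DiGraph(cluster=cluster_id)
    members = set(members)
    cons = [c for c in consequences if c.snp_id in members and c.effect in (GAIN, LOSS)]
    with_tf = {c.snp_id for c in cons}
    for m in sorted(members - with_tf):
        logger.warning("rSNP %s has no TF consequence, excluded from network", m)
    genes = {}
    for c in cons:
        genes.setdefault(c.snp_id, c.gene_id)
    for snp_id in sorted(with_tf):
        G.add_node(f"rsnp:{snp_id}", layer=2, gene=genes[snp_id], label=snp_id)
    for c in cons:
        tf_node = f"tf:{c.pwm_name}"
        if tf_node not in G:
            G.add_node(tf_node, layer=1, label=c.pwm_name)
        G.add_edge(tf_node, f"rsnp:{c.snp_id}", effect=c.effect)
    for pheno, snp_ids in optimal_sets.items():
        for snp_id in snp_ids:
            if snp_id in with_tf:
                ph_node = f"phenotype:{pheno}"
                if ph_node not in G:
                    G.add_node(ph_node, layer=3, label=pheno)
                G.add_edge(f"rsnp:{snp_id}", ph_node)
    return G


def is_tripartite(G: nx.DiGraph) -> bool:
    """Edges run only layer 1 -> 2 and 2 -> 3."""
    for u, v in G.edges:
        if G.nodes[u]["layer"] + 1 != G.nodes[v]["layer"]:
            return False
    return True


def prune_network_by_expression(
    G: nx.DiGraph, validations: Iterable[ExpressionValidation]
) -> nx.DiGraph:
    """Remove rSNP nodes lacking a significant expression validation, then
    any TF or phenotype node left with degree 0.  rSNPs with no validation
    record are treated as non-significant."""
    significant = {v.snp_id for v in validations if v.significant}
    H = G.copy()
    for node in [n for n, d in G.nodes(data=True) if d["layer"] == 2]:
        if H.nodes[node]["label"] not in significant:
            H.remove_node(node)
    for node in [n for n, d in H.nodes(data=True) if d["layer"] != 2]:
        if H.degree(node) == 0:
            H.remove_node(node)
    return H


def grouped_expression_table(
    validations: Iterable[ExpressionValidation],
    snps: Mapping[str, SNPRecord],
    normalized: pd.DataFrame,
    line_ids: Sequence[str],
    het: str = "exclude",
    min_group: int = DEFAULT_MIN_GROUP,
) -> pd.DataFrame:
    """Long-format per-line normalized expression split by allele group,
    one block per validated (rSNP, gene) — the data behind the usual
    allele-split box plots."""
    rows = []
    for v in validations:
        groups = split_lines_by_allele(
            snps[v.snp_id].dosages, list(line_ids), het=het, min_group=min_group
        )
        if groups is None or v.gene_id not in normalized.index:
            continue
        for label, lines in zip(("ref", "alt"), groups):
            for line in lines:
                rows.append(
                    {
                        "snp_id": v.snp_id, "gene_id": v.gene_id, "group": label,
                        "line": line, "expression": float(normalized.loc[v.gene_id, line]),
                    }
                )
    return pd.DataFrame(rows, columns=["snp_id", "gene_id", "group", "line", "expression"])
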