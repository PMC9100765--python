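"""rSNP-phenotype association (pipeline Phase 2).

Per phenotype, a Random-Forest regression on rSNP dosages is wrapped in the
Boruta shadow-feature procedure to obtain a robust importance ranking, and
incremental feature selection (IFS) then walks down that ranking, refitting
the forest on the top-k features and recording out-of-bag R², to choose the
optimal number of associated rSNPs (the smallest k attaining the peak R²).

Forest settings follow the classical regression defaults: impurity-based
importances, features-per-split = p/3, minimum leaf size 5, 500 trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .regulatory import SNPRecord
from .util import logger, stage_seed

CONFIRMED = "Confirmed"
TENTATIVE = "Tentative"
REJECTED = "Rejected"

DEFAULT_TREES = 500
DEFAULT_MAX_ITER = 100
DEFAULT_ALPHA = 0.01
MIN_LINES = 20


def encode_genotypes(snps: list[SNPRecord], line_ids: list[str]) -> pd.DataFrame:
    """Lines x rSNPs dosage matrix (0/1/2), missing imputed by per-SNP mode.

    SNPs with all dosages missing are dropped with a warning; columns are
    ordered by rSNP id for determinism.
    """
    cols = {}
    for snp in sorted(snps, key=lambda s: s.id):
        d = np.asarray(snp.dosages, dtype=float)
        missing = np.isnan(d)
        if missing.all():
            logger.warning("SNP %s: all dosages missing, dropped", snp.id)
            continue
        if missing.any():
            values, counts = np.unique(d[~missing], return_counts=True)
            d = d.copy()
            d[missing] = values[np.argmax(counts)]  # smallest mode on ties
        cols[snp.id] = d
    return pd.DataFrame(cols, index=pd.Index(line_ids, name="line"))


def _forest(n_trees: int, seed: int, oob: bool = False) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1 / 3,
        min_samples_leaf=5,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def rf_importance(X: np.ndarray, y: np.ndarray, n_trees: int = DEFAULT_TREES, seed: int = 0) -> np.ndarray:
    """Impurity-based importances of a regression forest (nonnegative, sum 1)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] < MIN_LINES:
        raise ValueError(f"need aligned X and y with >= {MIN_LINES} rows")
    if np.ptp(y) == 0:
        raise ValueError("constant response: importances undefined")
    return _forest(n_trees, seed).fit(X, y).feature_importances_


def _binom_half_two_sided(hits: int, n: int) -> float:
    """Two-sided exact binomial p-value at p = 1/2.

    The Binomial(n, 1/2) pmf is symmetric, so the minimum-likelihood
    two-sided test reduces to the double tail beyond |hits - n/2|.
    """
    lo = min(hits, n - hits)
    p = stats.binom.cdf(lo, n, 0.5) + stats.binom.sf(n - lo - 1, n, 0.5)
    return float(min(p, 1.0))


@dataclass
class BorutaResult:
    """Decisions and the full importance ranking from the shadow procedure."""

    median_z: pd.Series  # per-feature median standardized importance
    decision: pd.Series  # Confirmed | Tentative | Rejected
    ranking: list[str]  # all features, by median Z descending (ties by id)
    n_iter: int = 0
    hits: pd.Series = field(default_factory=pd.Series)


def boruta_rank(
    X: pd.DataFrame,
    y: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
) -> BorutaResult:
    """Boruta shadow-feature selection around the regression forest.

    Each iteration appends a column-permuted shadow copy of every active
    feature, fits the forest, and scores a "hit" for any undecided feature
    whose importance exceeds the best shadow importance.  Hit counts are
    tested against Binomial(iters, 1/2), two-sided, at level ``alpha`` with
    Bonferroni correction over the currently undecided features; rejected
    features leave the design, survivors at ``max_iter`` remain Tentative.
    Every original feature is ranked by its median standardized importance
    Z = (importance - mean shadow) / sd shadow over its active iterations.
    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] < MIN_LINES:
        raise ValueError(f"need aligned X and y with >= {MIN_LINES} rows")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    features = list(X.columns)
    decision = {f: TENTATIVE for f in features}
    hits = {f: 0 for f in features}
    z_history: dict[str, list[float]] = {f: [] for f in features}
    rng = np.random.default_rng(stage_seed(seed, "boruta-shadows"))
    active = list(features)  # undecided + confirmed stay in the design

    n_done = 0
    for it in range(1, max_iter + 1):
        Xa = X[active].to_numpy(dtype=float)
        shadows = Xa.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        design = np.hstack([Xa, shadows])
        imp = rf_importance(design, y, n_trees=n_trees, seed=stage_seed(seed, "boruta-rf", str(it)))
        real_imp, shadow_imp = imp[: len(active)], imp[len(active) :]
        shadow_max = shadow_imp.max()
        mu = shadow_imp.mean()
        sd = shadow_imp.std(ddof=1) if shadow_imp.size > 1 else 0.0
        if not np.isfinite(sd) or sd <= 0:
            sd = 1e-12
        undecided = [f for f in active if decision[f] == TENTATIVE]
        for f, v in zip(active, real_imp):
            z_history[f].append((v - mu) / sd)
            if decision[f] == TENTATIVE and v > shadow_max:
                hits[f] += 1
        m = len(undecided)
        if m:
            threshold = alpha / m
            for f in undecided:
                p = _binom_half_two_sided(hits[f], it)
                if p < threshold:
                    decision[f] = CONFIRMED if hits[f] > it / 2 else REJECTED
        active = [f for f in active if decision[f] != REJECTED]
        n_done = it
        if not any(decision[f] == TENTATIVE for f in active):
            break

    median_z = pd.Series({f: float(np.median(z_history[f])) for f in features})
    ranking = sorted(features, key=lambda f: (-median_z[f], f))
    return BorutaResult(
        median_z=median_z,
        decision=pd.Series(decision),
        ranking=ranking,
        n_iter=n_done,
        hits=pd.Series(hits),
    )


@dataclass
class IFSCurve:
    """Out-of-bag R² as ranked features are added one stride at a time."""

    phenotype: str
    ks: list[int]
    r2: list[float]
    ranking: list[str] = field(default_factory=list)  # the ranking walked

    @property
    def max_r2(self) -> float:
        return float(np.max(self.r2))

    @property
    def optimal_k(self) -> int:
        return int(self.ks[int(np.argmax(self.r2))])  # smallest k at the max


def ifs_curve(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: list[str],
    k_max: int | None = None,
    stride: int = 1,
    n_trees: int = DEFAULT_TREES,
    seed: int = 0,
    phenotype: str = "",
) -> IFSCurve:
    """Incremental feature selection along ``ranking``.

    Fits the forest on the top-k ranked features for k = 1, 1+stride, ...
    up to ``k_max`` (clipped to the feature count, with a warning) and
    records out-of-bag R²; the optimal k is the smallest recorded k
    attaining the maximum.
    """
    p = len(ranking)
    if k_max is None:
        k_max = p
    if k_max > p:
        logger.warning("k_max %d exceeds feature count %d, clipped", k_max, p)
        k_max = p
    y = np.asarray(y, dtype=float)
    ks, r2s = [], []
    for k in range(1, k_max + 1, stride):
        Xk = X[ranking[:k]].to_numpy(dtype=float)
        rf = _forest(n_trees, stage_seed(seed, "ifs", str(k)), oob=True).fit(Xk, y)
        ks.append(k)
        r2s.append(float(rf.oob_score_))
    return IFSCurve(phenotype=phenotype, ks=ks, r2=r2s, ranking=list(ranking))


@dataclass
class AssociationParams:
    n_trees: int = DEFAULT_TREES
    max_iter: int = DEFAULT_MAX_ITER
    alpha: float = DEFAULT_ALPHA
    stride: int = 1
    k_max: int | None = None
    seed: int = 0


def associate_all(
    X: pd.DataFrame,
    phenotypes: pd.DataFrame,
    params: AssociationParams | None = None,
) -> tuple[dict[str, list[str]], dict[str, IFSCurve], pd.DataFrame]:
    """Boruta + IFS for every phenotype column.

    Returns (optimal rSNP set per phenotype, IFS curve per phenotype, and a
    summary table of phenotype / max R² / optimal rSNP count).  Phenotypes
    with fewer than 20 non-missing values are skipped with a warning.
    """
    params = params or AssociationParams()
    if not X.index.equals(phenotypes.index):
        common = X.index.intersection(phenotypes.index)
        if len(common) < MIN_LINES:
            raise ValueError("line ids of genotypes and phenotypes do not align")
        logger.warning("aligning on %d shared lines", len(common))
        X, phenotypes = X.loc[common], phenotypes.loc[common]
    optimal: dict[str, list[str]] = {}
    curves: dict[str, IFSCurve] = {}
    rows = []
    for trait in phenotypes.columns:
        y = phenotypes[trait].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < MIN_LINES:
            logger.warning("phenotype %s: < %d non-missing values, skipped", trait, MIN_LINES)
            continue
        Xt, yt = X.loc[ok], y[ok]
        sub = stage_seed(params.seed, "assoc", trait)
        boruta = boruta_rank(
            Xt, yt, max_iter=params.max_iter, alpha=params.alpha,
            n_trees=params.n_trees, seed=sub,
        )
        curve = ifs_curve(
            Xt, yt, boruta.ranking, k_max=params.k_max, stride=params.stride,
            n_trees=params.n_trees, seed=sub, phenotype=trait,
        )
        optimal[trait] = sorted(boruta.ranking[: curve.optimal_k])
        curves[trait] = curve
        rows.append({"phenotype": trait, "max_r2": curve.max_r2, "n_rsnps": curve.optimal_k})
    summary = pd.DataFrame(rows, columns=["phenotype", "max_r2", "n_rsnps"])
    return optimal, curves, summary
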