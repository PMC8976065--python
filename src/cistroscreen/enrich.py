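"""Single-sample GSEA scoring and moderated permutation statistics.

``ssgsea_score`` implements the rank-weighted single-sample enrichment
score: with genes ranked by expression (descending), rank weight
``r_i = N - position_i + 1`` and exponent ``alpha`` (0.25 by default, the
conventional single-sample GSEA weighting), the score is the total sum of
the gap between the weighted in-set ECDF and the unweighted out-of-set ECDF:

    ES = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
    P_out(i) = |{j<=i, j not in S}| / (N - |S|)

``samroc_stat`` is a moderated mean-difference statistic
``d = (mean_A - mean_B) / (s + s0)`` with a variance-stabilising fudge
factor s0 (the per-run median of the per-set scale by default); inference is
two-sided by permutation of group labels, exhaustive when the number of
label splits is small, with Benjamini-Hochberg q-values on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SsgseaConfig",
    "SamrocResult",
    "ssgsea_score",
    "ssgsea_matrix",
    "normalize_scores",
    "samroc_stat",
    "permutation_p",
    "samroc_analysis",
    "bh_fdr",
    "common_pathways",
    "ora_hypergeometric",
]


@dataclass(frozen=True)
class SsgseaConfig:
    """Rank-weight exponent and normalization policy for ssGSEA."""

    alpha: float = 0.25
    normalization: str = "global_minmax"  # or "per_set_minmax"

    def __post_init__(self):
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.normalization not in ("global_minmax", "per_set_minmax"):
            raise ConfigError(f"unknown normalization '{self.normalization}'")


def ssgsea_score(
    expression: Mapping[str, float] | pd.Series,
    gene_set: Iterable[str],
    config: SsgseaConfig = SsgseaConfig(),
) -> float:
    """Enrichment score of one gene set in one sample's expression profile.

    Ranking is by expression descending with ties broken by gene id, so the
    score is deterministic and invariant under any strictly monotone
    transform of the expression values.  Set members absent from the profile
    are ignored; the effective set must be a nonempty proper subset of the
    profile's genes.
    """
    series = pd.Series(expression, dtype=float)
    if series.index.duplicated().any():
        raise DataError("duplicate gene ids in the expression profile")
    n = len(series)
    members = set(gene_set) & set(series.index)
    if not members:
        raise DataError("gene set has no overlap with the expression profile")
    if len(members) == n:
        raise DataError("gene set equals the expression universe (P_out undefined)")

    order = sorted(series.index, key=lambda g: (-series[g], g))
    in_set = np.fromiter((g in members for g in order), dtype=bool, count=n)
    ranks = np.arange(n, 0, -1, dtype=float)  # r_i = N - position_i + 1
    weights = ranks**config.alpha
    w_in = np.where(in_set, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set) / (n - len(members))
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    collection: GeneSetCollection,
    config: SsgseaConfig = SsgseaConfig(),
) -> pd.DataFrame:
    """Gene-set x sample matrix of enrichment scores."""
    rows = {}
    for name in collection:
        members = collection.members(name)
        rows[name] = [
            ssgsea_score(expr.values[s], members, config) for s in expr.samples
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.samples)


def normalize_scores(scores: pd.DataFrame, per_set: bool = False) -> pd.DataFrame:
    """Min-max scale scores to [0, 1] using the global matrix extrema.

    ``per_set=True`` scales each row independently instead.
    """
    if per_set:
        lo = scores.min(axis=1)
        hi = scores.max(axis=1)
        if (hi == lo).any():
            raise DataError("constant score row cannot be min-max normalized")
        return scores.sub(lo, axis=0).div(hi - lo, axis=0)
    lo = float(scores.to_numpy().min())
    hi = float(scores.to_numpy().max())
    if hi == lo:
        raise DataError("constant score matrix cannot be min-max normalized")
    return (scores - lo) / (hi - lo)


def _pooled_scale(a: np.ndarray, b: np.ndarray) -> float:
    """s = sqrt((1/nA + 1/nB) * pooled within-group variance)."""
    na, nb = len(a), len(b)
    pooled_var = (
        ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    ) / (na + nb - 2)
    return math.sqrt((1.0 / na + 1.0 / nb) * pooled_var)


def samroc_stat(
    group_a: Sequence[float], group_b: Sequence[float], s0: float = 0.0
) -> float:
    """Moderated mean-difference statistic d = (mean_A - mean_B) / (s + s0)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("both groups need >= 2 observations")
    if s0 < 0:
        raise ConfigError("s0 must be >= 0")
    s = _pooled_scale(a, b)
    if s + s0 == 0:
        raise DataError("zero scale: both groups constant and s0 = 0")
    return float((a.mean() - b.mean()) / (s + s0))


_EXHAUSTIVE_LIMIT = 200


def permutation_p(
    d_observed: float,
    pooled: Sequence[float],
    n_a: int,
    s0: float = 0.0,
    n_permutations: int = 1_000,
    seed: int | None = 0,
) -> float:
    """Two-sided permutation p-value for the moderated statistic.

    All C(n, n_a) label splits are enumerated when that count is at most
    200 (the observed split is one of them); otherwise ``n_permutations``
    random splits are drawn.  With the +1 smoothing
    p = (1 + #{|d*| >= |d|}) / (1 + #splits), so p is never exactly 0.
    """
    pooled = np.asarray(pooled, dtype=float)
    n = len(pooled)
    if not 2 <= n_a <= n - 2:
        raise DataError("each group needs >= 2 observations")
    abs_obs = abs(d_observed)
    tol = 1e-12 * max(1.0, abs_obs)

    def stat(idx_a: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[list(idx_a)] = True
        a, b = pooled[mask], pooled[~mask]
        s = _pooled_scale(a, b)
        if s + s0 == 0:
            return 0.0
        return (a.mean() - b.mean()) / (s + s0)

    if math.comb(n, n_a) <= _EXHAUSTIVE_LIMIT:
        splits = [np.array(c) for c in combinations(range(n), n_a)]
    else:
        rng = np.random.default_rng(seed)
        splits = [rng.permutation(n)[:n_a] for _ in range(n_permutations)]
    exceed = sum(1 for idx in splits if abs(stat(idx)) >= abs_obs - tol)
    return (1 + exceed) / (1 + len(splits))


@dataclass
class SamrocResult:
    """Per-set moderated statistics with permutation p and BH q."""

    table: pd.DataFrame  # columns: mean_a, mean_b, s, d, p, q
    s0: float
    group_a: str
    group_b: str

    def significant(self, fdr: float) -> set[str]:
        """Sets with q strictly below the FDR threshold."""
        return set(self.table.index[self.table["q"] < fdr])


def samroc_analysis(
    scores: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    s0: float | None = None,
    n_permutations: int = 1_000,
    seed: int = 0,
) -> SamrocResult:
    """Moderated differential-pathway analysis of a set x sample score matrix.

    The fudge factor s0 defaults to the median of the per-set pooled scale s
    over all sets in the run.  Permutation p-values and BH q-values are
    attached per set.
    """
    samples_a = [s for s in scores.columns if groups.get(s) == group_a]
    samples_b = [s for s in scores.columns if groups.get(s) == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise DataError("each group needs >= 2 samples")
    a = scores[samples_a].to_numpy(dtype=float)
    b = scores[samples_b].to_numpy(dtype=float)

    s_values = np.array(
        [_pooled_scale(a[i], b[i]) for i in range(len(scores.index))]
    )
    if s0 is None:
        s0 = float(np.median(s_values))
    if s0 < 0:
        raise ConfigError("s0 must be >= 0")

    rows = []
    for i, name in enumerate(scores.index):
        scale = s_values[i] + s0
        if scale == 0:
            raise DataError(f"zero scale for set '{name}' with s0 = 0")
        d = (a[i].mean() - b[i].mean()) / scale
        p = permutation_p(
            d,
            np.concatenate([a[i], b[i]]),
            n_a=len(samples_a),
            s0=s0,
            n_permutations=n_permutations,
            seed=seed + i,
        )
        rows.append((name, a[i].mean(), b[i].mean(), s_values[i], d, p))
    table = pd.DataFrame(
        rows, columns=["set", "mean_a", "mean_b", "s", "d", "p"]
    ).set_index("set")
    table["q"] = bh_fdr(table["p"].to_numpy())
    return SamrocResult(table=table, s0=s0, group_a=group_a, group_b=group_b)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def common_pathways(
    result_1: SamrocResult,
    result_2: SamrocResult,
    fdr_1: float = 0.075,
    fdr_2: float = 0.001,
) -> pd.DataFrame:
    """Gene sets significant in both runs (q strictly below each threshold).

    Returns the intersection with both runs' d, p and q, sorted by the first
    run's |d| descending.
    """
    shared = sorted(result_1.significant(fdr_1) & result_2.significant(fdr_2))
    t1 = result_1.table.loc[shared, ["d", "p", "q"]].add_suffix("_1")
    t2 = result_2.table.loc[shared, ["d", "p", "q"]].add_suffix("_2")
    out = pd.concat([t1, t2], axis=1)
    return out.reindex(out["d_1"].abs().sort_values(ascending=False).index)


def ora_hypergeometric(
    gene_list: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation p per gene set (upper-tail hypergeometric) + BH q.

    A local stand-in for web-service pathway over-representation analysis:
    p = P(overlap >= observed) when drawing |list| genes from the universe
    without replacement against each set's in-universe members.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list <= universe:
        raise DataError("gene list is not a subset of the universe")
    m = len(universe)
    n_draw = len(gene_list)
    rows = []
    for name in collection:
        members = set(collection.members(name)) & universe
        k = len(gene_list & members)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_draw))
        rows.append((name, len(members), k, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "p"]
    ).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")
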