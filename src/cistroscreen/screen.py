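"""Expression-side filters and the integrative candidate-prioritization chain.

The chain reproduces a threshold-rule multi-omic screen: differential
expression by mean fold change (fpkm floor 3.0, fold change 4.0, strict
inequalities), the top-30 head of each ranked list, a 5%-or-more cohort
alteration-frequency filter, the requirement of an AR-binding site in either
condition, and an external qRT-PCR validation flag.  A gene is a final
candidate only if it clears every filter; records keep per-filter provenance
so the attrition is auditable.

Also included is the bespoke microarray re-analysis filter: probe collapse
by per-gene maximum after dropping poor-quality probes, and the
ANOVA + fold-change + confidence-interval-overlap signature filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFilterConfig",
    "AblFilterConfig",
    "CandidateRecord",
    "DEResult",
    "de_filter",
    "top_n",
    "alteration_filter",
    "integrate_candidates",
    "collapse_probes",
    "abl_signature_filter",
]


@dataclass(frozen=True)
class DEFilterConfig:
    """Thresholds for the differential-expression screen.

    ``min_fpkm`` applies to the mean of the upregulated condition (strict >),
    ``min_fc`` to the pseudocounted mean fold change (strict >).  The
    microarray re-analysis mode of the same screen uses min_fc 1.5.
    """

    min_fpkm: float = 3.0
    min_fc: float = 4.0
    pseudocount: float = 0.01
    top_n: int = 30
    rank_metric: str = "fold_change"  # or "mean_difference"

    def __post_init__(self):
        if self.min_fc <= 1:
            raise ConfigError("min_fc must be > 1")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.rank_metric not in ("fold_change", "mean_difference"):
            raise ConfigError(f"unknown rank metric '{self.rank_metric}'")


@dataclass(frozen=True)
class AblFilterConfig:
    """Thresholds for the androgen-ablated signature filter."""

    p_max: float = 0.001
    fc_min: float = 2.5
    ci_overlap_max: float = 0.10
    ci_level: float = 0.95
    overlap_norm: str = "shorter"  # or "union"

    def __post_init__(self):
        if not 0 < self.p_max <= 1:
            raise ConfigError("p_max must lie in (0, 1]")
        if self.fc_min <= 0:
            raise ConfigError("fc_min must be > 0")
        if not 0 <= self.ci_overlap_max <= 1:
            raise ConfigError("ci_overlap_max must lie in [0, 1]")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.overlap_norm not in ("shorter", "union"):
            raise ConfigError(f"unknown overlap normalization '{self.overlap_norm}'")


@dataclass
class CandidateRecord:
    """One gene's provenance through every screening filter."""

    gene: str
    direction: str  # up_in_<cond> | down_in_<cond>
    de_rank: int
    de_fold_change: float
    alteration_pass: bool
    max_alteration_percent: float | None
    arbs_pass: bool
    arbs_conditions: tuple[str, ...]
    validation_pass: bool

    @property
    def final_pass(self) -> bool:
        return self.alteration_pass and self.arbs_pass and self.validation_pass

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "direction": self.direction,
            "de_rank": self.de_rank,
            "de_fold_change": self.de_fold_change,
            "alteration_pass": self.alteration_pass,
            "max_alteration_percent": self.max_alteration_percent,
            "arbs_pass": self.arbs_pass,
            "arbs_conditions": ",".join(self.arbs_conditions),
            "validation_pass": self.validation_pass,
            "final_pass": self.final_pass,
        }


@dataclass
class DEResult:
    """Ranked up/down gene lists for an ordered condition pair.

    ``up`` holds (gene, fold change) for genes upregulated in ``treated``
    relative to ``baseline``, ranked by fold change descending (ties broken
    by gene id); ``down`` is symmetric.
    """

    baseline: str
    treated: str
    up: list[tuple[str, float]] = field(default_factory=list)
    down: list[tuple[str, float]] = field(default_factory=list)

    @property
    def up_genes(self) -> list[str]:
        return [g for g, _ in self.up]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, _ in self.down]


def de_filter(
    expr: ExpressionMatrix,
    baseline: str,
    treated: str,
    config: DEFilterConfig = DEFilterConfig(),
) -> DEResult:
    """Threshold-rule differential expression between two conditions.

    A gene is up in ``treated`` iff its treated mean exceeds ``min_fpkm``
    (strict) and the pseudocounted mean fold change exceeds ``min_fc``
    (strict); symmetric for down.  The expression floor applies to the
    upregulated condition only.
    """
    mean_b = expr.condition_means(baseline)
    mean_t = expr.condition_means(treated)
    eps = config.pseudocount
    result = DEResult(baseline=baseline, treated=treated)

    fc_up = (mean_t + eps) / (mean_b + eps)
    up_mask = (mean_t > config.min_fpkm) & (fc_up > config.min_fc)
    fc_down = (mean_b + eps) / (mean_t + eps)
    down_mask = (mean_b > config.min_fpkm) & (fc_down > config.min_fc)

    if config.rank_metric == "fold_change":
        up_key, down_key = fc_up, fc_down
    else:
        up_key, down_key = mean_t - mean_b, mean_b - mean_t
    result.up = sorted(
        ((g, float(fc_up[g])) for g in mean_t.index[up_mask]),
        key=lambda gv: (-up_key[gv[0]], gv[0]),
    )
    result.down = sorted(
        ((g, float(fc_down[g])) for g in mean_t.index[down_mask]),
        key=lambda gv: (-down_key[gv[0]], gv[0]),
    )
    return result


def top_n(ranked: Sequence[tuple[str, float]], n: int = 30) -> list[tuple[str, float]]:
    """Head of a ranked (gene, score) list; boundary ties resolved by gene id."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    ordered = sorted(ranked, key=lambda gv: (-gv[1], gv[0]))
    return ordered[:n]


def alteration_filter(
    genes: Iterable[str],
    table: pd.DataFrame,
    min_freq: float = 5.0,
) -> dict[str, tuple[bool, float | None]]:
    """Gene passes iff its max percent-altered over cohorts is >= min_freq.

    The boundary is inclusive ("5% or more").  Genes missing from the table
    fail with a logged warning and a None percent.
    """
    if (table.to_numpy() < 0).any():
        raise DataError("alteration table contains negative percentages")
    out: dict[str, tuple[bool, float | None]] = {}
    for g in genes:
        if g not in table.index:
            logger.warning("gene '%s' missing from the alteration table; fails", g)
            out[g] = (False, None)
            continue
        mx = float(table.loc[g].max())
        out[g] = (mx >= min_freq, mx)
    return out


def integrate_candidates(
    up_list: Sequence[tuple[str, float]],
    down_list: Sequence[tuple[str, float]],
    alteration: Mapping[str, tuple[bool, float | None]],
    bound_conditions: Mapping[str, Sequence[str]],
    validation_flags: Mapping[str, bool] | None = None,
    conditions: tuple[str, str] = ("AD", "CR"),
) -> list[CandidateRecord]:
    """Carry every top-ranked DE gene through the remaining filters.

    ``bound_conditions`` maps gene -> conditions in which it carries an
    AR-binding site (empty / absent -> no site, arbs_pass False).
    ``validation_flags`` records external qRT-PCR reproducibility; genes
    absent from the map are treated as validated (only known failures are
    flagged).  final_pass requires every upstream flag.
    """
    validation_flags = dict(validation_flags or {})
    records: list[CandidateRecord] = []
    for direction, ranked in (
        (f"up_in_{conditions[1]}", up_list),
        (f"down_in_{conditions[1]}", down_list),
    ):
        for rank, (gene, fc) in enumerate(ranked, start=1):
            alt_pass, alt_pct = alteration.get(gene, (False, None))
            conds = tuple(bound_conditions.get(gene, ()))
            records.append(
                CandidateRecord(
                    gene=gene,
                    direction=direction,
                    de_rank=rank,
                    de_fold_change=float(fc),
                    alteration_pass=bool(alt_pass),
                    max_alteration_percent=alt_pct,
                    arbs_pass=bool(conds),
                    arbs_conditions=conds,
                    validation_pass=bool(validation_flags.get(gene, True)),
                )
            )
    return records


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, str] | Iterable[tuple[str, str]],
    quality_flags: Mapping[str, str],
    drop_flags: tuple[str, ...] = ("A", "M"),
) -> pd.DataFrame:
    """Collapse a probe x sample matrix to genes by per-sample maximum.

    Probes carrying a poor-quality flag (absent signal 'A' or high-background
    'M') are dropped first; genes left with no surviving probe disappear.
    A probe mapped to more than one gene is an error.
    """
    if isinstance(probe_to_gene, Mapping):
        pairs = list(probe_to_gene.items())
    else:
        pairs = list(probe_to_gene)
    mapping: dict[str, str] = {}
    for probe, gene in pairs:
        if probe in mapping and mapping[probe] != gene:
            raise DataError(f"probe '{probe}' mapped to multiple genes")
        mapping[probe] = gene

    surviving = [
        p
        for p in probe_matrix.index
        if quality_flags.get(p) not in drop_flags
    ]
    unmapped = [p for p in surviving if p not in mapping]
    if unmapped:
        raise DataError(f"retained probes without a gene mapping: {unmapped[:5]}")
    if not surviving:
        return probe_matrix.iloc[0:0].copy()
    sub = probe_matrix.loc[surviving]
    genes = pd.Series({p: mapping[p] for p in surviving})
    collapsed = sub.groupby(genes).max()
    collapsed.index.name = "gene_id"
    return collapsed


def _mean_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    """t-based confidence interval for the mean; a point when variance is 0."""
    n = len(values)
    m = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return m, m
    half = stats.t.ppf(0.5 + level / 2, df=n - 1) * sd / np.sqrt(n)
    return m - half, m + half


def _ci_overlap_fraction(
    ci1: tuple[float, float], ci2: tuple[float, float], norm: str
) -> float:
    inter = max(0.0, min(ci1[1], ci2[1]) - max(ci1[0], ci2[0]))
    len1, len2 = ci1[1] - ci1[0], ci2[1] - ci2[0]
    if norm == "shorter":
        denom = min(len1, len2)
    else:
        denom = (max(ci1[1], ci2[1]) - min(ci1[0], ci2[0]))
    if denom == 0.0:
        # degenerate point CI (zero within-group variance): overlap is 0
        # unless the group means coincide
        m1 = (ci1[0] + ci1[1]) / 2
        m2 = (ci2[0] + ci2[1]) / 2
        return 1.0 if m1 == m2 else 0.0
    return inter / denom


def abl_signature_filter(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    target_group: str,
    comparator_group: str,
    config: AblFilterConfig = AblFilterConfig(),
) -> pd.DataFrame:
    """Signature filter: one-way ANOVA, fold change, and CI-overlap criteria.

    Per gene: (i) one-way ANOVA F-test across all groups with p <= p_max,
    (ii) mean fold change of ``target_group`` over ``comparator_group``
    strictly above ``fc_min``, and (iii) overlap of the two groups' t-based
    CIs for the mean at most ``ci_overlap_max`` of the shorter interval.
    Returns a per-gene DataFrame with columns p, fold_change, ci_overlap and
    passed.
    """
    group_samples: dict[str, list[str]] = {}
    for sample in matrix.columns:
        if sample not in groups:
            raise DataError(f"sample '{sample}' has no group label")
        group_samples.setdefault(groups[sample], []).append(sample)
    if len(group_samples) < 2:
        raise DataError("need >= 2 groups")
    for grp in (target_group, comparator_group):
        if grp not in group_samples:
            raise DataError(f"group '{grp}' has no samples")
        if len(group_samples[grp]) < 2:
            raise DataError(f"group '{grp}' needs >= 2 samples for the CI criterion")

    arrays = {g: matrix[ss].to_numpy(dtype=float) for g, ss in group_samples.items()}
    rows = []
    for i, gene in enumerate(matrix.index):
        per_group = [arrays[g][i] for g in group_samples]
        if all(np.ptp(v) == 0 for v in per_group) and len({v[0] for v in per_group}) == 1:
            p = 1.0  # all values identical: no evidence of any effect
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                f_p = stats.f_oneway(*per_group).pvalue
            # zero within-group variance makes F infinite: p -> 0
            p = 0.0 if np.isnan(f_p) else float(f_p)
        tv = arrays[target_group][i]
        cv = arrays[comparator_group][i]
        mean_c = float(np.mean(cv))
        fc = float(np.mean(tv)) / mean_c if mean_c != 0 else np.inf
        overlap = _ci_overlap_fraction(
            _mean_ci(tv, config.ci_level),
            _mean_ci(cv, config.ci_level),
            config.overlap_norm,
        )
        passed = (
            p <= config.p_max
            and fc > config.fc_min
            and overlap <= config.ci_overlap_max
        )
        rows.append((gene, p, fc, overlap, passed))
    out = pd.DataFrame(
        rows, columns=["gene", "p", "fold_change", "ci_overlap", "passed"]
    ).set_index("gene")
    return out
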