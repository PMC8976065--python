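"""Synthetic two-condition cistrome / transcriptome / alteration benchmark data.

Everything downstream of read mapping in the screening pipeline can be
exercised on data generated here, with a machine-readable record of the
planted truth.  The generator emulates the structure of a paired
androgen-dependent (AD) vs castration-resistant (CR) xenograft design:
three ChIP-seq replicates per condition whose peak calls contain designated
positive/negative control loci, genes planted as condition-exclusive,
shared, or unbound, log-normal expression with planted fold changes, and
cohort alteration-frequency tables.

Randomness is organised as one pseudo-random stream per output artifact,
derived from the master seed by stable labelled sub-seeding, so adding a new
generator never shifts the draws of existing ones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cistrome import CalibrationSpec, Interval
from .errors import CapacityError, ConfigError, DataError
from .io import (
    ExpressionMatrix,
    GeneModel,
    GeneSetCollection,
    Peak,
    write_expression_tsv,
    write_gene_table,
    write_gmt,
    write_narrowpeak,
)

__all__ = [
    "TruthConfig",
    "TruthTable",
    "ControlLocus",
    "CistromeBundle",
    "SyntheticBundle",
    "allocate_counts",
    "generate_genome",
    "plant_truth",
    "generate_cistrome",
    "generate_expression",
    "generate_alteration_table",
    "generate_gene_sets",
    "simulate_bundle",
]

PLANTED_SET_NAME = "PLANTED_COHERENT"

_CLASS_ORDER = ("exclusive_a", "exclusive_b", "shared", "unbound")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Independent stream per artifact: master seed + CRC32 of the label."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class ControlLocus:
    """A control interval with per-sample planted q-values.

    role 'positive' mimics an androgen-responsive enhancer that a working
    ChIP must call; role 'negative' mimics a housekeeping promoter that it
    must not.  Samples absent from ``q_by_sample`` get no peak at the locus.
    """

    interval: Interval
    role: str
    q_by_sample: Mapping[str, float]

    def __post_init__(self):
        if self.role not in ("positive", "negative"):
            raise ConfigError(f"control role must be positive|negative, got {self.role}")


@dataclass(frozen=True)
class TruthConfig:
    """Study-design parameters for the synthetic benchmark.

    Defaults reflect the emulated design: two conditions with three
    replicates each, a 400-bp peak width standing in for MACS calls, the
    0.129 q-value separation point between true and non-specific control
    peaks, and a 20-kb promoter window.  Noise defaults (10% replicate
    dropout, 5 spurious peaks per Mb per sample, log-normal sigma 0.25 for
    expression) are stipulated realistic levels, not literature estimates.
    """

    n_genes: int
    chrom_sizes: Mapping[str, int]
    frac_exclusive_a: float = 0.3
    frac_exclusive_b: float = 0.2
    frac_shared: float = 0.4
    frac_unbound: float = 0.1
    replicates_per_condition: int = 3
    replicate_dropout: float = 0.1
    noise_peak_rate: float = 5.0
    control_loci: tuple[ControlLocus, ...] | None = None
    de_config: Mapping[str, tuple[str, float, float]] = field(default_factory=dict)
    alteration_config: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0
    conditions: tuple[str, str] = ("AD", "CR")
    peak_width: int = 400
    q_separation: float = 0.129
    upstream_window: int = 20_000
    min_gene_gap: int = 45_000
    edge_margin: int = 1_000

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must be nonempty")
        fracs = (
            self.frac_exclusive_a,
            self.frac_exclusive_b,
            self.frac_shared,
            self.frac_unbound,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError(f"class fractions sum to {sum(fracs)}, expected 1")
        if not 0 <= self.replicate_dropout <= 1:
            raise ConfigError("replicate_dropout must lie in [0, 1]")
        if self.replicates_per_condition < 1:
            raise ConfigError("replicates_per_condition must be >= 1")
        if self.noise_peak_rate < 0:
            raise ConfigError("noise_peak_rate must be >= 0")
        if not 0 < self.q_separation < 1:
            raise ConfigError("q_separation must lie in (0, 1)")
        if self.peak_width < 2:
            raise ConfigError("peak_width must be >= 2")

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (
            self.frac_exclusive_a,
            self.frac_exclusive_b,
            self.frac_shared,
            self.frac_unbound,
        )

    def class_label(self, key: str) -> str:
        """Map internal class key to a condition-labelled name."""
        return {
            "exclusive_a": f"exclusive_{self.conditions[0]}",
            "exclusive_b": f"exclusive_{self.conditions[1]}",
        }.get(key, key)


@dataclass
class TruthTable:
    """Planted per-gene truth: binding class, DE class, alteration status."""

    binding: dict[str, str]
    de: dict[str, str] = field(default_factory=dict)
    altered: dict[str, bool] = field(default_factory=dict)

    def genes_in_class(self, cls: str) -> set[str]:
        return {g for g, c in self.binding.items() if c == cls}

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.binding)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "binding_class": [self.binding[g] for g in genes],
                "de_class": [self.de.get(g, "none") for g in genes],
                "altered": [bool(self.altered.get(g, False)) for g in genes],
            }
        )


def allocate_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of ``n * fractions`` to integers summing to n.

    Ties in the fractional remainders are broken by position, so the
    allocation is deterministic for any fractional configuration.
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("fractions must sum to 1")
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    shortfall = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in remainders[:shortfall]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# genome and truth


def generate_genome(config: TruthConfig) -> list[GeneModel]:
    """Place non-overlapping gene bodies with strand and TSS.

    Genes are laid down left to right per chromosome with at least
    ``min_gene_gap`` between bodies (wide enough that promoter windows of
    neighbours never touch), at least ``edge_margin`` from chromosome edges.
    Raises CapacityError when the genome cannot hold ``n_genes``.
    """
    rng = _rng(config.seed, "genome")
    genes: list[GeneModel] = []
    i = 0
    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        pos = config.edge_margin
        while i < config.n_genes:
            length = int(rng.integers(1_000, 10_001))
            jitter = int(rng.integers(0, 5_001))
            start = pos + (jitter if genes and genes[-1].chrom == chrom else 0)
            if start + length + config.edge_margin > size:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"G{i:05d}"
            genes.append(
                GeneModel(
                    gene_id=gid,
                    symbol=f"SYN{i:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    strand=strand,
                )
            )
            pos = start + length + config.min_gene_gap
            i += 1
        if i >= config.n_genes:
            break
    if i < config.n_genes:
        raise CapacityError(
            f"genome can hold only {i} of the requested {config.n_genes} genes "
            f"without overlap"
        )
    return genes


def plant_truth(genes: Sequence[GeneModel], config: TruthConfig) -> TruthTable:
    """Assign each gene a binding class by largest-remainder allocation."""
    counts = allocate_counts(len(genes), config.fractions)
    rng = _rng(config.seed, "truth")
    order = rng.permutation(len(genes))
    binding: dict[str, str] = {}
    idx = 0
    for cls, k in zip(_CLASS_ORDER, counts):
        label = config.class_label(cls)
        for j in order[idx : idx + k]:
            binding[genes[j].gene_id] = label
        idx += k
    return TruthTable(binding=binding)


# ---------------------------------------------------------------------------
# cistrome

_CTRL_CHROM = "chrCtrl"


@dataclass
class CistromeBundle:
    """Per-sample peak sets plus the control design needed to calibrate."""

    peaks: dict[str, list[Peak]]
    calibration: CalibrationSpec
    samples_by_condition: dict[str, list[str]]
    control_samples: list[str]
    q_separation: float


def _default_control_loci(
    config: TruthConfig, condition_samples: list[str], ctrl_samples: list[str]
) -> tuple[ControlLocus, ...]:
    """Positive/negative control pair on a dedicated control contig.

    Condition samples carry a confident peak at the positive locus; the
    negative (no-signal) sample carries one exactly at the separation point,
    so calibration recovers ``q_separation`` as the threshold.
    """
    rng = _rng(config.seed, "controls")
    sep = config.q_separation
    pos_q = {s: float(rng.uniform(0.2, 0.8) * sep) for s in condition_samples}
    pos_q.update({s: sep for s in ctrl_samples})
    neg_q = {
        s: float(sep + rng.uniform(0.2, 0.8) * (1 - sep))
        for s in condition_samples + ctrl_samples
        if rng.random() < 0.5
    }
    w = config.peak_width
    positive = ControlLocus(Interval(_CTRL_CHROM, 10_000, 10_000 + w), "positive", pos_q)
    negative = ControlLocus(Interval(_CTRL_CHROM, 50_000, 50_000 + w), "negative", neg_q)
    return (positive, negative)


def _place_site(gene: GeneModel, config: TruthConfig, rng: np.random.Generator) -> int:
    """Sample a peak start inside the gene body or its upstream window."""
    w = config.peak_width
    regions = [(gene.start, gene.end - w)]
    if gene.strand == "+":
        up = (max(0, gene.tss - config.upstream_window), gene.tss - w)
    else:
        up = (gene.tss + 1, gene.tss + 1 + config.upstream_window - w)
    if up[1] > up[0]:
        regions.append(up)
    lo, hi = regions[int(rng.integers(0, len(regions)))]
    return int(rng.integers(lo, hi + 1))


def generate_cistrome(
    genes: Sequence[GeneModel], truth: TruthTable, config: TruthConfig
) -> CistromeBundle:
    """Emit per-sample narrowPeak-style peak sets realising the planted truth.

    Each planted bound gene gets one binding site (shared across replicates,
    with a small positional jitter well under half the peak width so
    replicate peaks always overlap).  Condition mean signals are drawn so
    shared genes sit at cross-condition fold change inside (0.5, 2) while
    exclusive genes are present in only their condition.  Spurious peaks are
    placed only in intergenic space at least ``upstream_window`` from any
    gene body, so they can never annotate a gene.
    """
    missing = {g.gene_id for g in genes} - set(truth.binding)
    if missing:
        raise DataError(f"truth does not cover genes: {sorted(missing)[:5]}")

    cond_a, cond_b = config.conditions
    samples_by_condition = {
        c: [f"{c}_rep{i + 1}" for i in range(config.replicates_per_condition)]
        for c in config.conditions
    }
    condition_samples = [s for ss in samples_by_condition.values() for s in ss]
    ctrl_samples = ["ctrl_rep1"]
    peaks: dict[str, list[Peak]] = {s: [] for s in condition_samples + ctrl_samples}

    sig_rng = _rng(config.seed, "signals")
    site_rng = _rng(config.seed, "sites")
    drop_rng = _rng(config.seed, "dropout")
    q_rng = _rng(config.seed, "qvalues")
    w = config.peak_width

    for gene in genes:
        cls = truth.binding[gene.gene_id]
        if cls == "unbound":
            continue
        if cls == f"exclusive_{cond_a}":
            means = {cond_a: float(sig_rng.uniform(5, 15))}
        elif cls == f"exclusive_{cond_b}":
            means = {cond_b: float(sig_rng.uniform(5, 15))}
        else:  # shared: fold change strictly inside (0.5, 2)
            sa = float(sig_rng.uniform(5, 15))
            ratio = float(sig_rng.uniform(0.625, 1.6))
            means = {cond_a: sa, cond_b: sa / ratio}
        site = _place_site(gene, config, site_rng)
        for cond, mean in means.items():
            for sample in samples_by_condition[cond]:
                if drop_rng.random() < config.replicate_dropout:
                    continue
                jitter = int(site_rng.integers(-(w // 4), w // 4 + 1))
                start = max(0, site + jitter)
                q = float(q_rng.uniform(0.2, 0.8) * config.q_separation)
                peaks[sample].append(
                    Peak(
                        chrom=gene.chrom,
                        start=start,
                        end=start + w,
                        name=f"{gene.gene_id}_{sample}",
                        signal=mean,
                        q=q,
                        sample_id=sample,
                    )
                )

    loci = config.control_loci
    if loci is None:
        loci = _default_control_loci(config, condition_samples, ctrl_samples)
    positive = [l for l in loci if l.role == "positive"]
    negative = [l for l in loci if l.role == "negative"]
    if len(positive) != 1 or len(negative) != 1:
        raise ConfigError("control_loci must contain exactly one positive and one negative locus")
    for locus in loci:
        for sample, q in locus.q_by_sample.items():
            iv = locus.interval
            peaks.setdefault(sample, []).append(
                Peak(iv.chrom, iv.start, iv.end, f"{locus.role}_ctrl_{sample}",
                     signal=10.0, q=float(q), sample_id=sample)
            )

    _add_noise_peaks(peaks, genes, config)
    for sample in peaks:
        peaks[sample].sort(key=lambda p: (p.chrom, p.start, p.end))

    calibration = CalibrationSpec(
        positive_locus=positive[0].interval,
        negative_locus=negative[0].interval,
        positive_samples=tuple(condition_samples),
        negative_samples=tuple(ctrl_samples),
    )
    return CistromeBundle(
        peaks=peaks,
        calibration=calibration,
        samples_by_condition=samples_by_condition,
        control_samples=ctrl_samples,
        q_separation=config.q_separation,
    )


def _add_noise_peaks(
    peaks: dict[str, list[Peak]], genes: Sequence[GeneModel], config: TruthConfig
) -> None:
    if config.noise_peak_rate == 0:
        return
    rng = _rng(config.seed, "noise")
    w = config.peak_width
    margin = config.upstream_window + w
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        forbidden.setdefault(g.chrom, []).append(
            (max(0, g.start - margin), g.end + margin)
        )
    for c in forbidden:
        forbidden[c].sort()

    for sample in sorted(peaks):
        for chrom in sorted(config.chrom_sizes):
            size = config.chrom_sizes[chrom]
            n = int(rng.poisson(config.noise_peak_rate * size / 1e6))
            placed = 0
            attempts = 0
            while placed < n and attempts < 50 * n:
                attempts += 1
                start = int(rng.integers(0, max(1, size - w)))
                if _in_forbidden(start, start + w, forbidden.get(chrom, [])):
                    continue
                q = float(rng.uniform(0.2, 0.8) * config.q_separation)
                peaks[sample].append(
                    Peak(chrom, start, start + w, f"noise_{sample}_{placed}",
                         signal=float(rng.uniform(1, 5)), q=q, sample_id=sample)
                )
                placed += 1


def _in_forbidden(start: int, end: int, regions: list[tuple[int, int]]) -> bool:
    import bisect

    i = bisect.bisect_right(regions, (start, end))
    for j in (i - 1, i):
        if 0 <= j < len(regions):
            lo, hi = regions[j]
            if start < hi and lo < end:
                return True
    return False


# ---------------------------------------------------------------------------
# expression, alterations, gene sets


def generate_expression(
    genes: Sequence[GeneModel],
    de_config: Mapping[str, tuple[str, float, float]],
    dispersion: float,
    n_samples: int,
    seed: int,
    conditions: tuple[str, str] = ("AD", "CR"),
    base_default: float = 10.0,
) -> tuple[ExpressionMatrix, dict[str, tuple[str, float]]]:
    """Log-normal expression around condition means with planted fold changes.

    ``de_config`` maps gene -> (condition, log2 fold change, base fpkm); the
    gene's mean in the named condition is base * 2**log2fc and ``base`` in the
    other.  Multiplicative noise is mean-one log-normal with sigma
    ``dispersion``, so planted genes realise their fold change in expectation
    and dispersion 0 gives the means exactly.
    """
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    for g, (cond, _fc, base) in de_config.items():
        if base <= 0:
            raise ConfigError(f"de_config base fpkm for {g} must be > 0")
        if cond not in conditions:
            raise ConfigError(f"de_config condition '{cond}' not in {conditions}")

    rng = _rng(seed, "expression")
    gene_ids = [g.gene_id for g in genes]
    means = pd.DataFrame(base_default, index=gene_ids, columns=list(conditions))
    # non-DE baseline varies across genes but is identical across conditions
    baseline = base_default * rng.lognormal(0.0, 0.5, size=len(gene_ids))
    for c in conditions:
        means[c] = baseline
    truth: dict[str, tuple[str, float]] = {}
    for g, (cond, log2fc, base) in de_config.items():
        if g not in means.index:
            raise DataError(f"de_config gene '{g}' not in the gene table")
        other = conditions[0] if cond == conditions[1] else conditions[1]
        means.loc[g, other] = base
        means.loc[g, cond] = base * 2.0 ** log2fc
        truth[g] = (cond, log2fc)

    samples, condition_map, cols = [], {}, []
    for c in conditions:
        for i in range(n_samples):
            s = f"{c}_expr{i + 1}"
            samples.append(s)
            condition_map[s] = c
            mean_col = means[c].to_numpy()
            if dispersion == 0:
                vals = mean_col.copy()
            else:
                z = rng.standard_normal(len(gene_ids))
                vals = mean_col * np.exp(dispersion * z - dispersion**2 / 2)
            cols.append(vals)
    df = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=samples)
    return ExpressionMatrix(df, condition_map), truth


def generate_alteration_table(
    genes: Sequence[str],
    alteration_config: Mapping[str, Mapping[str, float]],
    cohorts: Sequence[str],
    seed: int,
    background_max: float = 4.9,
) -> pd.DataFrame:
    """Percent-altered table (gene x cohort): planted genes at/above their
    configured floor, background genes drawn uniformly below 5%."""
    cohorts = list(cohorts)
    if not cohorts:
        raise ConfigError("cohort list must be nonempty")
    if not 0 <= background_max < 5.0:
        raise ConfigError("background_max must lie in [0, 5)")
    rng = _rng(seed, "alterations")
    genes = list(genes)
    table = pd.DataFrame(
        rng.uniform(0.0, background_max, size=(len(genes), len(cohorts))),
        index=genes,
        columns=cohorts,
    )
    for g, per_cohort in alteration_config.items():
        if g not in table.index:
            raise DataError(f"alteration_config gene '{g}' not in the gene list")
        for cohort, pct in per_cohort.items():
            if pct < 0:
                raise DataError(f"negative alteration percent for {g}/{cohort}")
            if cohort not in table.columns:
                raise DataError(f"unknown cohort '{cohort}'")
            table.loc[g, cohort] = float(pct)
    return table


def generate_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    planted_set: Sequence[str] | None,
    seed: int,
) -> GeneSetCollection:
    """Random gene sets plus an optional planted coherent set.

    The planted set (named ``PLANTED_COHERENT``) is intended to be paired
    with a coordinated expression shift of its members (e.g. via
    ``generate_expression``'s de_config), so that single-sample enrichment
    followed by the moderated statistic flags it.
    """
    genes = list(genes)
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ConfigError(f"invalid set size range {size_range}")
    if hi > len(genes):
        raise ConfigError(f"set size {hi} exceeds universe of {len(genes)} genes")
    rng = _rng(seed, "gene_sets")
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    if planted_set is not None:
        members = tuple(planted_set)
        if not members:
            raise ConfigError("planted set must be nonempty")
        if not set(members) <= set(genes):
            raise DataError("planted set members must be drawn from the universe")
        sets[PLANTED_SET_NAME] = ("planted coherent set", members)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = tuple(sorted(rng.choice(genes, size=size, replace=False)))
        sets[f"RANDOM_SET_{i:04d}"] = ("random set", members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class SyntheticBundle:
    """Everything a full pipeline run needs, with the planted truth attached."""

    config: TruthConfig
    genes: list[GeneModel]
    truth: TruthTable
    cistrome: CistromeBundle
    expression: ExpressionMatrix
    alterations: pd.DataFrame
    gene_sets: GeneSetCollection
    validation_flags: dict[str, bool]
    planted_candidates: set[str]
    paths: dict[str, str] = field(default_factory=dict)


def _default_candidate_design(
    truth: TruthTable, config: TruthConfig, n_candidates: int = 6
) -> tuple[dict, dict, dict, set[str]]:
    """Plant a candidate chain with decoys failing exactly one filter each.

    Candidates are bound genes that are strongly up in the second condition,
    frequently altered, and validation-positive.  Decoys: an unbound DE+altered
    gene, a bound DE gene below the alteration floor, and a bound DE+altered
    gene whose external validation failed.
    """
    cond_b = config.conditions[1]
    bound = sorted(
        truth.genes_in_class("shared")
        | truth.genes_in_class(f"exclusive_{cond_b}")
        | truth.genes_in_class(f"exclusive_{config.conditions[0]}")
    )
    unbound = sorted(truth.genes_in_class("unbound"))
    need = n_candidates + 2
    if len(bound) < need or len(unbound) < 1:
        raise ConfigError(
            "not enough bound/unbound genes to plant the candidate design"
        )
    candidates = bound[:n_candidates]
    decoy_no_alt, decoy_no_valid = bound[n_candidates : n_candidates + 2]
    decoy_unbound = unbound[0]

    de_config = {g: (cond_b, 3.0, 8.0) for g in candidates}
    de_config[decoy_no_alt] = (cond_b, 3.0, 8.0)
    de_config[decoy_no_valid] = (cond_b, 3.0, 8.0)
    de_config[decoy_unbound] = (cond_b, 3.0, 8.0)
    alteration_config = {g: {"cohort1": 7.5} for g in candidates}
    alteration_config[decoy_no_valid] = {"cohort1": 7.5}
    alteration_config[decoy_unbound] = {"cohort1": 7.5}
    validation = {decoy_no_valid: False}
    return de_config, alteration_config, validation, set(candidates)


def simulate_bundle(
    config: TruthConfig,
    outdir: str | Path | None = None,
    n_gene_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 30),
    expression_dispersion: float = 0.0,
) -> SyntheticBundle:
    """Generate a coherent multi-omic bundle (and optionally write it out).

    When ``config.de_config`` is empty a default planted candidate design is
    used (see ``_default_candidate_design``).  Written artifacts: narrowPeak
    per sample, the gene table, expression and alteration TSVs, a GMT file,
    validation flags, the flat truth TSV and a JSON run manifest.
    """
    genes = generate_genome(config)
    truth = plant_truth(genes, config)

    de_config = dict(config.de_config)
    alteration_config = {g: dict(v) for g, v in config.alteration_config.items()}
    validation: dict[str, bool] = {}
    planted_candidates: set[str] = set()
    if not de_config:
        de_config, alteration_config, validation, planted_candidates = (
            _default_candidate_design(truth, config)
        )

    cistrome = generate_cistrome(genes, truth, config)
    expression, de_truth = generate_expression(
        genes,
        de_config,
        dispersion=expression_dispersion,
        n_samples=config.replicates_per_condition,
        seed=config.seed,
        conditions=config.conditions,
    )
    truth.de = {
        g: f"up_in_{cond}" for g, (cond, fc) in de_truth.items() if fc > 0
    } | {g: f"down_in_{cond}" for g, (cond, fc) in de_truth.items() if fc < 0}
    alterations = generate_alteration_table(
        [g.gene_id for g in genes],
        alteration_config,
        cohorts=["cohort1", "cohort2"],
        seed=config.seed,
    )
    truth.altered = {
        g: bool(alterations.loc[g].max() >= 5.0) for g in alterations.index
    }
    planted_members = sorted(planted_candidates) or [g.gene_id for g in genes[:10]]
    gene_sets = generate_gene_sets(
        [g.gene_id for g in genes],
        n_sets=n_gene_sets,
        size_range=set_size_range,
        planted_set=planted_members,
        seed=config.seed,
    )

    bundle = SyntheticBundle(
        config=config,
        genes=genes,
        truth=truth,
        cistrome=cistrome,
        expression=expression,
        alterations=alterations,
        gene_sets=gene_sets,
        validation_flags=validation,
        planted_candidates=planted_candidates,
    )
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _write_bundle(bundle: SyntheticBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for sample, peaks in bundle.cistrome.peaks.items():
        p = outdir / f"{sample}.narrowPeak"
        write_narrowpeak(peaks, p)
        paths[f"peaks:{sample}"] = str(p)
    write_gene_table(bundle.genes, outdir / "genes.bed")
    paths["genes"] = str(outdir / "genes.bed")
    write_expression_tsv(bundle.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    bundle.alterations.to_csv(outdir / "alterations.tsv", sep="\t", index_label="gene_id")
    paths["alterations"] = str(outdir / "alterations.tsv")
    write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    paths["gene_sets"] = str(outdir / "gene_sets.gmt")
    flags = pd.DataFrame(
        sorted(bundle.validation_flags.items()), columns=["gene_id", "validated"]
    )
    flags.to_csv(outdir / "validation_flags.tsv", sep="\t", index=False)
    paths["validation_flags"] = str(outdir / "validation_flags.tsv")
    bundle.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(outdir / "truth.tsv")

    cal = bundle.cistrome.calibration
    manifest = {
        "seed": bundle.config.seed,
        "n_genes": bundle.config.n_genes,
        "conditions": list(bundle.config.conditions),
        "samples_by_condition": bundle.cistrome.samples_by_condition,
        "control_samples": bundle.cistrome.control_samples,
        "calibration": {
            "positive_locus": [cal.positive_locus.chrom, cal.positive_locus.start,
                               cal.positive_locus.end],
            "negative_locus": [cal.negative_locus.chrom, cal.negative_locus.start,
                               cal.negative_locus.end],
            "positive_samples": list(cal.positive_samples),
            "negative_samples": list(cal.negative_samples),
        },
        "planted_candidates": sorted(bundle.planted_candidates),
        "planted_gene_set": PLANTED_SET_NAME,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    paths["manifest"] = str(outdir / "manifest.json")
    bundle.paths = paths
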