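"""End-to-end screen orchestration from a single declarative config.

``run_screen`` executes the full chain — calibrate on control loci, filter
genome-wide, call replicate-consensus binding sites, annotate to genes,
classify exclusive/shared, summarise Venn and cross-study overlap, run the
differential-expression and alteration filters, integrate candidates, and
(optionally) run the enrichment screen — writing a report bundle atomically:
outputs appear under the configured directory only if every stage succeeded.
Re-running with identical config and inputs is bit-identical; a manifest
records the config hash, seed, package version and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .cistrome import (
    CalibrationSpec,
    Interval,
    annotate_arbs_to_genes,
    calibrate_q_threshold,
    call_consensus_arbs,
    classify_differential_genes,
    cross_study_overlap,
    filter_peaks,
    venn_counts,
)
from .enrich import (
    SsgseaConfig,
    common_pathways,
    normalize_scores,
    samroc_analysis,
    ssgsea_matrix,
)
from .errors import ConfigError, PipelineError
from .io import (
    read_expression_tsv,
    read_gene_table,
    read_gmt,
    read_narrowpeak,
    write_report,
)
from .screen import DEFilterConfig, alteration_filter, de_filter, integrate_candidates, top_n

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_screen"]

_THRESHOLD_DEFAULTS = {
    "q_cap": 0.25,
    "min_support": 2,
    "upstream_window": 20_000,
    "annotation_mode": "upstream",
    "fc_low": 0.5,
    "fc_high": 2.0,
    "signal_pseudocount": 0.01,
    "min_fpkm": 3.0,
    "min_fc": 4.0,
    "de_pseudocount": 0.01,
    "top_n": 30,
    "min_alteration": 5.0,
    "ssgsea_alpha": 0.25,
    "fdr_pair": (0.075, 0.001),
    "n_permutations": 1_000,
}


@dataclass
class RunConfig:
    """Declarative description of a full screening run.

    ``peaks`` maps condition -> {sample -> narrowPeak path}; ``conditions``
    orders them (baseline first, treated second).  ``thresholds`` carries the
    default screening thresholds; any key may be overridden.
    """

    conditions: tuple[str, str]
    peaks: dict[str, dict[str, str]]
    control_peaks: dict[str, str]
    genes: str
    expression: str
    expression_conditions: dict[str, str]
    alterations: str
    positive_locus: tuple[str, int, int]
    negative_locus: tuple[str, int, int]
    outdir: str
    seed: int = 0
    validation_flags: str | None = None
    reference_gene_lists: dict[str, str] = field(default_factory=dict)
    enrichment: dict[str, Any] | None = None
    thresholds: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.conditions = tuple(self.conditions)  # type: ignore[assignment]
        merged = dict(_THRESHOLD_DEFAULTS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    def to_canonical_dict(self) -> dict:
        d = {
            "conditions": list(self.conditions),
            "peaks": self.peaks,
            "control_peaks": self.control_peaks,
            "genes": self.genes,
            "expression": self.expression,
            "expression_conditions": self.expression_conditions,
            "alterations": self.alterations,
            "positive_locus": list(self.positive_locus),
            "negative_locus": list(self.negative_locus),
            "outdir": self.outdir,
            "seed": self.seed,
            "validation_flags": self.validation_flags,
            "reference_gene_lists": self.reference_gene_lists,
            "enrichment": self.enrichment,
            "thresholds": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in sorted(self.thresholds.items())
            },
        }
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def validate_config(config: RunConfig) -> list[str]:
    """Collect every violation rather than failing on the first."""
    errors: list[str] = []
    t = config.thresholds

    if len(config.conditions) != 2 or len(set(config.conditions)) != 2:
        errors.append("conditions must be two distinct labels")
    if config.seed < 0:
        errors.append(f"seed must be >= 0, got {config.seed}")
    if not 0 < t["q_cap"] <= 1:
        errors.append(f"q_cap {t['q_cap']} outside (0, 1]")
    if t["fc_low"] >= t["fc_high"]:
        errors.append(f"fc_low {t['fc_low']} must be < fc_high {t['fc_high']}")
    if t["min_fc"] <= 1:
        errors.append(f"min_fc {t['min_fc']} must be > 1")
    if t["top_n"] < 1:
        errors.append("top_n must be >= 1")
    if t["min_support"] < 1:
        errors.append("min_support must be >= 1")
    if t["upstream_window"] < 0:
        errors.append("upstream_window must be >= 0")
    if t["annotation_mode"] not in ("upstream", "symmetric"):
        errors.append(f"unknown annotation_mode '{t['annotation_mode']}'")
    if t["min_alteration"] < 0:
        errors.append("min_alteration must be >= 0")
    if t["ssgsea_alpha"] < 0:
        errors.append("ssgsea_alpha must be >= 0")

    paths: list[tuple[str, str]] = [("genes", config.genes),
                                    ("expression", config.expression),
                                    ("alterations", config.alterations)]
    for cond, samples in config.peaks.items():
        for sample, p in samples.items():
            paths.append((f"peaks[{cond}][{sample}]", p))
    for sample, p in config.control_peaks.items():
        paths.append((f"control_peaks[{sample}]", p))
    if config.validation_flags:
        paths.append(("validation_flags", config.validation_flags))
    for name, p in config.reference_gene_lists.items():
        paths.append((f"reference_gene_lists[{name}]", p))
    if config.enrichment:
        paths.append(("enrichment.gene_sets", config.enrichment.get("gene_sets", "")))
        for ds in config.enrichment.get("datasets", []):
            paths.append((f"enrichment dataset '{ds.get('name')}'", ds.get("expression", "")))
    for label, p in paths:
        if not p or not Path(p).is_file():
            errors.append(f"{label}: missing input file '{p}'")
    return errors


def _read_validation_flags(path: str | None) -> dict[str, bool]:
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return {}
    return {str(r.gene_id): bool(r.validated) for r in df.itertuples()}


def run_screen(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle atomically.

    Returns the manifest dict.  On any stage failure the partially written
    outputs are removed and a PipelineError naming the stage is raised.
    """
    errors = validate_config(config)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    outdir = Path(config.outdir)
    if outdir.exists():
        raise ConfigError(f"output directory '{outdir}' already exists")
    tmpdir = outdir.parent / (outdir.name + ".partial")
    if tmpdir.exists():
        shutil.rmtree(tmpdir)
    tmpdir.mkdir(parents=True)
    try:
        manifest = _run_stages(config, tmpdir)
        tmpdir.rename(outdir)
        return manifest
    except Exception:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def _run_stages(config: RunConfig, outdir: Path) -> dict:
    t = config.thresholds
    counts: dict[str, int] = {}
    cond_a, cond_b = config.conditions

    peaks_by_sample = _stage("read_peaks")(
        lambda: {
            sample: read_narrowpeak(path, sample)
            for cond in config.peaks
            for sample, path in sorted(config.peaks[cond].items())
        }
        | {
            sample: read_narrowpeak(path, sample)
            for sample, path in sorted(config.control_peaks.items())
        }
    )()
    counts["peaks_in"] = sum(len(v) for v in peaks_by_sample.values())
    genes = _stage("read_genes")(read_gene_table)(config.genes)
    counts["genes"] = len(genes)

    spec = CalibrationSpec(
        positive_locus=Interval(*config.positive_locus),
        negative_locus=Interval(*config.negative_locus),
        positive_samples=tuple(
            s for c in config.conditions for s in sorted(config.peaks[c])
        ),
        negative_samples=tuple(sorted(config.control_peaks)),
        cap=t["q_cap"],
    )
    threshold = _stage("calibrate")(calibrate_q_threshold)(peaks_by_sample, spec)
    logger.info("calibrated q threshold: %g", threshold)

    filtered = _stage("filter")(
        lambda: {s: filter_peaks(p, threshold) for s, p in peaks_by_sample.items()}
    )()
    counts["peaks_filtered"] = sum(len(v) for v in filtered.values())

    # control-design invariant: positive locus called in every positive
    # sample and in no negative sample
    pos = spec.positive_locus
    for s in spec.positive_samples:
        assert any(p.overlaps(pos.chrom, pos.start, pos.end) for p in filtered[s]), s
    for s in spec.negative_samples:
        assert not any(p.overlaps(pos.chrom, pos.start, pos.end) for p in filtered[s]), s

    binding_tables = {}
    for cond in config.conditions:
        reps = {s: filtered[s] for s in sorted(config.peaks[cond])}
        arbs = _stage("consensus")(call_consensus_arbs)(
            reps, min_support=t["min_support"], condition=cond
        )
        counts[f"consensus_arbs_{cond}"] = len(arbs)
        table = _stage("annotate")(annotate_arbs_to_genes)(
            arbs,
            genes,
            upstream_window=t["upstream_window"],
            mode=t["annotation_mode"],
            condition=cond,
        )
        counts[f"bound_genes_{cond}"] = len(table.bound_genes)
        binding_tables[cond] = table

    partition = _stage("classify")(classify_differential_genes)(
        binding_tables[cond_a],
        binding_tables[cond_b],
        fc_low=t["fc_low"],
        fc_high=t["fc_high"],
        pseudocount=t["signal_pseudocount"],
    )
    only_a, only_b, shared, total = venn_counts(partition)
    venn = {
        f"exclusive_{cond_a}": only_a,
        f"exclusive_{cond_b}": only_b,
        "shared": shared,
        "total": total,
    }
    (outdir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True) + "\n")
    part_rows = (
        [(g, f"exclusive_{cond_a}") for g in sorted(partition.exclusive_a)]
        + [(g, f"exclusive_{cond_b}") for g in sorted(partition.exclusive_b)]
        + [(g, "shared") for g in sorted(partition.shared)]
    )
    pd.DataFrame(part_rows, columns=["gene_id", "class"]).to_csv(
        outdir / "partition.tsv", sep="\t", index=False
    )

    if config.reference_gene_lists:
        rows = []
        bound_all = partition.bound_genes
        for name, path in sorted(config.reference_gene_lists.items()):
            ref = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
            n_ov, n_ref, pct = _stage("overlap")(cross_study_overlap)(bound_all, ref)
            rows.append((name, n_ov, n_ref, pct))
        pd.DataFrame(
            rows, columns=["reference", "n_overlap", "n_reference", "percent"]
        ).to_csv(outdir / "cross_study_overlap.tsv", sep="\t", index=False)

    expr = _stage("read_expression")(read_expression_tsv)(
        config.expression, config.expression_conditions
    )
    de_cfg = DEFilterConfig(
        min_fpkm=t["min_fpkm"],
        min_fc=t["min_fc"],
        pseudocount=t["de_pseudocount"],
        top_n=t["top_n"],
    )
    de = _stage("de_filter")(de_filter)(expr, cond_a, cond_b, de_cfg)
    counts["de_up"] = len(de.up)
    counts["de_down"] = len(de.down)
    up30 = top_n(de.up, t["top_n"])
    down30 = top_n(de.down, t["top_n"])
    for name, lst in (("de_up", de.up), ("de_down", de.down)):
        pd.DataFrame(lst, columns=["gene_id", "fold_change"]).to_csv(
            outdir / f"{name}.tsv", sep="\t", index=False
        )

    alterations = _stage("read_alterations")(pd.read_csv)(
        config.alterations, sep="\t", index_col=0
    )
    alt = _stage("alteration_filter")(alteration_filter)(
        [g for g, _ in up30 + down30], alterations, min_freq=t["min_alteration"]
    )
    counts["alteration_pass"] = sum(1 for ok, _ in alt.values() if ok)

    flags = _stage("read_validation")(_read_validation_flags)(config.validation_flags)
    bound_conditions = {
        g: tuple(c for c in config.conditions if binding_tables[c].bound(g))
        for c_tbl in binding_tables.values()
        for g in c_tbl.bound_genes
    }
    records = _stage("integrate")(integrate_candidates)(
        up30, down30, alt, bound_conditions, flags, conditions=config.conditions
    )
    counts["candidates_considered"] = len(records)
    counts["candidates_final"] = sum(1 for r in records if r.final_pass)
    write_report([r.to_dict() for r in records], outdir / "candidates")

    if config.enrichment:
        _stage("enrich")(_run_enrichment)(config, outdir)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "q_threshold": threshold,
        "counts": counts,
        "venn": venn,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _run_enrichment(config: RunConfig, outdir: Path) -> None:
    enr = config.enrichment or {}
    t = config.thresholds
    collection = read_gmt(enr["gene_sets"])
    ss_cfg = SsgseaConfig(alpha=t["ssgsea_alpha"])
    results = []
    for ds in enr.get("datasets", []):
        expr = read_expression_tsv(ds["expression"], ds["groups"])
        scores = normalize_scores(ssgsea_matrix(expr, collection, ss_cfg))
        res = samroc_analysis(
            scores,
            ds["groups"],
            group_a=ds["group_a"],
            group_b=ds["group_b"],
            n_permutations=t["n_permutations"],
            seed=config.seed,
        )
        res.table.to_csv(outdir / f"enrichment_{ds['name']}.tsv", sep="\t")
        results.append(res)
    if len(results) == 2:
        fdr1, fdr2 = t["fdr_pair"]
        shared = common_pathways(results[0], results[1], fdr1, fdr2)
        shared.to_csv(outdir / "common_pathways.tsv", sep="\t")
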