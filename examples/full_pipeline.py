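"""The whole screen from files on disk, driven by one declarative config.

Writes a synthetic benchmark bundle (peaks, genes, expression, alterations,
validation flags) to a temporary directory, builds a RunConfig pointing at
those files, runs every stage, and checks the final candidates against the
planted truth.
"""

import tempfile
from pathlib import Path

import pandas as pd

from cistroscreen.pipeline import RunConfig, run_screen
from cistroscreen.synthio import TruthConfig, simulate_bundle

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    config = TruthConfig(
        n_genes=200,
        chrom_sizes={"chr1": 40_000_000},
        replicate_dropout=0.0,
        noise_peak_rate=0.0,
        seed=7,
    )
    bundle = simulate_bundle(config, outdir=tmp / "data")
    cal = bundle.cistrome.calibration

    run_config = RunConfig(
        conditions=("AD", "CR"),
        peaks={
            c: {s: bundle.paths[f"peaks:{s}"] for s in ss}
            for c, ss in bundle.cistrome.samples_by_condition.items()
        },
        control_peaks={s: bundle.paths[f"peaks:{s}"]
                       for s in bundle.cistrome.control_samples},
        genes=bundle.paths["genes"],
        expression=bundle.paths["expression"],
        expression_conditions=bundle.expression.conditions,
        alterations=bundle.paths["alterations"],
        positive_locus=(cal.positive_locus.chrom, cal.positive_locus.start,
                        cal.positive_locus.end),
        negative_locus=(cal.negative_locus.chrom, cal.negative_locus.start,
                        cal.negative_locus.end),
        validation_flags=bundle.paths["validation_flags"],
        outdir=str(tmp / "out"),
        seed=7,
    )
    manifest = run_screen(run_config)

    print(f"calibrated q threshold: {manifest['q_threshold']:.3f}")
    for stage, count in manifest["counts"].items():
        print(f"  {stage}: {count}")

    candidates = pd.read_csv(tmp / "out" / "candidates.tsv", sep="\t")
    final = set(candidates[candidates.final_pass].gene)
    print(f"final candidates match planted truth: {final == bundle.planted_candidates}")
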