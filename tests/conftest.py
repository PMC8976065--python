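import pytest

from cistroscreen.synthio import TruthConfig, simulate_bundle


@pytest.fixture(scope="session")
def clean_bundle():
    """Zero-dropout, zero-noise synthetic bundle: planted truth is exactly
    recoverable, so any deviation downstream is an implementation defect."""
    config = TruthConfig(
        n_genes=60,
        chrom_sizes={"chr1": 12_000_000},
        replicate_dropout=0.0,
        noise_peak_rate=0.0,
        seed=11,
    )
    return simulate_bundle(config)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Bundle at the default noise levels (dropout, spurious peaks)."""
    config = TruthConfig(
        n_genes=60,
        chrom_sizes={"chr1": 12_000_000},
        seed=11,
    )
    return simulate_bundle(config)
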