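"""Wet-lab readout quantification formulas.

ChIP-qPCR enrichment (fold over IgG and percent input), relative expression
by the 2^-ddCt convention, caliper tumor volume, and blank-corrected
proliferation normalization.
"""

import numpy as np

from cistroscreen.assay import (
    fold_over_igg,
    percent_input,
    proliferation_rate,
    relative_expression,
    tumor_volume,
)

# A working ChIP at an androgen-responsive enhancer: the antibody Ct comes up
# ~4-6 cycles before the IgG control, i.e. 16-64x enrichment.
print(f"fold over IgG (dCt 4): {fold_over_igg(24.0, 28.0):.0f}x")

# 10% of chromatin reserved as input; the IP comes up ~4.3 cycles behind the
# fraction-adjusted input -> ~5% of input recovered.
print(f"percent input: {percent_input(21.2, 20.2, 0.10):.2f}%")

# Target gene normalized by a housekeeping gene, relative to a calibrator
# sample with dCt 2.0: one cycle earlier means 2x expression.
print(f"relative expression: {relative_expression(23.0, 22.0, 2.0):.1f}x")

# Caliper measurement, largest diameter 12 mm, orthogonal 8 mm.
print(f"tumor volume: {tumor_volume(12.0, 8.0):.0f} mm^3")

# WST absorbances over 3 timepoints, triplicate wells, blank 0.1: treated
# wells reach ~70% of the control mean.
control = np.array([[0.5, 0.52, 0.48], [0.8, 0.82, 0.78], [1.1, 1.12, 1.08]])
treated = np.array([[0.38, 0.40, 0.36], [0.59, 0.61, 0.57], [0.80, 0.82, 0.78]])
rates = proliferation_rate(treated, control, blank=0.1)
print("proliferation rate per timepoint:", np.round(rates.mean(axis=1), 3))
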