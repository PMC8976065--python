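"""Deterministic quantification formulas for wet-lab readouts.

ChIP-qPCR enrichment (percent input and fold over IgG), relative expression
by the 2^-ddCt convention, caliper tumor volume, and blank-corrected
proliferation normalization.  PCR efficiency is fixed at 100% (base 2);
``PCR_BASE`` is the single place to change that assumption.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

PCR_BASE = 2.0

__all__ = [
    "QpcrWell",
    "TumorMeasurement",
    "percent_input",
    "fold_over_igg",
    "relative_expression",
    "tumor_volume",
    "proliferation_rate",
]


@dataclass(frozen=True)
class QpcrWell:
    """One qPCR well: a Ct value with its assay role.

    ``input_fraction`` is the proportion of chromatin reserved as input in a
    ChIP experiment (only meaningful for role 'input').
    """

    sample_id: str
    target: str
    role: str  # IP | IgG | input | target | reference
    ct: float
    input_fraction: float = 1.0

    def __post_init__(self):
        if self.role not in ("IP", "IgG", "input", "target", "reference"):
            raise ConfigError(f"unknown well role '{self.role}'")
        if not (self.ct > 0) and not math.isinf(self.ct):
            raise DataError(f"Ct must be positive (or inf for no amplification), got {self.ct}")
        if not 0 < self.input_fraction <= 1:
            raise DataError(f"input_fraction {self.input_fraction} outside (0, 1]")


@dataclass(frozen=True)
class TumorMeasurement:
    """One caliper measurement: largest (L) and orthogonal (W) diameters, mm."""

    animal_id: str
    day: int
    length: float
    width: float

    def __post_init__(self):
        if not self.length >= self.width >= 0:
            raise DataError(
                f"need L >= W >= 0, got L={self.length}, W={self.width}"
            )

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP recovery as percent of input chromatin.

    The input Ct is first adjusted for the reserved fraction
    (adjusted = ct_input - log2(1/fraction)); then
    percent = 100 * 2^(adjusted - ct_ip).  An infinite IP Ct (the
    no-amplification sentinel) yields 0% with a warning.
    """
    if input_fraction <= 0:
        raise DataError(f"input_fraction must be > 0, got {input_fraction}")
    if math.isinf(ct_ip):
        logger.warning("IP well did not amplify; percent input reported as 0")
        return 0.0
    adjusted = ct_input - math.log(1.0 / input_fraction, PCR_BASE)
    return 100.0 * PCR_BASE ** (adjusted - ct_ip)


def fold_over_igg(ct_antibody: float, ct_igg: float) -> float:
    """Enrichment of the specific antibody over the IgG control: 2^(Ct_IgG - Ct_ab)."""
    return PCR_BASE ** (ct_igg - ct_antibody)


def relative_expression(
    ct_target: float, ct_reference: float, calibrator_delta_ct: float
) -> float:
    """Relative level by the 2^-ddCt convention.

    delta Ct = ct_target - ct_reference (e.g. normalised by GAPDH);
    the result is 2^(calibrator_delta_ct - delta_ct), i.e. 1.0 for the
    calibrator itself.
    """
    delta_ct = ct_target - ct_reference
    return PCR_BASE ** (calibrator_delta_ct - delta_ct)


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume V = L * W^2 * 0.5 (mm^3)."""
    if width > length:
        raise DataError(
            f"W={width} exceeds L={length}; L must be the largest diameter"
        )
    if width < 0:
        raise DataError("diameters must be non-negative")
    return length * width**2 * 0.5


def proliferation_rate(
    treatment: np.ndarray | list,
    control: np.ndarray | list,
    blank: float = 0.0,
) -> np.ndarray:
    """Normalized proliferation per timepoint from WST-type absorbances.

    Both series are blank-subtracted; each treatment value is divided by the
    matched-timepoint control mean.  ``treatment`` and ``control`` are arrays
    of shape (timepoints,) or (timepoints, replicates).
    """
    t = np.atleast_2d(np.asarray(treatment, dtype=float).T).T
    c = np.atleast_2d(np.asarray(control, dtype=float).T).T
    if t.shape[0] != c.shape[0]:
        raise DataError("treatment and control timepoints are not aligned")
    c_mean = (c - blank).mean(axis=1)
    if (c_mean <= 0).any():
        raise DataError("control absorbance must exceed the blank at every timepoint")
    rates = (t - blank) / c_mean[:, None]
    return rates.squeeze()
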