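"""Wet-lab calculation formulas: LDH cytotoxicity and qPCR quantities.

Percent specific lysis from an LDH-release plate:

    100 * ((mix - splenocyte_control) - negative_control)
        / (positive_control - negative_control)

Amplification efficiency from a standard curve of threshold cycles over a
serial dilution: the least-squares slope of Ct against log10(relative
input) gives efficiency = 10^(-1/slope) (2.0 = perfect doubling per
cycle). Relative expression is normalized against a simultaneously
amplified reference gene (GAPDH): efficiency^(-(Ct_target - Ct_ref)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class CtlReadings:
    """Absorbance readings from one E:T condition of an LDH release assay."""

    mix: float                # effector + target wells
    splenocyte_control: float  # effectors alone
    negative_control: float    # target spontaneous release
    positive_control: float    # target maximal release
    e_t_ratio: str = ""        # label such as "30:1"

    def __post_init__(self) -> None:
        for name in ("mix", "splenocyte_control", "negative_control", "positive_control"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.positive_control <= self.negative_control:
            raise ValueError(
                "positive_control must exceed negative_control "
                f"({self.positive_control} <= {self.negative_control})"
            )


@dataclass
class CtlResult:
    percent_lysis: float
    out_of_range: bool  # QC flag: lysis < 0% or > 100%, reported unclipped
    e_t_ratio: str = ""


@dataclass
class QpcrRecord:
    """One target/reference Ct pair with the reaction's efficiency."""

    ct_target: float
    ct_reference: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.ct_target <= 0 or self.ct_reference <= 0:
            raise ValueError("Ct values must be positive")
        if not 1.0 < self.efficiency <= 2.2:
            raise ValueError(f"efficiency must lie in (1, 2.2], got {self.efficiency}")


@dataclass
class EfficiencyFit:
    efficiency: float
    slope: float
    r_squared: float
    n: int


def ctl_cytotoxicity(readings: CtlReadings) -> CtlResult:
    """Percent specific lysis; out-of-range values flagged, never clipped."""
    pct = (
        100.0
        * ((readings.mix - readings.splenocyte_control) - readings.negative_control)
        / (readings.positive_control - readings.negative_control)
    )
    return CtlResult(
        percent_lysis=float(pct),
        out_of_range=bool(pct < 0.0 or pct > 100.0),
        e_t_ratio=readings.e_t_ratio,
    )


def estimate_efficiency(dilution_factors, ct_values) -> EfficiencyFit:
    """Amplification efficiency from a serial-dilution standard curve.

    ``dilution_factors`` are relative cDNA inputs (e.g. 1, 0.5, 0.25 ...).
    The slope of Ct versus log10(input) must be negative (more template,
    earlier threshold); efficiency = 10^(-1/slope).
    """
    d = np.asarray(dilution_factors, dtype=float)
    ct = np.asarray(ct_values, dtype=float)
    if d.shape != ct.shape:
        raise ValueError("dilution_factors and ct_values must have the same length")
    if len(d) < 3:
        raise ValueError(f"need >= 3 dilution points, got {len(d)}")
    if np.any(d <= 0):
        raise ValueError("dilution factors must be positive")
    fit = stats.linregress(np.log10(d), ct)
    if fit.slope >= 0:
        raise ValueError(
            f"non-negative standard-curve slope ({fit.slope:.4g}); "
            "amplification must reduce Ct with more input"
        )
    return EfficiencyFit(
        efficiency=float(10.0 ** (-1.0 / fit.slope)),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue ** 2),
        n=len(d),
    )


def relative_expression(record: QpcrRecord) -> float:
    """Reference-normalized expression: efficiency^(-(Ct_target - Ct_ref))."""
    delta_ct = record.ct_target - record.ct_reference
    return float(record.efficiency ** (-delta_ct))
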