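"""Instrument QC: blank-based detection limits, censored-value
substitution, spike recoveries, and certified-reference-material checks.

The detection limit (LOD) is 3x the standard deviation of reagent blanks
and the quantification limit (LOQ) 10x the same SD, so LOQ/LOD = 10/3
whenever both derive from one blank set.  Non-detects are substituted by
the LOQ by default (the conservative rule used in the study), with
half-LOQ and zero offered as alternatives.
"""

from __future__ import annotations

import enum
import statistics
from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict, Field

from .datatypes import ConcentrationDataset, Matrix, Measurement


class InsufficientBlanksError(ValueError):
    pass


class MissingLimitsError(KeyError):
    pass


class DetectionLimits(BaseModel):
    """Blank-derived LOD/LOQ for one element, µg/L."""

    model_config = ConfigDict(frozen=True)

    element: str
    lod: float = Field(ge=0)
    loq: float = Field(ge=0)
    n_blanks: int = Field(ge=2)


class RecoveryResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    element: str
    spike_level: float = Field(gt=0)  # µg/L
    recovery: float = Field(ge=0)     # percent


class CensorPolicy(str, enum.Enum):
    """Substitution rule for below-detection values."""

    LOQ = "loq"
    HALF_LOQ = "half_loq"
    ZERO = "zero"


def detection_limits(
    blanks: Iterable[Measurement], element: str
) -> DetectionLimits:
    """LOD/LOQ for ``element`` from reagent-blank measurements.

    LOD = 3 x sample SD of the blanks, LOQ = 10 x the same SD (n-1
    denominator).  Requires at least two uncensored blank values.
    """
    values = [
        m.value
        for m in blanks
        if m.element == element and m.matrix is Matrix.BLANK and not m.censored
    ]
    if len(values) < 2:
        raise InsufficientBlanksError(
            f"need >= 2 uncensored blanks for {element}, got {len(values)}"
        )
    sd = statistics.stdev(values)
    return DetectionLimits(
        element=element, lod=3.0 * sd, loq=10.0 * sd, n_blanks=len(values)
    )


def substitute_censored(
    dataset: ConcentrationDataset,
    limits: Mapping[str, DetectionLimits],
    policy: CensorPolicy = CensorPolicy.LOQ,
) -> ConcentrationDataset:
    """Assign a numeric value to every censored measurement.

    ``policy`` maps a non-detect to its element's LOQ (default), LOQ/2,
    or zero.  Censored flags are preserved for provenance; uncensored
    values pass through untouched.
    """
    policy = CensorPolicy(policy)
    out: list[Measurement] = []
    for m in dataset:
        if not m.censored:
            out.append(m)
            continue
        if m.element not in limits:
            raise MissingLimitsError(
                f"censored measurement for {m.element} but no detection "
                "limits supplied for that element"
            )
        loq = limits[m.element].loq
        value = {
            CensorPolicy.LOQ: loq,
            CensorPolicy.HALF_LOQ: loq / 2.0,
            CensorPolicy.ZERO: 0.0,
        }[policy]
        out.append(m.model_copy(update={"value": value}))
    return ConcentrationDataset(out, dataset.brewing)


def spike_recovery(measured: float, base: float, spiked: float) -> float:
    """Spike recovery in percent: (measured - base) / spiked x 100.

    ``base`` is the unspiked sample concentration (≈0 for reagent-grade
    infusion blanks); ``spiked`` the nominal added concentration, µg/L.
    """
    if spiked <= 0:
        raise ValueError(f"spike level must be positive, got {spiked}")
    return (measured - base) / spiked * 100.0


class CrmCheck(BaseModel):
    """Outcome of a certified-reference-material comparison."""

    model_config = ConfigDict(frozen=True)

    passed: bool
    score: float  # |detected - certified| / combined SD; inf if both SDs 0 and means differ


def crm_check(
    detected_mean: float,
    detected_sd: float,
    certified_mean: float,
    certified_sd: float,
    k: float = 2.0,
) -> CrmCheck:
    """Compare a detected CRM mean against its certificate.

    Passes when |detected - certified| <= k x sqrt(certified_sd^2 +
    detected_sd^2), i.e. the bias is within ``k`` combined standard
    deviations (default coverage factor 2).
    """
    if detected_sd < 0 or certified_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    diff = abs(detected_mean - certified_mean)
    combined = (certified_sd**2 + detected_sd**2) ** 0.5
    if combined == 0.0:
        score = 0.0 if diff == 0.0 else float("inf")
    else:
        score = diff / combined
    return CrmCheck(passed=score <= k, score=score)
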