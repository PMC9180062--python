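"""Deterministic dietary exposure and risk computation.

For one subpopulation with consumption ratio r = D / B_w (grams of tea
per kg body weight per day) and one element with made-tea concentration
C (mg/kg, read as µg/g) and brewing transfer rate T:

    EDI = C x T x r                      (µg / kg bw / day)
    HQ  = EDI / RfD                      (dimensionless; < 1 acceptable)
    adjusted HQ = HQ x bioavailability
    HI  = sum of HQ over elements        (same op serves adjusted HI)
    TR  = (EDI x 1e-3 mg/µg) x Sf        (carcinogens only)
    TR_total = sum of TR; acceptability threshold 1e-4

All arithmetic is done at full double precision; rounding happens only
in the report layer.  Every quantity is homogeneous of degree 1 in C and
in r, which the tests exploit.

The hazard index is implemented as the plain SUM of hazard quotients
(the standard aggregation for multi-contaminant exposure); see the
methods note for why a mean aggregation is not used.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .datatypes import ConsumptionProfile, ToxRef
from .reference import TR_ACCEPTABILITY_THRESHOLD

MG_PER_UG = 1e-3


class NotACarcinogenError(ValueError):
    pass


class ExposureResult(BaseModel):
    """Per-element exposure for one consumption profile."""

    model_config = ConfigDict(frozen=True)

    profile: str
    element: str
    edi: float          # µg/kg bw/day
    hq: float           # dimensionless
    adjusted_hq: float  # dimensionless

    @property
    def acceptable(self) -> bool:
        return self.hq < 1.0


class RiskSummary(BaseModel):
    """Aggregate non-carcinogenic and carcinogenic risk for one profile."""

    model_config = ConfigDict(frozen=True)

    profile: str
    hi: float
    adjusted_hi: float
    tr: dict[str, float]            # per carcinogenic element
    tr_adjusted: dict[str, float]   # TR x bioavailability (interpretive)
    tr_total: float
    contribution: dict[str, float]  # element share of tr_total

    @property
    def tr_exceeds_threshold(self) -> bool:
        return self.tr_total > TR_ACCEPTABILITY_THRESHOLD


def edi(c_t: float, t: float, profile: ConsumptionProfile) -> float:
    """Estimated daily intake, µg per kg body weight per day.

    ``c_t`` is the made-tea concentration (mg/kg), ``t`` the brewing
    transfer rate; only the fraction released into the infusion is
    ingested.  Equals C x T x r for the profile's ratio r = D / B_w.
    """
    if c_t < 0 or t < 0:
        raise ValueError("concentration and transfer rate must be nonnegative")
    return c_t * t * profile.ratio


def hq(edi_value: float, rfd: float) -> float:
    """Hazard quotient EDI / RfD (both µg/kg bw/day); < 1 is acceptable."""
    if rfd <= 0:
        raise ValueError(f"RfD must be positive, got {rfd}")
    return edi_value / rfd


def adjusted_hq(hq_value: float, bioavailability: float) -> float:
    """HQ scaled by the element's oral bioavailability fraction."""
    if not 0 < bioavailability <= 1:
        raise ValueError(
            f"bioavailability must be in (0, 1], got {bioavailability}"
        )
    return hq_value * bioavailability


def hi(hqs: Sequence[float] | Mapping[str, float]) -> float:
    """Hazard index: the sum of per-element hazard quotients.

    Accepts a sequence or an element-keyed mapping; serves both the plain
    and the bioavailability-adjusted index.
    """
    values = list(hqs.values()) if isinstance(hqs, Mapping) else list(hqs)
    if not values:
        raise ValueError("hazard index of an empty element set is undefined")
    return float(sum(values))


def tr(edi_value: float, sf: Optional[float]) -> float:
    """Target carcinogenic risk: EDI (converted µg -> mg) x slope factor.

    ``sf`` is in (mg/kg bw/day)^-1 while EDI is carried in µg/kg bw/day,
    so the single explicit unit conversion of the pipeline happens here.
    """
    if sf is None:
        raise NotACarcinogenError("no slope factor: element is not a carcinogen")
    return edi_value * MG_PER_UG * sf


def tr_total(trs: Mapping[str, float]) -> tuple[float, dict[str, float]]:
    """Total carcinogenic risk and per-element contribution fractions.

    Contributions sum to 1 whenever the total is positive.
    """
    if not trs:
        raise ValueError("tr_total of an empty carcinogen set is undefined")
    total = float(sum(trs.values()))
    if total > 0:
        contribution = {e: v / total for e, v in trs.items()}
    else:
        contribution = {e: 0.0 for e in trs}
    return total, contribution


def invert_consumption_ratio(
    hq_value: float, rfd: float, c_t: float, t: float
) -> float:
    """Back-solve the consumption ratio r = D / B_w from a known HQ.

    r = HQ x RfD / (C x T), in g per kg bw per day.  Used to reconstruct
    unpublished survey ratios from published hazard quotients; ``hq_value``
    is dimensionless (divide a percent-scale figure by 100 first).
    """
    denom = c_t * t
    if denom <= 0 or rfd <= 0:
        raise ValueError("C, T and RfD must all be positive to invert")
    return hq_value * rfd / denom


def assess(
    concentrations: Mapping[str, float],
    transfer_rates: Mapping[str, float],
    toxref: Mapping[str, ToxRef],
    profiles: Sequence[ConsumptionProfile],
) -> tuple[list[ExposureResult], list[RiskSummary]]:
    """Run the full deterministic risk pipeline for every profile.

    Parameters
    ----------
    concentrations : per-element made-tea concentration, mg/kg
    transfer_rates : per-element brewing transfer rate, fraction
    toxref : per-element toxicological constants
    profiles : subpopulation consumption profiles

    Returns
    -------
    (exposures, summaries) : one :class:`ExposureResult` per
    (profile, element) and one :class:`RiskSummary` per profile.
    Deterministic given its inputs; no rounding is applied.
    """
    elements = list(concentrations)
    missing = [e for e in elements if e not in toxref]
    if missing:
        raise KeyError(f"elements without toxicological reference: {missing}")
    missing_t = [e for e in elements if e not in transfer_rates]
    if missing_t:
        raise KeyError(f"elements without transfer rate: {missing_t}")

    exposures: list[ExposureResult] = []
    summaries: list[RiskSummary] = []
    for profile in profiles:
        hqs: dict[str, float] = {}
        adj_hqs: dict[str, float] = {}
        trs: dict[str, float] = {}
        trs_adj: dict[str, float] = {}
        for e in elements:
            ref = toxref[e]
            edi_value = edi(concentrations[e], transfer_rates[e], profile)
            hq_value = hq(edi_value, ref.rfd)
            adj_value = adjusted_hq(hq_value, ref.bioavailability)
            hqs[e] = hq_value
            adj_hqs[e] = adj_value
            exposures.append(
                ExposureResult(
                    profile=profile.name,
                    element=e,
                    edi=edi_value,
                    hq=hq_value,
                    adjusted_hq=adj_value,
                )
            )
            if ref.is_carcinogen:
                tr_value = tr(edi_value, ref.sf)
                trs[e] = tr_value
                trs_adj[e] = tr_value * ref.bioavailability
        total, contribution = tr_total(trs) if trs else (0.0, {})
        summaries.append(
            RiskSummary(
                profile=profile.name,
                hi=hi(hqs),
                adjusted_hi=hi(adj_hqs),
                tr=trs,
                tr_adjusted=trs_adj,
                tr_total=total,
                contribution=contribution,
            )
        )
    return exposures, summaries
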