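"""Shipped reference data for the Tieguanyin tea exposure study.

Holds the toxicological constants (oral reference doses, carcinogenic
slope factors, oral bioavailabilities), the published summary statistics
of the 91-sample Tieguanyin survey (made-tea concentration mean/SD/range,
mean brewing transfer rates), the instrument QC reference (detection
limits, spike recoveries, certified reference material), and the published
subpopulation hazard-quotient table used to back-derive consumption
ratios.  Everything downstream — defaults for the risk pipeline, the
synthetic-data generator, and the desk-scale reproduction checks — reads
from here.
"""

from __future__ import annotations

from .datatypes import ToxRef

#: Canonical element order for the five monitored potentially toxic elements.
STUDY_ELEMENTS: tuple[str, ...] = ("Cu", "Pb", "Cr", "Cd", "Ni")

# Oral reference dose, µg/kg bw/day.
RFD_UG_PER_KG_DAY: dict[str, float] = {
    "Cu": 40.0,
    "Pb": 3.57,
    "Cr": 3.0,
    "Cd": 1.0,
    "Ni": 20.0,
}

# Oral carcinogenic slope factor, (mg/kg bw/day)^-1; only Pb, Cr and Cd
# have established oral slopes.
SF_PER_MG_KG_DAY: dict[str, float] = {
    "Pb": 0.0085,
    "Cr": 0.5,
    "Cd": 6.3,
}

# Oral bioavailability fraction used for the adjusted hazard quotients.
BIOAVAILABILITY: dict[str, float] = {
    "Cu": 0.40,
    "Pb": 0.60,
    "Cr": 0.01,
    "Cd": 0.50,
    "Ni": 0.10,
}

# Made-tea concentration summaries over the 91-sample survey, mg/kg:
# (range_min, range_max, mean, sd).  The Cd range minimum was reported
# only as "below detection"; 0.0 stands in for ND.
MADE_TEA_SUMMARY_MG_KG: dict[str, tuple[float, float, float, float]] = {
    "Cu": (2.65, 11.61, 8.18, 2.10),
    "Pb": (0.21, 2.00, 0.84, 0.40),
    "Cr": (0.08, 1.38, 0.51, 0.28),
    "Cd": (0.0, 0.11, 0.04, 0.02),
    "Ni": (1.02, 2.93, 1.90, 0.70),
}

# Mean brewing transfer rate (fraction of leaf burden released to the
# infusion) under the 7 g / 150 mL / 10 min protocol.
MEAN_TRANSFER_RATE: dict[str, float] = {
    "Cu": 0.102,
    "Pb": 0.315,
    "Cr": 0.423,
    "Cd": 0.536,
    "Ni": 0.704,
}

# Instrument detection/quantification limits from 10 reagent blanks, µg/L.
LOD_UG_L: dict[str, float] = {
    "Cu": 0.09,
    "Pb": 0.01,
    "Cr": 0.009,
    "Cd": 0.003,
    "Ni": 0.02,
}
LOQ_UG_L: dict[str, float] = {
    "Cu": 0.3,
    "Pb": 0.03,
    "Cr": 0.03,
    "Cd": 0.01,
    "Ni": 0.06,
}

# Spike recoveries (%) for tea infusion at 10 / 50 / 100 µg/L.
SPIKE_RECOVERY_PCT: dict[str, dict[float, float]] = {
    "Cu": {10.0: 110.6, 50.0: 110.7, 100.0: 114.2},
    "Ni": {10.0: 103.6, 50.0: 96.8, 100.0: 98.8},
    "Pb": {10.0: 90.1, 50.0: 85.9, 100.0: 87.2},
    "Cd": {10.0: 85.3, 50.0: 87.3, 100.0: 84.3},
    "Cr": {10.0: 100.4, 50.0: 94.7, 100.0: 96.8},
}

# Certified reference material (green tea, GBW10052), µg/kg:
# element -> (certified mean, certified sd, detected mean, detected sd).
CRM_GREEN_TEA_UG_KG: dict[str, tuple[float, float, float, float]] = {
    "Cu": (24.0, 1.0, 24.4, 0.5),
    "Ni": (5.4, 0.4, 5.4, 0.2),
    "Pb": (1.6, 0.2, 1.7, 0.1),
    "Cd": (0.076, 0.004, 0.077, 0.001),
    "Cr": (0.92, 0.20, 0.92, 0.01),
}

#: The six survey subpopulations, in reporting order.
SUBPOPULATIONS: tuple[str, ...] = (
    "male",
    "female",
    "urban",
    "rural",
    "age_18_40",
    "age_ge_41",
)

# Published per-subpopulation hazard quotients on the PERCENT scale
# (2 significant figures as printed).  Dimensionless HQ = value / 100.
# These cells are the only surviving trace of the unpublished consumption
# survey; the default profiles back-solve D/B_w from the Cu row.
PUBLISHED_HQ_PERCENT: dict[str, dict[str, float]] = {
    "Cu": {"male": 4.7e-3, "female": 3.1e-3, "urban": 4.0e-3,
           "rural": 3.7e-3, "age_18_40": 3.7e-3, "age_ge_41": 5.0e-3},
    "Pb": {"male": 1.7e-2, "female": 1.1e-2, "urban": 1.4e-2,
           "rural": 1.3e-2, "age_18_40": 1.3e-2, "age_ge_41": 1.8e-2},
    "Cr": {"male": 1.6e-2, "female": 1.1e-2, "urban": 1.4e-2,
           "rural": 1.3e-2, "age_18_40": 1.3e-2, "age_ge_41": 1.7e-2},
    "Cd": {"male": 4.9e-3, "female": 3.2e-3, "urban": 4.2e-3,
           "rural": 3.8e-3, "age_18_40": 3.8e-3, "age_ge_41": 5.1e-3},
    "Ni": {"male": 1.5e-2, "female": 1.0e-2, "urban": 1.3e-2,
           "rural": 1.2e-2, "age_18_40": 1.2e-2, "age_ge_41": 1.6e-2},
}

PUBLISHED_ADJUSTED_HQ_PERCENT: dict[str, dict[str, float]] = {
    "Cu": {"male": 2.0e-3, "female": 1.2e-3, "urban": 1.6e-3,
           "rural": 1.5e-3, "age_18_40": 1.5e-3, "age_ge_41": 2.0e-3},
    "Pb": {"male": 1.0e-2, "female": 6.7e-3, "urban": 8.6e-3,
           "rural": 8.0e-3, "age_18_40": 8.0e-3, "age_ge_41": 1.0e-2},
    "Cr": {"male": 1.6e-4, "female": 1.1e-4, "urban": 1.4e-4,
           "rural": 1.3e-4, "age_18_40": 1.3e-4, "age_ge_41": 1.7e-4},
    "Cd": {"male": 2.4e-3, "female": 1.6e-3, "urban": 2.1e-3,
           "rural": 1.9e-3, "age_18_40": 1.9e-3, "age_ge_41": 2.5e-3},
    "Ni": {"male": 1.5e-3, "female": 1.0e-3, "urban": 1.3e-3,
           "rural": 1.2e-3, "age_18_40": 1.2e-3, "age_ge_41": 1.6e-3},
}

PUBLISHED_HI_PERCENT: dict[str, float] = {
    "male": 5.8e-2, "female": 3.8e-2, "urban": 4.9e-2,
    "rural": 4.6e-2, "age_18_40": 4.6e-2, "age_ge_41": 6.1e-2,
}

PUBLISHED_ADJUSTED_HI_PERCENT: dict[str, float] = {
    "male": 1.6e-2, "female": 1.1e-2, "urban": 1.4e-2,
    "rural": 1.3e-2, "age_18_40": 1.3e-2, "age_ge_41": 1.7e-2,
}

# Regulatory comparison points.
DRINKING_WATER_PB_LIMIT_MG_L: float = 0.01
TR_ACCEPTABILITY_THRESHOLD: float = 1e-4


def default_toxref() -> list[ToxRef]:
    """The five-element toxicology reference table shipped with the package.

    Returns one :class:`~tearisk.datatypes.ToxRef` per study element with
    the oral RfD (µg/kg bw/day), the oral slope factor where one is
    established (Pb, Cr, Cd), and the oral bioavailability fraction.
    """
    return [
        ToxRef(
            element=e,
            rfd=RFD_UG_PER_KG_DAY[e],
            sf=SF_PER_MG_KG_DAY.get(e),
            bioavailability=BIOAVAILABILITY[e],
        )
        for e in STUDY_ELEMENTS
    ]


def toxref_map(refs: list[ToxRef] | None = None) -> dict[str, ToxRef]:
    """Index a toxref list by element symbol (defaults to the shipped table)."""
    refs = default_toxref() if refs is None else refs
    return {t.element: t for t in refs}
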