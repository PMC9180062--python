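"""Core domain types for brewed-tea heavy-metal exposure assessment.

Unit conventions (canonical throughout the package):

* made tea concentrations: mg/kg dry leaf (numerically identical to µg/g)
* infusion / blank / spike concentrations: µg/L
* estimated daily intake (EDI): µg per kg body weight per day
* hazard quotient (HQ), hazard index (HI), carcinogenic risk (TR): dimensionless

The matrix tag on every measurement carries its unit, so made-tea (mg/kg)
and infusion (µg/L) values can never be averaged together by accident.
"""

from __future__ import annotations

import enum
from typing import Iterable, Iterator, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ElementRegistryError(KeyError):
    """Raised when a dataset references an unregistered element symbol."""


#: Extensible registry of element symbols the pipeline knows about.
#: The five defaults are the potentially toxic elements monitored in
#: Tieguanyin tea; users may register others (e.g. As, Hg) at run time.
ELEMENTS: list[str] = ["Cu", "Pb", "Cr", "Cd", "Ni"]


def register_element(symbol: str) -> None:
    """Add a new element symbol to the registry (idempotent)."""
    if symbol not in ELEMENTS:
        ELEMENTS.append(symbol)


def check_element(symbol: str) -> str:
    if symbol not in ELEMENTS:
        raise ElementRegistryError(
            f"unknown element {symbol!r}; registered: {ELEMENTS}"
        )
    return symbol


class Matrix(str, enum.Enum):
    """Sample matrix; also fixes the concentration unit of its values."""

    MADE_TEA = "made_tea"  # mg/kg dry leaf
    INFUSION = "infusion"  # µg/L
    BLANK = "blank"        # µg/L
    SPIKE = "spike"        # µg/L

    @property
    def unit(self) -> str:
        return "mg/kg" if self is Matrix.MADE_TEA else "ug/L"


class Measurement(BaseModel):
    """One concentration determination for one sample and element.

    ``censored=True`` marks a non-detect: the instrument reported the value
    only as "below detection".  Its ``value`` stays ``None`` until a
    substitution policy (see :mod:`tearisk.qc`) assigns one; the flag is
    preserved afterwards for provenance.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    element: str
    matrix: Matrix
    value: Optional[float] = None
    censored: bool = False

    @model_validator(mode="after")
    def _check(self) -> "Measurement":
        check_element(self.element)
        if self.value is not None and self.value < 0:
            raise ValueError(
                f"negative concentration {self.value} for sample "
                f"{self.sample_id!r}, element {self.element}"
            )
        if not self.censored and self.value is None:
            raise ValueError(
                f"uncensored measurement without a value: sample "
                f"{self.sample_id!r}, element {self.element}"
            )
        return self


class BrewingSpec(BaseModel):
    """Brewing protocol: leaf mass steeped in a volume of boiling water.

    ``steep_time_min`` is metadata only; the transfer-rate algebra uses
    just the mass and volume.
    """

    model_config = ConfigDict(frozen=True)

    tea_mass_g: float = Field(gt=0)
    water_volume_l: float = Field(gt=0)
    steep_time_min: float = Field(default=10.0, ge=0)


#: The study brewing protocol: 7 g made tea, 150 mL boiling water, 10 min.
DEFAULT_BREWING = BrewingSpec(tea_mass_g=7.0, water_volume_l=0.150, steep_time_min=10.0)


class ConcentrationDataset:
    """A collection of measurements sharing one brewing specification.

    (sample_id, element, matrix) triples are unique.  Thin wrapper over a
    list of :class:`Measurement` with a :meth:`to_frame` escape hatch to
    pandas for bulk statistics.
    """

    def __init__(
        self,
        measurements: Iterable[Measurement],
        brewing: BrewingSpec = DEFAULT_BREWING,
    ) -> None:
        self.measurements = list(measurements)
        self.brewing = brewing
        seen: set[tuple[str, str, Matrix]] = set()
        for m in self.measurements:
            key = (m.sample_id, m.element, m.matrix)
            if key in seen:
                raise ValueError(f"duplicate measurement key {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self) -> Iterator[Measurement]:
        return iter(self.measurements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationDataset):
            return NotImplemented
        return (
            self.measurements == other.measurements
            and self.brewing == other.brewing
        )

    def filter(
        self,
        matrix: Optional[Matrix] = None,
        element: Optional[str] = None,
    ) -> "ConcentrationDataset":
        ms = [
            m
            for m in self.measurements
            if (matrix is None or m.matrix is matrix)
            and (element is None or m.element == element)
        ]
        return ConcentrationDataset(ms, self.brewing)

    def elements(self) -> list[str]:
        """Registered-order list of elements present in the dataset."""
        present = {m.element for m in self.measurements}
        return [e for e in ELEMENTS if e in present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "element": m.element,
                    "matrix": m.matrix.value,
                    "value": m.value,
                    "censored": m.censored,
                }
                for m in self.measurements
            ],
            columns=["sample_id", "element", "matrix", "value", "censored"],
        )


class ToxRef(BaseModel):
    """Per-element toxicological constants.

    ``rfd`` is the oral reference dose in µg/kg bw/day; ``sf`` the oral
    carcinogenic slope factor in (mg/kg bw/day)^-1, ``None`` for
    non-carcinogens; ``bioavailability`` the absorbed fraction in (0, 1].
    """

    model_config = ConfigDict(frozen=True)

    element: str
    rfd: float = Field(gt=0)
    sf: Optional[float] = Field(default=None, ge=0)
    bioavailability: float = Field(gt=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "ToxRef":
        check_element(self.element)
        return self

    @property
    def is_carcinogen(self) -> bool:
        return self.sf is not None


class ConsumptionProfile(BaseModel):
    """A subpopulation's tea consumption normalised to body weight.

    Either ``daily_tea_mass_g`` and ``body_weight_kg`` are given, or the
    ratio ``ratio_g_per_kg_day`` directly; the ratio r = D / B_w is the
    canonical internal representation (all exposure formulas are functions
    of r alone).
    """

    model_config = ConfigDict(frozen=True)

    name: str
    daily_tea_mass_g: Optional[float] = Field(default=None, ge=0)
    body_weight_kg: Optional[float] = Field(default=None, gt=0)
    ratio_g_per_kg_day: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _derive_ratio(self) -> "ConsumptionProfile":
        if self.ratio_g_per_kg_day is None:
            if self.daily_tea_mass_g is None or self.body_weight_kg is None:
                raise ValueError(
                    f"profile {self.name!r} needs either ratio_g_per_kg_day "
                    "or both daily_tea_mass_g and body_weight_kg"
                )
            object.__setattr__(
                self,
                "ratio_g_per_kg_day",
                self.daily_tea_mass_g / self.body_weight_kg,
            )
        elif self.daily_tea_mass_g is not None and self.body_weight_kg is not None:
            implied = self.daily_tea_mass_g / self.body_weight_kg
            if abs(implied - self.ratio_g_per_kg_day) > 1e-9 * max(implied, 1.0):
                raise ValueError(
                    f"profile {self.name!r}: ratio {self.ratio_g_per_kg_day} "
                    f"inconsistent with D/B_w = {implied}"
                )
        return self

    @property
    def ratio(self) -> float:
        assert self.ratio_g_per_kg_day is not None
        return self.ratio_g_per_kg_day
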