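"""Brewing transfer rates: the link between leaf and infusion concentrations.

The transfer rate T of an element is the fraction of its mass in the
brewed leaves that ends up in the infusion:

    T = (C_i x V_i) / (C_t x M_t)

with C_i the infusion concentration (µg/L), V_i the water volume (L),
C_t the made-tea concentration (mg/kg, read as µg/g so units cancel) and
M_t the leaf mass (g).  T is dimensionless; values above 1 are physically
impossible but can arise from measurement noise and are flagged rather
than rejected.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .datatypes import BrewingSpec, ConcentrationDataset, Matrix

logger = logging.getLogger(__name__)


class UndefinedTransferError(ZeroDivisionError):
    """Transfer rate is undefined when the leaf concentration is zero."""


class TransferResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    sample_id: str
    element: str
    transfer_rate: float       # fraction
    made_tea_conc: float       # mg/kg
    infusion_conc: float       # µg/L

    @property
    def exceeds_unity(self) -> bool:
        return self.transfer_rate > 1.0


def transfer_rate(c_i: float, c_t: float, brewing: BrewingSpec) -> float:
    """Fraction of the element's leaf burden released into the infusion.

    Parameters
    ----------
    c_i : infusion concentration, µg/L
    c_t : made-tea concentration, mg/kg (numerically µg/g)
    brewing : leaf mass and water volume used
    """
    if c_t <= 0:
        raise UndefinedTransferError(
            f"transfer rate undefined for made-tea concentration {c_t}"
        )
    return (c_i * brewing.water_volume_l) / (c_t * brewing.tea_mass_g)


def infusion_concentration(c_t: float, t: float, brewing: BrewingSpec) -> float:
    """Infusion concentration (µg/L) implied by a leaf level and transfer rate.

    Exact algebraic inverse of :func:`transfer_rate`:
    C_i = T x C_t x M_t / V_i.
    """
    if t < 0 or c_t < 0:
        raise ValueError("transfer rate and concentration must be nonnegative")
    return t * c_t * brewing.tea_mass_g / brewing.water_volume_l


def per_sample_transfer(dataset: ConcentrationDataset) -> list[TransferResult]:
    """Pair made-tea and infusion measurements by (sample, element) and
    compute each sample's transfer rate.  Samples lacking either matrix,
    or with a still-censored value, are skipped with a logged count."""
    df = dataset.to_frame()
    made = df[(df.matrix == Matrix.MADE_TEA.value) & df.value.notna()]
    inf = df[(df.matrix == Matrix.INFUSION.value) & df.value.notna()]
    merged = made.merge(
        inf, on=["sample_id", "element"], suffixes=("_t", "_i"), how="outer",
        indicator=True,
    )
    n_unpaired = int((merged["_merge"] != "both").sum())
    if n_unpaired:
        logger.warning("skipped %d unpaired (sample, element) pairs", n_unpaired)
    paired = merged[merged["_merge"] == "both"]
    results = []
    for row in paired.itertuples():
        results.append(
            TransferResult(
                sample_id=row.sample_id,
                element=row.element,
                transfer_rate=transfer_rate(row.value_i, row.value_t, dataset.brewing),
                made_tea_conc=row.value_t,
                infusion_conc=row.value_i,
            )
        )
    return results


def mean_transfer_rates(dataset: ConcentrationDataset) -> pd.DataFrame:
    """Per-element mean, SD and n of per-sample transfer rates.

    The mean is the arithmetic mean of per-sample ratios (each sample is
    one replicate), not the ratio of element totals.  Elements with no
    paired samples are omitted with a warning; SD is NaN for n = 1.

    Returns a DataFrame indexed by element with columns
    ``mean_t``, ``sd_t``, ``n``.
    """
    results = per_sample_transfer(dataset)
    if not results:
        logger.warning("no paired made-tea/infusion samples at all")
        return pd.DataFrame(columns=["mean_t", "sd_t", "n"])
    df = pd.DataFrame(
        [(r.element, r.transfer_rate) for r in results],
        columns=["element", "t"],
    )
    missing = set(dataset.elements()) - set(df.element)
    for e in sorted(missing):
        logger.warning("element %s has no paired samples; omitted", e)
    out = df.groupby("element")["t"].agg(mean_t="mean", sd_t="std", n="count")
    order = [e for e in dataset.elements() if e in out.index]
    return out.loc[order]


def flag_exceedances(
    results: list[TransferResult], threshold: float = 1.0
) -> list[TransferResult]:
    """Subset of results whose transfer rate exceeds ``threshold``."""
    return [r for r in results if r.transfer_rate > threshold]
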