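"""Readers and writers for the package's plain-text interchange formats.

* concentration tables: long-format CSV (``sample_id, element, value``),
  one file per matrix; a configurable token (default ``"ND"``) marks
  below-detection values
* toxicology reference: CSV or YAML (``element, rfd, sf, bioavailability``)
* consumption profiles: YAML list (``name`` plus either
  ``daily_tea_mass_g``/``body_weight_kg`` or ``ratio_g_per_kg_day``)
* risk report: CSV or markdown in the published-table layout — one row per
  element plus an HI row, one (HQ, adjusted HQ) column pair per profile,
  percent scale, two significant figures
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .datatypes import (
    BrewingSpec,
    ConcentrationDataset,
    ConsumptionProfile,
    DEFAULT_BREWING,
    Matrix,
    Measurement,
    ToxRef,
)
from .report import format_hq_percent
from .risk import ExposureResult, RiskSummary

PathLike = Union[str, Path]

DEFAULT_ND_TOKEN = "ND"


class FormatError(ValueError):
    """Input file does not match the expected layout."""


def read_concentrations(
    path: PathLike,
    matrix: Matrix,
    nd_token: str = DEFAULT_ND_TOKEN,
    brewing: BrewingSpec = DEFAULT_BREWING,
) -> ConcentrationDataset:
    """Read a long-format concentration CSV into a dataset.

    Values equal to ``nd_token`` become censored measurements (no numeric
    value); anything else must parse as a nonnegative float.  Unknown
    element symbols and negative values are rejected with the offending
    row named.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "element", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    measurements = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        raw = row.value
        if isinstance(raw, str) and raw.strip() == nd_token:
            m = Measurement(
                sample_id=str(row.sample_id),
                element=str(row.element),
                matrix=matrix,
                censored=True,
            )
        else:
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}:{i}: unparseable value {raw!r}"
                ) from exc
            m = Measurement(
                sample_id=str(row.sample_id),
                element=str(row.element),
                matrix=matrix,
                value=value,
            )
        measurements.append(m)
    return ConcentrationDataset(measurements, brewing)


def write_concentrations(
    dataset: ConcentrationDataset,
    path: PathLike,
    nd_token: str = DEFAULT_ND_TOKEN,
) -> None:
    """Write a dataset back to the long CSV dialect.

    Censored measurements that have not been substituted are written as
    the ND token; substituted ones keep their numeric value (the flag is
    in-memory provenance and is reconstructed by the censoring policy,
    not the file).  Round-trips bit-equal through ``repr`` floats.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "element", "value"])
        for m in dataset:
            value = nd_token if m.value is None else repr(m.value)
            writer.writerow([m.sample_id, m.element, value])


def read_qc_batch(
    path: PathLike, nd_token: str = DEFAULT_ND_TOKEN
) -> ConcentrationDataset:
    """Read a mixed QC batch (blanks + spikes) from a CSV that carries an
    explicit ``matrix`` column alongside ``sample_id, element, value``."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "element", "matrix", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    measurements = []
    for row in df.itertuples():
        raw = row.value
        censored = isinstance(raw, str) and raw.strip() == nd_token
        measurements.append(
            Measurement(
                sample_id=str(row.sample_id),
                element=str(row.element),
                matrix=Matrix(row.matrix),
                value=None if censored else float(raw),
                censored=censored,
            )
        )
    return ConcentrationDataset(measurements)


def write_qc_batch(
    dataset: ConcentrationDataset,
    path: PathLike,
    nd_token: str = DEFAULT_ND_TOKEN,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "element", "matrix", "value"])
        for m in dataset:
            value = nd_token if m.value is None else repr(m.value)
            writer.writerow([m.sample_id, m.element, m.matrix.value, value])


def read_toxref(path: PathLike) -> list[ToxRef]:
    """Read a toxicology reference table from CSV or YAML.

    Columns/keys: ``element``, ``rfd`` (µg/kg bw/day), ``sf``
    ((mg/kg bw/day)^-1, empty for non-carcinogens), ``bioavailability``
    (fraction).
    """
    path = Path(path)
    if path.suffix.lower() in {".yml", ".yaml"}:
        rows = yaml.safe_load(path.read_text())
        if not isinstance(rows, list):
            raise FormatError(f"{path}: expected a YAML list of entries")
    else:
        df = pd.read_csv(path)
        required = {"element", "rfd", "bioavailability"}
        if not required <= set(df.columns):
            raise FormatError(
                f"{path}: missing columns {sorted(required - set(df.columns))}"
            )
        rows = df.to_dict("records")
    refs = []
    for row in rows:
        sf = row.get("sf")
        if sf is not None and pd.isna(sf):
            sf = None
        refs.append(
            ToxRef(
                element=row["element"],
                rfd=row["rfd"],
                sf=sf,
                bioavailability=row["bioavailability"],
            )
        )
    return refs


def write_toxref(refs: Sequence[ToxRef], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "element": t.element,
                "rfd": t.rfd,
                "sf": t.sf,
                "bioavailability": t.bioavailability,
            }
            for t in refs
        ]
    ).to_csv(path, index=False)


def read_profiles(path: PathLike) -> list[ConsumptionProfile]:
    """Read consumption profiles from a YAML list."""
    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list):
        raise FormatError(f"{path}: expected a YAML list of profiles")
    return [ConsumptionProfile(**entry) for entry in entries]


def write_profiles(profiles: Sequence[ConsumptionProfile], path: PathLike) -> None:
    entries = [
        {"name": p.name, "ratio_g_per_kg_day": p.ratio} for p in profiles
    ]
    Path(path).write_text(yaml.safe_dump(entries, sort_keys=False))


def read_sim_specs(path: PathLike) -> list["ElementSimSpec"]:
    """Read per-element simulation parameters from a YAML list
    (keys: element, mean, sd, range_min, range_max, transfer_mean,
    transfer_sd, nd_fraction)."""
    from .synthetic import ElementSimSpec

    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list):
        raise FormatError(f"{path}: expected a YAML list of element specs")
    return [ElementSimSpec(**entry) for entry in entries]


def write_sim_specs(specs: Sequence["ElementSimSpec"], path: PathLike) -> None:
    Path(path).write_text(
        yaml.safe_dump([s.model_dump() for s in specs], sort_keys=False)
    )


def risk_report_frame(
    exposures: Sequence[ExposureResult],
    summaries: Sequence[RiskSummary],
) -> pd.DataFrame:
    """Assemble the published-table layout as a DataFrame of formatted strings.

    Rows: one per element (dataset order) plus a final ``HI`` row.
    Columns: ``HQ (%) <profile>`` then ``Adjusted HQ (%) <profile>`` for
    each profile.  All cells percent scale, 2 significant figures.
    """
    if not summaries:
        raise ValueError("no risk summaries to report")
    profiles = [s.profile for s in summaries]
    by_profile: dict[str, dict[str, ExposureResult]] = {p: {} for p in profiles}
    elements: list[str] = []
    for ex in exposures:
        by_profile[ex.profile][ex.element] = ex
        if ex.element not in elements:
            elements.append(ex.element)
    element_sets = {frozenset(by_profile[p]) for p in profiles}
    if len(element_sets) > 1:
        raise ValueError("profiles do not share a common element set")
    columns: dict[str, list[str]] = {}
    for kind, attr in (("HQ (%)", "hq"), ("Adjusted HQ (%)", "adjusted_hq")):
        for s in summaries:
            col = [
                format_hq_percent(getattr(by_profile[s.profile][e], attr))
                for e in elements
            ]
            col.append(
                format_hq_percent(s.hi if attr == "hq" else s.adjusted_hi)
            )
            columns[f"{kind} {s.profile}"] = col
    return pd.DataFrame(columns, index=elements + ["HI"])


def write_risk_report(
    exposures: Sequence[ExposureResult],
    summaries: Sequence[RiskSummary],
    path: PathLike,
    format: str = "csv",
) -> None:
    """Write the HQ / adjusted-HQ / HI table as CSV or markdown."""
    frame = risk_report_frame(exposures, summaries)
    path = Path(path)
    if format == "csv":
        frame.to_csv(path, index_label="element")
    elif format in {"md", "markdown"}:
        path.write_text(_markdown_table(frame, index_label="element"))
    else:
        raise ValueError(f"unknown report format {format!r}")


def _markdown_table(frame: pd.DataFrame, index_label: str = "") -> str:
    header = [index_label, *map(str, frame.columns)]
    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    for idx, row in frame.iterrows():
        lines.append("| " + " | ".join([str(idx), *map(str, row)]) + " |")
    return "\n".join(lines) + "\n"


def cancer_risk_frame(summaries: Sequence[RiskSummary]) -> pd.DataFrame:
    """Long-format carcinogenic-risk table: one row per (profile, element)
    with TR, bioavailability-adjusted TR, the profile total and the
    element's contribution fraction; full precision (plotting data)."""
    rows = []
    for s in summaries:
        for e, value in s.tr.items():
            rows.append(
                {
                    "profile": s.profile,
                    "element": e,
                    "tr": value,
                    "tr_adjusted": s.tr_adjusted[e],
                    "tr_total": s.tr_total,
                    "contribution": s.contribution[e],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["profile", "element", "tr", "tr_adjusted", "tr_total", "contribution"],
    )


def transfer_report_frame(mean_rates: pd.DataFrame) -> pd.DataFrame:
    """Transfer summary with rates also on the percent scale (bar-chart data)."""
    out = mean_rates.copy()
    out["mean_t_pct"] = out["mean_t"] * 100.0
    return out
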