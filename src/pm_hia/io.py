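"""Reading, validating and writing the long-format input and output tables.

Inputs are tidy CSVs: an exposure table (district, year, pm25) and a
demography table (district, year, age_group, population, deaths).  Validation
is total — every panel invariant is enforced at read time with row-numbered
diagnostics, so downstream code never re-checks.  Output summary tables are
written with bounds in separate low/high columns for machine use, or with
``"x (lo, hi)"`` cells for human reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .ages import AGE_BANDS

__all__ = [
    "ExposurePanel",
    "DemographyPanel",
    "PanelValidationError",
    "read_exposure",
    "read_demography",
    "write_summary",
    "read_summary",
    "RoundingProfile",
    "StudyConfig",
    "load_config",
]

EXPOSURE_COLUMNS = ["district", "year", "pm25"]
DEMOGRAPHY_COLUMNS = ["district", "year", "age_group", "population", "deaths"]


class PanelValidationError(ValueError):
    """An input table violates a panel invariant; message names the rows."""


def _rows(idx) -> str:
    # +2: header line plus 1-based indexing, so messages point at file lines
    shown = [str(i + 2) for i in list(idx)[:8]]
    more = "" if len(idx) <= 8 else f" (+{len(idx) - 8} more)"
    return ", ".join(shown) + more


@dataclass(frozen=True)
class ExposurePanel:
    """District x year annual-mean PM2.5 (µg/m³), unique and non-negative."""

    data: pd.DataFrame

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "ExposurePanel":
        missing = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"exposure table missing columns {missing}")
        df = df.loc[:, EXPOSURE_COLUMNS].copy()
        df["year"] = df["year"].astype(int)
        df["pm25"] = df["pm25"].astype(float)
        dup = df.duplicated(["district", "year"])
        if dup.any():
            raise PanelValidationError(
                f"duplicate (district, year) keys at rows {_rows(df.index[dup])}"
            )
        neg = df["pm25"] < 0
        if neg.any():
            raise PanelValidationError(
                f"negative pm25 at rows {_rows(df.index[neg])}"
            )
        if df["pm25"].isna().any():
            na = df["pm25"].isna()
            raise PanelValidationError(f"missing pm25 at rows {_rows(df.index[na])}")
        return ExposurePanel(df.reset_index(drop=True))

    @property
    def districts(self) -> list[str]:
        return sorted(self.data["district"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())


@dataclass(frozen=True)
class DemographyPanel:
    """District x year x age-band population and cause-specific death counts.

    Counts are integers; deaths never exceed population; every district-year
    carries all 12 bands.
    """

    data: pd.DataFrame

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "DemographyPanel":
        missing = [c for c in DEMOGRAPHY_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError(f"demography table missing columns {missing}")
        df = df.loc[:, DEMOGRAPHY_COLUMNS].copy()
        df["year"] = df["year"].astype(int)

        bad_band = ~df["age_group"].isin(AGE_BANDS)
        if bad_band.any():
            seen = sorted(df.loc[bad_band, "age_group"].unique())
            raise PanelValidationError(
                f"unknown age band(s) {seen} at rows {_rows(df.index[bad_band])}; "
                f"valid bands: {', '.join(AGE_BANDS)}"
            )
        for col in ("population", "deaths"):
            vals = pd.to_numeric(df[col], errors="coerce")
            nonint = vals.isna() | (vals != vals.round())
            if nonint.any():
                raise PanelValidationError(
                    f"non-integer {col} at rows {_rows(df.index[nonint])}"
                )
            df[col] = vals.astype(int)
            neg = df[col] < 0
            if neg.any():
                raise PanelValidationError(
                    f"negative {col} at rows {_rows(df.index[neg])}"
                )
        excess = df["deaths"] > df["population"]
        if excess.any():
            raise PanelValidationError(
                f"deaths exceed population at rows {_rows(df.index[excess])}"
            )
        dup = df.duplicated(["district", "year", "age_group"])
        if dup.any():
            raise PanelValidationError(
                f"duplicate (district, year, age_group) keys at rows "
                f"{_rows(df.index[dup])}"
            )
        counts = df.groupby(["district", "year"])["age_group"].nunique()
        gaps = counts[counts != len(AGE_BANDS)]
        if not gaps.empty:
            keys = ", ".join(f"{d}/{y}" for d, y in gaps.index[:8])
            raise PanelValidationError(
                f"incomplete age-band coverage for district/year: {keys}"
            )
        return DemographyPanel(df.reset_index(drop=True))

    @property
    def districts(self) -> list[str]:
        return sorted(self.data["district"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())


def read_exposure(path: str | Path) -> ExposurePanel:
    """Read and validate a district-year PM2.5 CSV."""
    return ExposurePanel.from_frame(pd.read_csv(path, encoding="utf-8"))


def read_demography(path: str | Path) -> DemographyPanel:
    """Read and validate a district-year-age population/deaths CSV."""
    return DemographyPanel.from_frame(pd.read_csv(path, encoding="utf-8"))


# ---------------------------------------------------------------------------
# summary-table output


@dataclass(frozen=True)
class RoundingProfile:
    """Display rounding for written tables; in-memory values keep full precision."""

    deaths_decimals: int = 0
    rate_decimals: int = 1
    percent_decimals: int = 1


def _rounded(df: pd.DataFrame, profile: RoundingProfile) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in ("year", "age_group"):
            continue
        if col.startswith(("deaths", "attributable", "avoided")) and "rate" not in col:
            out[col] = out[col].round(profile.deaths_decimals).astype(int)
        elif col.startswith("population"):
            out[col] = out[col].round(0).astype(int)
        elif "pct" in col:
            out[col] = out[col].round(profile.percent_decimals)
        elif "rate" in col:
            out[col] = out[col].round(profile.rate_decimals)
    return out


def write_summary(
    table,
    path: str | Path,
    rounding: RoundingProfile | None = RoundingProfile(),
    style: Literal["machine", "human"] = "machine",
) -> Path:
    """Write a summary table to CSV with a deterministic column order.

    ``machine`` keeps bounds as separate ``*_low``/``*_high`` columns;
    ``human`` folds each bounded triple into a single ``"x (lo, hi)"`` cell.
    Pass ``rounding=None`` to write full precision.
    """
    df = table.data if hasattr(table, "data") else table
    df = df.copy()
    if rounding is not None:
        df = _rounded(df, rounding)
    if style == "human":
        bounded = [
            c
            for c in df.columns
            if f"{c}_low" in df.columns and f"{c}_high" in df.columns
        ]
        for col in bounded:
            df[col] = [
                f"{p} ({lo}, {hi})"
                for p, lo, hi in zip(df[col], df[f"{col}_low"], df[f"{col}_high"])
            ]
            df = df.drop(columns=[f"{col}_low", f"{col}_high"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_summary(path: str | Path) -> pd.DataFrame:
    """Read back a machine-style summary CSV."""
    return pd.read_csv(path, encoding="utf-8", keep_default_na=False)


# ---------------------------------------------------------------------------
# run configuration


class ScenarioConfig(BaseModel):
    label: str
    reference_conc: float = Field(ge=0)
    clamp_to_observed: bool = True


class UncertaintyConfig(BaseModel):
    method: Literal["endpoint", "montecarlo"] = "endpoint"
    draws: int = Field(default=1000, ge=100)
    seed: int = 0


class StudyConfig(BaseModel):
    """YAML-backed run configuration for the command-line pipeline."""

    study_window: tuple[int, int] = (2016, 2020)
    reporting_thresholds: list[int] = [25, 45, 65]
    scenarios: list[ScenarioConfig] = []
    uncertainty: UncertaintyConfig = UncertaintyConfig()
    params_path: Optional[str] = None

    @field_validator("study_window")
    @classmethod
    def _ordered(cls, v):
        if v[0] > v[1]:
            raise ValueError(f"study window start {v[0]} after end {v[1]}")
        return v


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return StudyConfig.model_validate(raw)
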