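"""Global Exposure Mortality Model (GEMM) hazard-ratio curves.

The GEMM describes the relative risk of cause-specific mortality as a
supra-linear function of the annual-mean ambient PM2.5 concentration.  For an
exposure increment ``z = max(0, c - c_cf)`` above the counterfactual
concentration ``c_cf`` the model evaluates

    T(z)  = log(1 + z / alpha) * omega(z)
    omega = 1 / (1 + exp(-(z - mu) / nu))
    RR    = exp(theta_age * T(z))

where ``alpha`` (µg/m³) sets the concentration scale of the logarithmic term,
``mu`` and ``nu`` (µg/m³) are the midpoint and width of a logistic weight, and
``theta_age`` is an age-group-specific log-risk coefficient.  Below the
counterfactual concentration no excess risk is assigned (``RR = 1``).

Confidence bounds come from the plug-in interval ``theta ± 1.96 * SE``: the
exponential is monotone, so pushing the endpoint coefficients through the
curve preserves the 95% coverage of the normal interval on ``theta``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from .ages import AGE_BANDS

__all__ = [
    "GemmParameterSet",
    "RrEstimate",
    "gemm_transform",
    "relative_risk",
    "load_gemm_parameters",
    "default_parameter_path",
]

_Z95 = 1.96
ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class RrEstimate:
    """Relative risk with its 95% confidence bounds."""

    rr: float
    rr_low: float
    rr_high: float

    def __post_init__(self) -> None:
        if not (0 < self.rr_low <= self.rr <= self.rr_high):
            raise ValueError(
                f"bounds must satisfy 0 < low <= rr <= high, got "
                f"({self.rr_low}, {self.rr}, {self.rr_high})"
            )


@dataclass(frozen=True)
class GemmParameterSet:
    """Per-cause GEMM coefficients and shape constants.

    ``entries`` maps each 5-year age band to ``(theta, theta_se)``; the shape
    constants ``alpha``, ``mu``, ``nu`` and the counterfactual concentration
    are shared across bands.  ``source_version`` is a free-text provenance tag
    identifying which published GEMM fit was transcribed.
    """

    cause: str
    entries: dict[str, tuple[float, float]]
    alpha: float
    mu: float
    nu: float
    counterfactual_conc: float
    source_version: str = field(default="unspecified")

    def __post_init__(self) -> None:
        missing = [b for b in AGE_BANDS if b not in self.entries]
        extra = [b for b in self.entries if b not in AGE_BANDS]
        if missing or extra:
            raise ValueError(
                f"parameter set must cover exactly the 12 bands "
                f"{', '.join(AGE_BANDS)}; missing={missing}, unknown={extra}"
            )
        for band, (theta, se) in self.entries.items():
            if not math.isfinite(theta) or not math.isfinite(se):
                raise ValueError(f"non-finite coefficient in band {band!r}")
            if se < 0:
                raise ValueError(f"theta_se must be >= 0, got {se} in band {band!r}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")
        if self.counterfactual_conc < 0:
            raise ValueError(
                f"counterfactual_conc must be >= 0, got {self.counterfactual_conc}"
            )

    def theta(self, age_group: str) -> tuple[float, float]:
        """``(theta, theta_se)`` for a band; raises ``KeyError`` if unknown."""
        try:
            return self.entries[age_group]
        except KeyError:
            raise KeyError(
                f"age band {age_group!r} not in parameter set; valid bands: "
                f"{', '.join(AGE_BANDS)}"
            ) from None


def gemm_transform(concentration: ArrayLike, params: GemmParameterSet) -> ArrayLike:
    """Evaluate the GEMM concentration transform ``T(z)``.

    Accepts a scalar or ndarray of annual-mean PM2.5 concentrations (µg/m³).
    Returns 0 at or below the counterfactual concentration and is strictly
    increasing above it.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        bad = c[c < 0] if c.ndim else c
        raise ValueError(f"concentration must be >= 0, got {np.atleast_1d(bad)[0]}")
    z = np.maximum(0.0, c - params.counterfactual_conc)
    omega = 1.0 / (1.0 + np.exp(-(z - params.mu) / params.nu))
    t = np.log1p(z / params.alpha) * omega
    if np.ndim(concentration) == 0:
        return float(t)
    return t


def relative_risk(
    concentration: float, age_group: str, params: GemmParameterSet
) -> RrEstimate:
    """Relative risk of cause-specific mortality at a given concentration.

    The point estimate is ``exp(theta * T)``; the bounds push
    ``theta ± 1.96 * SE`` through the same curve.  All three collapse to 1
    when the exposure increment above the counterfactual is zero.
    """
    theta, se = params.theta(age_group)
    t = gemm_transform(concentration, params)
    lo = math.exp((theta - _Z95 * se) * t)
    hi = math.exp((theta + _Z95 * se) * t)
    return RrEstimate(rr=math.exp(theta * t), rr_low=min(lo, hi), rr_high=max(lo, hi))


def default_parameter_path() -> Path:
    """Path of the packaged ischemic-heart-disease GEMM parameter file."""
    return Path(str(resources.files("pm_hia").joinpath("data/gemm_ihd.csv")))


def load_gemm_parameters(path: str | Path | None = None) -> GemmParameterSet:
    """Read a GEMM parameter file and return a validated parameter set.

    The file is a CSV with header ``cause,age_group,theta,theta_se`` preceded
    by a commented YAML block carrying the shared constants::

        # alpha: 1.9
        # mu: 12.0
        # ...

    With ``path=None`` the packaged IHD file is loaded.
    """
    path = default_parameter_path() if path is None else Path(path)
    text = path.read_text(encoding="utf-8")

    header_lines: list[str] = []
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            header_lines.append(line.lstrip().lstrip("#").rstrip())
        elif line.strip():
            body_lines.append(line)
    # free-text comment lines are allowed; only `key: value` lines are metadata
    kv_lines = [
        ln for ln in header_lines if re.match(r"^\s*[A-Za-z_][A-Za-z0-9_]*:\s", ln)
    ]
    meta = yaml.safe_load("\n".join(kv_lines)) or {}
    if not isinstance(meta, dict):
        raise ValueError(f"{path}: commented header block is not a YAML mapping")
    required = ("alpha", "mu", "nu", "counterfactual_conc")
    missing_meta = [k for k in required if k not in meta]
    if missing_meta:
        raise ValueError(f"{path}: header block missing keys {missing_meta}")

    expected_cols = ["cause", "age_group", "theta", "theta_se"]
    rows = [line.split(",") for line in body_lines]
    if not rows or [c.strip() for c in rows[0]] != expected_cols:
        raise ValueError(f"{path}: expected header {','.join(expected_cols)}")

    cause: str | None = None
    entries: dict[str, tuple[float, float]] = {}
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise ValueError(f"{path}: row {i}: expected 4 fields, got {len(row)}")
        row_cause, band, theta_s, se_s = (f.strip() for f in row)
        if cause is None:
            cause = row_cause
        elif row_cause != cause:
            raise ValueError(f"{path}: row {i}: mixed causes {cause!r} and {row_cause!r}")
        if band in entries:
            raise ValueError(f"{path}: row {i}: duplicate age band {band!r}")
        try:
            theta, se = float(theta_s), float(se_s)
        except ValueError:
            raise ValueError(
                f"{path}: row {i}: non-numeric theta/theta_se ({theta_s!r}, {se_s!r})"
            ) from None
        entries[band] = (theta, se)

    if cause is None:
        raise ValueError(f"{path}: no coefficient rows")
    try:
        return GemmParameterSet(
            cause=cause,
            entries=entries,
            alpha=float(meta["alpha"]),
            mu=float(meta["mu"]),
            nu=float(meta["nu"]),
            counterfactual_conc=float(meta["counterfactual_conc"]),
            source_version=str(meta.get("source_version", "unspecified")),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None
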