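"""Population-attributable-fraction arithmetic for burden and benefit.

The burden PAF is the fraction of observed deaths attributable to current
exposure,

    PAF_burden = p (RR - 1) / (1 + p (RR - 1)),

with exposure prevalence ``p = 1`` for ambient air pollution (exposure is
ubiquitous), where it reduces to ``1 - 1/RR_baseline``.  The benefit PAF is
the fraction of deaths avoided by lowering exposure to a reference level,

    PAF_benefit = 1 - RR_reference / RR_baseline.

Attributable (or avoided) deaths are observed deaths times the PAF: with the
mortality rate M = deaths / population, the product M x PAF x Population
cancels exactly to deaths x PAF, so no rounded rate ever enters the burden
arithmetic.

All functions accept scalars or numpy arrays and broadcast elementwise.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "paf_burden",
    "paf_benefit",
    "attributable_deaths",
    "rate_per_100k",
    "avoidable_mortality_rate",
]


def _as_float(x):
    a = np.asarray(x, dtype=float)
    return a


def _maybe_scalar(a, like):
    return float(a) if np.ndim(like) == 0 else a


def paf_burden(rr_baseline, prevalence: float = 1.0):
    """Population attributable fraction of the existing exposure burden.

    Computes ``p(RR-1) / (1 + p(RR-1))``; at ``p = 1`` this is algebraically
    identical to ``1 - 1/RR``.  An RR below 1 (possible only if risk clamping
    below the counterfactual is disabled) produces a negative fraction, which
    is passed through with a warning rather than rejected, so configuration
    mistakes stay auditable.
    """
    rr = _as_float(rr_baseline)
    if np.any(rr <= 0):
        raise ValueError(f"rr_baseline must be > 0, got {np.min(rr)}")
    if not (0 < prevalence <= 1):
        raise ValueError(f"prevalence must be in (0, 1], got {prevalence}")
    excess = prevalence * (rr - 1.0)
    if np.any(excess < 0):
        warnings.warn(
            "RR < 1 produced a negative attributable fraction; exposure below "
            "the counterfactual is normally clamped to RR = 1",
            stacklevel=2,
        )
    return _maybe_scalar(excess / (1.0 + excess), rr_baseline)


def paf_benefit(rr_baseline, rr_reference):
    """Attributable fraction avoided by reducing exposure to a reference level.

    ``1 - RR_reference / RR_baseline``: zero when the reference scenario does
    not change the risk, and equal to the p=1 burden PAF when the reference
    risk is 1 (full rollback to the counterfactual).
    """
    base = _as_float(rr_baseline)
    ref = _as_float(rr_reference)
    if np.any(base <= 0) or np.any(ref <= 0):
        raise ValueError("relative risks must be > 0")
    return _maybe_scalar(1.0 - ref / base, rr_baseline)


def attributable_deaths(deaths, paf):
    """Deaths attributable to (or avoided under) a scenario: deaths x PAF."""
    d = _as_float(deaths)
    if np.any(d < 0):
        raise ValueError(f"deaths must be >= 0, got {np.min(d)}")
    return _maybe_scalar(d * _as_float(paf), deaths)


def rate_per_100k(count, population):
    """Rate per 100,000 population."""
    pop = _as_float(population)
    if np.any(pop <= 0):
        raise ValueError(f"population must be > 0, got {np.min(pop)}")
    return _maybe_scalar(1e5 * _as_float(count) / pop, count)


def avoidable_mortality_rate(avoided_deaths, ihd_deaths):
    """Avoided deaths as a percentage of observed cause-specific deaths."""
    d = _as_float(ihd_deaths)
    if np.any(d <= 0):
        raise ValueError("avoidable mortality rate is undefined for zero deaths")
    return _maybe_scalar(100.0 * _as_float(avoided_deaths) / d, avoided_deaths)
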