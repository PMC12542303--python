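"""Canonical 5-year age-band labels for adult (25+) mortality strata.

The band dialect is fixed as ``"25-29" ... "75-79", "80+"``; the terminal
open-ended band pools everyone aged 80 and above.
"""

from __future__ import annotations

AGE_BANDS: tuple[str, ...] = (
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80+",
)

#: Lower bound (years) of each band, used to map bands onto reporting groups.
BAND_LOWER_AGE: dict[str, int] = {
    band: int(band.split("-")[0].rstrip("+")) for band in AGE_BANDS
}


def validate_band(age_group: str) -> str:
    """Return ``age_group`` if it is a known band, else raise ``KeyError``."""
    if age_group not in BAND_LOWER_AGE:
        raise KeyError(
            f"unknown age band {age_group!r}; valid bands are {', '.join(AGE_BANDS)}"
        )
    return age_group


def bands_at_or_above(threshold: int) -> list[str]:
    """Bands whose lower age bound is >= ``threshold`` (e.g. 25, 45, 65)."""
    return [b for b in AGE_BANDS if BAND_LOWER_AGE[b] >= threshold]
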