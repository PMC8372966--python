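"""Six microhabitat classification schemes.

Species carry a primary and (optionally) a secondary adult microhabitat
code — arboreal (A), cave (C), fossorial (F), saxicolous (S), terrestrial
(T), aquatic (W), or semi-aquatic (SW) — plus a flag recording whether an
alternative literature source (which counts vegetation-climbers as
arboreal) lists the species as arboreal. The schemes differ along three
axes:

* majority-rule (``-M``: the primary code wins) versus lenient (``-L``: a
  terrestrial primary is overridden by a non-terrestrial secondary);
* six versus seven categories (``7-`` schemes keep semi-aquatic as its own
  category; ``6-`` schemes remap SW species to aquatic or another
  non-aquatic category, recorded per species in an override column);
* the alternative arboreality source (``-Mc-`` schemes force category A
  when the flag is set).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

PRIMARY_CODES = frozenset({"A", "C", "F", "S", "T", "W", "SW"})
SIX_CATEGORIES = frozenset({"A", "C", "F", "S", "T", "W"})
SEVEN_CATEGORIES = SIX_CATEGORIES | {"SW"}

SCHEMES: tuple[str, ...] = ("6-M", "6-L", "7-M", "7-L", "6-McM", "6-McL")

#: Permitted output categories per scheme.
SCHEME_CATEGORIES: dict[str, frozenset[str]] = {
    "6-M": SIX_CATEGORIES,
    "6-L": SIX_CATEGORIES,
    "7-M": SEVEN_CATEGORIES,
    "7-L": SEVEN_CATEGORIES,
    "6-McM": SIX_CATEGORIES,
    "6-McL": SIX_CATEGORIES,
}


class ClassificationError(ValueError):
    """Raised for unknown codes or schemes."""


@dataclass(frozen=True)
class MicrohabitatRecord:
    """One species' raw microhabitat data.

    ``sw_override`` records, per species, the category a semi-aquatic
    species falls into under six-category schemes (defaults to aquatic);
    this is natural-history information, not derivable by rule.
    """

    species_id: str
    primary: str
    secondary: str | None = None
    mcentire_arboreal: bool = False
    sw_override: str | None = None

    def __post_init__(self) -> None:
        if self.primary not in PRIMARY_CODES:
            raise ClassificationError(
                f"{self.species_id}: unknown primary code {self.primary!r}"
            )
        if self.secondary is not None and self.secondary not in PRIMARY_CODES:
            raise ClassificationError(
                f"{self.species_id}: unknown secondary code {self.secondary!r}"
            )
        if self.sw_override is not None and self.sw_override not in SIX_CATEGORIES:
            raise ClassificationError(
                f"{self.species_id}: sw_override must be a six-category code, "
                f"got {self.sw_override!r}"
            )


def classify(record: MicrohabitatRecord, scheme: str) -> str:
    """Single category for one species under one scheme.

    Majority-rule schemes return the primary code. Lenient schemes
    override a terrestrial primary with a non-terrestrial secondary
    (secondary codes are only consulted when the primary is terrestrial).
    Under six-category schemes a resulting SW is remapped to the species'
    ``sw_override`` (aquatic by default). Under the alternative-source
    schemes the arboreal flag forces category A outright.
    """
    if scheme not in SCHEMES:
        raise ClassificationError(f"unknown scheme {scheme!r}")

    if "Mc" in scheme and record.mcentire_arboreal:
        return "A"

    lenient = scheme.endswith("L")
    category = record.primary
    if (
        lenient
        and record.primary == "T"
        and record.secondary is not None
        and record.secondary != "T"
    ):
        category = record.secondary

    if scheme.startswith("6") and category == "SW":
        category = record.sw_override or "W"

    assert category in SCHEME_CATEGORIES[scheme]
    return category


def classify_table(
    records: pd.DataFrame, schemes: tuple[str, ...] = SCHEMES
) -> pd.DataFrame:
    """Wide per-scheme classification table (one column per scheme).

    ``records`` needs columns species, primary and optionally secondary,
    mcentire_arboreal, sw_override. Missing values are treated as absent.
    """
    def _get(row, col, default=None):
        if col not in records.columns:
            return default
        v = row[col]
        return default if pd.isna(v) else v

    out = {"species": records["species"].tolist()}
    recs = [
        MicrohabitatRecord(
            species_id=row["species"],
            primary=row["primary"],
            secondary=_get(row, "secondary"),
            mcentire_arboreal=bool(_get(row, "mcentire_arboreal", False)),
            sw_override=_get(row, "sw_override"),
        )
        for _, row in records.iterrows()
    ]
    for scheme in schemes:
        out[scheme] = [classify(r, scheme) for r in recs]
    return pd.DataFrame(out)
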