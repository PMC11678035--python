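"""Batch adsorption/desorption statistics for drug-humic interactions.

Each batch experiment mixes a drug solution with humic acid, equilibrates,
and measures the remaining solution concentration; the recovered solid is
then shaken with fresh water and the leached concentration measured.  Two
standard mass-balance percentages summarise a record:

* adsorption efficiency — the share of the initial drug removed from
  solution, ``100 (c0 - c_eq) / c0``;
* mobile fraction — the share of the *adsorbed* drug released back into
  water, ``100 c_leach V / ((c0 - c_eq) V)``; its complement is the
  strongly bound fraction.

Both are invariant under rescaling all concentrations, so they compare
doses directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .simulate import SorptionRecord

__all__ = [
    "SorptionSummary",
    "adsorption_efficiency",
    "mobile_fraction",
    "sorption_table",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class SorptionSummary:
    """Derived percentages for one batch record (NaN when undefined)."""

    c0: float
    adsorption_efficiency: float
    adsorbed_amount: float
    mobile_fraction: float
    strongly_bound_fraction: float
    note: str = ""


def adsorption_efficiency(record: SorptionRecord) -> float:
    """Percentage of the initial drug adsorbed at batch equilibrium."""
    if record.c0 <= 0:
        raise ValidationError("adsorption efficiency undefined for c0 = 0")
    return 100.0 * (record.c0 - record.c_eq_ads) / record.c0


def mobile_fraction(record: SorptionRecord) -> float:
    """Percentage of the adsorbed drug leached back into water.

    Undefined (raises) when nothing adsorbed; a leached amount exceeding
    the adsorbed amount is rejected at record construction already.
    """
    adsorbed = record.adsorbed_amount
    if adsorbed <= 0:
        raise ValidationError("mobile fraction undefined: nothing was adsorbed")
    return 100.0 * record.leached_amount / adsorbed


def sorption_table(records: Iterable[SorptionRecord]) -> list[SorptionSummary]:
    """Summarise a batch series, sorted by dose; bad rows flagged, not fatal."""
    records = list(records)
    if not records:
        raise ValidationError("sorption_table needs at least one record")
    out: list[SorptionSummary] = []
    for rec in sorted(records, key=lambda r: r.c0):
        note = ""
        try:
            eff = adsorption_efficiency(rec)
        except ValidationError as exc:
            eff, note = math.nan, str(exc)
        try:
            mob = mobile_fraction(rec)
            strong = 100.0 - mob
        except ValidationError as exc:
            mob = strong = math.nan
            note = (note + "; " if note else "") + str(exc)
        out.append(
            SorptionSummary(
                c0=rec.c0,
                adsorption_efficiency=eff,
                adsorbed_amount=rec.adsorbed_amount,
                mobile_fraction=mob,
                strongly_bound_fraction=strong,
                note=note,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[SorptionSummary]) -> pd.DataFrame:
    """Tabulate summaries for CSV serialisation."""
    return pd.DataFrame(
        {
            "c0": [s.c0 for s in summaries],
            "adsorption_efficiency_pct": [s.adsorption_efficiency for s in summaries],
            "adsorbed_amount_mg": [s.adsorbed_amount for s in summaries],
            "mobile_fraction_pct": [s.mobile_fraction for s in summaries],
            "strongly_bound_fraction_pct": [s.strongly_bound_fraction for s in summaries],
            "note": [s.note for s in summaries],
        }
    )
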