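"""Relative growth rate and growing degree-days.

RGR between the two destructive harvests of a pot pair follows the classical
mean relative growth rate, (ln W₂ − ln W₁)/Δt, computed from the aboveground
dry masses of the paired plants. Growing degree-days use the daily max/min
average above a species base temperature (5.6 °C for Dactylis glomerata,
below which it does not grow), accumulated over a window counting only
positive daily values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .data_model import PairMap
from .errors import ValidationError

#: Base temperature below which Dactylis glomerata does not grow, °C.
DACTYLIS_BASE_TEMP_C = 5.6


@dataclass(frozen=True)
class GrowthPair:
    """Aboveground dry masses of a t₁/t₁₄ plant pair."""

    w1: float
    w2: float
    dt: float

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValidationError(f"biomass must be > 0 (w1={self.w1}, "
                                  f"w2={self.w2})")
        if self.dt <= 0:
            raise ValidationError(f"dt={self.dt} must be > 0")


def rgr(pair: GrowthPair) -> float:
    """Mean relative growth rate (ln w₂ − ln w₁)/Δt, d⁻¹.

    Negative for shrinking plants; antisymmetric under swapping w₁ and w₂.
    """
    return (math.log(pair.w2) - math.log(pair.w1)) / pair.dt


def gdd_day(t_max: float, t_min: float,
            base: float = DACTYLIS_BASE_TEMP_C) -> float:
    """Growing degree-days for one day: max(0, (t_max + t_min)/2 − base)."""
    if t_max < t_min:
        raise ValidationError(f"t_max={t_max} < t_min={t_min}")
    return max(0.0, (t_max + t_min) / 2.0 - base)


def cumulative_gdd(series: pd.DataFrame, location: str,
                   start: str | pd.Timestamp, end: str | pd.Timestamp,
                   base: float = DACTYLIS_BASE_TEMP_C) -> float:
    """Sum of positive daily GDD for ``location`` over [start, end].

    Calendar gaps inside the window are reported with a warning and
    contribute nothing (no interpolation); an empty window returns 0 with
    a warning.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    sub = series[(series["location"] == location)
                 & (pd.to_datetime(series["date"]) >= start)
                 & (pd.to_datetime(series["date"]) <= end)]
    if sub.empty:
        warnings.warn(f"no temperature records for {location} in "
                      f"[{start.date()}, {end.date()}]", stacklevel=2)
        return 0.0
    expected = pd.date_range(start, end, freq="D")
    have = set(pd.to_datetime(sub["date"]).dt.normalize())
    gaps = [d for d in expected if d not in have]
    if gaps:
        warnings.warn(f"{len(gaps)} missing day(s) for {location} in window "
                      f"(first: {gaps[0].date()})", stacklevel=2)
    return float(sum(gdd_day(r.t_max_c, r.t_min_c, base)
                     for r in sub.itertuples(index=False)))


def rgr_pipeline(df: pd.DataFrame, pair_map: PairMap
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RGR for every harvest pair and species, with an exclusion ledger.

    Pairs with missing or non-positive biomass at either harvest are
    recorded in the ledger and skipped; shrinking plants yield negative RGR
    with a flag (they are legitimate growth observations even though they
    disqualify the pair for uptake estimation).
    """
    by_pot = {pid: grp.set_index("species")
              for pid, grp in df.groupby("pot_id", sort=False)}
    pots = df.drop_duplicates("pot_id").set_index("pot_id")
    rows, ledger = [], []
    for cell, hp in sorted(pair_map.harvest_pairs.items()):
        site, block, rep, fert, comb, label = cell
        dt = (float(pots.loc[hp.t14_pot_id, "harvest_day"])
              - float(pots.loc[hp.t1_pot_id, "harvest_day"]))
        t1p, t14p = by_pot[hp.t1_pot_id], by_pot[hp.t14_pot_id]
        for species in t1p.index:
            if species not in t14p.index:
                continue
            w1 = t1p.loc[species, "plant_biomass_g"]
            w2 = t14p.loc[species, "plant_biomass_g"]
            if pd.isna(w1) or pd.isna(w2) or w1 <= 0 or w2 <= 0:
                ledger.append({"site": site, "block": block, "replicate": rep,
                               "fertiliser": fert, "combination": comb,
                               "label": label, "species": species,
                               "reason": "missing or non-positive biomass"})
                continue
            value = rgr(GrowthPair(float(w1), float(w2), dt))
            rows.append({"site": site, "block": block, "replicate": rep,
                         "fertiliser": fert, "combination": comb,
                         "label": label, "species": species, "rgr_per_d": value,
                         "w1_g": float(w1), "w2_g": float(w2), "dt": dt,
                         "flags": "shrank" if value < 0 else ""})
    return pd.DataFrame(rows), pd.DataFrame(
        ledger, columns=["site", "block", "replicate", "fertiliser",
                         "combination", "label", "species", "reason"])


def gdd_report(series: pd.DataFrame, windows: dict[str, tuple[str, str]],
               base: float = DACTYLIS_BASE_TEMP_C) -> pd.DataFrame:
    """Cumulative GDD per location over per-location windows.

    ``windows`` maps location → (start, end) ISO dates; returns a tidy
    report table (location, start, end, cumulative_gdd).
    """
    rows = []
    for location, (start, end) in windows.items():
        rows.append({"location": location, "start": start, "end": end,
                     "cumulative_gdd": cumulative_gdd(series, location,
                                                      start, end, base)})
    return pd.DataFrame(rows)
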