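"""Community ecology layer: productivity, growth calls, interactions, diversity.

Definitions follow the study's conventions. "Maximum monoculture
productivity" of a medium is the highest cells/ml reached by any species in
monoculture at any sampled timepoint; "maximum co-culture productivity" is
the highest total cells/ml reached by the co-culture. Replicates are
averaged at each timepoint before taking maxima. Growth on a substrate is
positive when a species' maximum is at least twice its maximum on the water
control. Co-culture totals at least 20% below the monoculture maximum are
called competition, at least 20% above cross-feeding, otherwise neutral;
the same ±20% margin defines per-species benefit. Community diversity is
Simpson's evenness E = (1/Σ pᵢ²)/S with S the seeded richness (4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROWTH_FACTOR = 2.0
INTERACTION_MARGIN = 0.20
SEEDED_RICHNESS = 4

#: Tidy growth-series columns: one row per (species, timepoint, replicate).
SERIES_COLUMNS = ("species", "timepoint", "replicate", "abundance")


@dataclass
class EcologySummary:
    medium: str
    substrate_class: str
    max_mono_productivity: float
    max_co_productivity: float
    growth_calls: dict[str, bool]
    interaction_call: str
    species_benefit: dict[str, bool]


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    missing = set(SERIES_COLUMNS) - set(series.columns)
    if missing:
        raise ValueError(f"growth series lacks columns {sorted(missing)}")
    if series.empty:
        raise ValueError("empty growth series")
    if (series["abundance"] < 0).any():
        raise ValueError("abundances must be >= 0")
    return series


def max_productivity(series: pd.DataFrame, scope: str = "mono") -> float:
    """Replicate-mean-then-max productivity.

    mono scope: max over (species, timepoint) of the replicate-mean
    abundance. co scope: totals are summed across species per (timepoint,
    replicate) first, then replicate-averaged and maximized. If the series
    already carries totals (single pseudo-species), both scopes coincide.
    """
    series = _validate_series(series)
    if scope == "mono":
        means = series.groupby(["species", "timepoint"])["abundance"].mean()
    elif scope == "co":
        totals = series.groupby(["timepoint", "replicate"])["abundance"].sum()
        means = totals.groupby("timepoint").mean()
    else:
        raise ValueError(f"scope must be 'mono' or 'co', got {scope!r}")
    return float(means.max())


def max_per_replicate_then_mean(series: pd.DataFrame) -> float:
    """Alternative convention: max over timepoints within each replicate,
    then mean across replicates. Provided for audit; not the default."""
    series = _validate_series(series)
    per_rep = series.groupby("replicate")["abundance"].max()
    return float(per_rep.mean())


def growth_positive(substrate_max, control_max, factor: float = GROWTH_FACTOR) -> bool:
    """True iff the substrate maximum is at least ``factor``x the control's.

    Accepts scalars or abundance arrays (maxima are taken). A zero control
    maximum is treated as positive iff the substrate shows any growth.
    """
    s = float(np.max(np.asarray(substrate_max, dtype=float)))
    c = float(np.max(np.asarray(control_max, dtype=float)))
    if s < 0 or c < 0:
        raise ValueError("abundances must be >= 0")
    if c == 0:
        logger.info("zero water-control maximum; calling positive iff substrate grew")
        return s > 0
    return s >= factor * c


def interaction_call(max_co: float, max_mono: float,
                     margin: float = INTERACTION_MARGIN) -> str:
    """competition / cross_feeding / neutral from the ±margin rule."""
    if max_mono <= 0:
        raise ValueError("monoculture maximum must be > 0 for an interaction call")
    if max_co <= (1.0 - margin) * max_mono:
        return "competition"
    if max_co >= (1.0 + margin) * max_mono:
        return "cross_feeding"
    return "neutral"


def species_benefit(species_max_in_co: float, species_max_in_mono: float,
                    margin: float = INTERACTION_MARGIN) -> bool:
    """True iff the species does at least ``margin`` better in co-culture.

    A species absent in monoculture but present in co-culture benefits by
    definition (infinite ratio; e.g. growth enabled by cross-fed breakdown
    products).
    """
    if species_max_in_mono < 0 or species_max_in_co < 0:
        raise ValueError("abundances must be >= 0")
    if species_max_in_mono == 0:
        if species_max_in_co > 0:
            logger.info("species grew only in co-culture (infinite benefit ratio)")
            return True
        return False
    return species_max_in_co >= (1.0 + margin) * species_max_in_mono


def simpson_evenness(relative, richness: int = SEEDED_RICHNESS) -> float:
    """Simpson's evenness E = (1/Σ pᵢ²)/S; 1 at the uniform community.

    ``richness`` is the seeded species count (4 for all co-cultures here),
    not the detected count, so the index is continuous as species cross the
    detection limit.
    """
    p = np.asarray(list(relative.values()) if isinstance(relative, dict) else relative,
                   dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be >= 0")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero profile: evenness undefined")
    p = p / total
    return float(1.0 / np.sum(p**2) / richness)


def summarize_medium(medium: str, substrate_class: str,
                     mono_series: pd.DataFrame, co_series: pd.DataFrame,
                     water_mono_series: pd.DataFrame | None = None,
                     margin: float = INTERACTION_MARGIN,
                     growth_factor: float = GROWTH_FACTOR) -> EcologySummary:
    """Assemble the per-medium ecology calls from tidy growth series.

    ``mono_series``/``co_series`` are tidy frames (SERIES_COLUMNS) for this
    medium; ``water_mono_series`` is the monoculture series on the water
    control, used for growth calls (omitted -> no growth calls).
    """
    max_mono = max_productivity(mono_series, "mono")
    max_co = max_productivity(co_series, "co")
    call = interaction_call(max_co, max_mono, margin) if max_mono > 0 else "undefined"

    growth_calls: dict[str, bool] = {}
    benefit: dict[str, bool] = {}
    for sp, grp in mono_series.groupby("species"):
        sp_mono_max = max_productivity(grp, "mono")
        if water_mono_series is not None:
            water = water_mono_series[water_mono_series["species"] == sp]
            if not water.empty:
                growth_calls[str(sp)] = growth_positive(
                    sp_mono_max, max_productivity(water, "mono"), growth_factor)
        sp_co = co_series[co_series["species"] == sp]
        if not sp_co.empty:
            benefit[str(sp)] = species_benefit(
                max_productivity(sp_co, "mono"), sp_mono_max, margin)
    return EcologySummary(medium=medium, substrate_class=substrate_class,
                          max_mono_productivity=max_mono,
                          max_co_productivity=max_co,
                          growth_calls=growth_calls,
                          interaction_call=call,
                          species_benefit=benefit)
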