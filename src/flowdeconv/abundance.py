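"""Relative and absolute species abundances with background correction.

Relative abundance of a species in a sample is the summed weight of the
clusters assigned to it. Absolute totals come from volumetric counting: the
cytometer records every retained event in a fixed injected volume (3 µl),
so cells/ml = retained events / volume × dilution factor (samples were
diluted 5-fold before acquisition). Sterile-media controls estimate
background: monoculture totals subtract the sterile total directly, while
co-cultures subtract species-specific backgrounds (sterile clusters run
through the same classifier) because background particles autofluoresce and
would otherwise bias individual species. Negative corrected values clamp to
zero and are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import ClusterClassifier, ClusterPrediction, predict
from .clustering import ClusterSet
from .events import SPECIES, SampleMeta

logger = logging.getLogger(__name__)

WEIGHT_TOL = 1e-6


@dataclass
class BackgroundModel:
    """Per-medium background in cells/ml, split by apparent species."""

    medium: str
    per_species_background: dict[str, float]
    total_background: float

    def __post_init__(self) -> None:
        if self.total_background < 0 or any(v < 0 for v in self.per_species_background.values()):
            raise ValueError("background abundances must be >= 0")


@dataclass
class AbundanceProfile:
    sample_id: str
    relative: dict[str, float]
    absolute: dict[str, float]  # cells/ml, post-correction if corrected
    total_absolute: float
    corrected: bool = False
    background_ref: str | None = None


def relative_abundance(predictions: list[ClusterPrediction],
                       clusterset: ClusterSet) -> dict[str, float]:
    """Species fraction = sum of its clusters' weights."""
    if len(predictions) != clusterset.k:
        raise ValueError("every cluster must carry a prediction")
    out = {sp: 0.0 for sp in SPECIES}
    total = 0.0
    for pred, cluster in zip(predictions, clusterset.clusters):
        out[pred.species] = out.get(pred.species, 0.0) + cluster.weight
        total += cluster.weight
    if clusterset.k and abs(total - 1.0) > WEIGHT_TOL:
        raise ValueError(f"cluster weights sum to {total}, not 1")
    return out


def absolute_total(retained_count: int, meta: SampleMeta) -> float:
    """Volumetric count -> cells/ml: count / volume(ml) × dilution factor."""
    if retained_count < 0:
        raise ValueError("retained count must be >= 0")
    vol_ml = meta.acquisition_volume_ul * 1e-3
    if vol_ml <= 0:
        raise ValueError("acquisition volume must be positive")
    return retained_count / vol_ml * meta.dilution_factor


def correct_monoculture(sample_total: float, sterile_total: float) -> float:
    """Subtract the sterile-media background total, clamped at zero."""
    if sample_total < 0 or sterile_total < 0:
        raise ValueError("abundances must be >= 0")
    corrected = sample_total - sterile_total
    if corrected < 0:
        logger.info("monoculture correction clamped to 0 (%.3g - %.3g)",
                    sample_total, sterile_total)
    return max(0.0, corrected)


def correct_coculture(per_species: dict[str, float],
                      background: BackgroundModel | None) -> dict[str, float]:
    """Subtract species-specific background from each species, clamped at 0."""
    if background is None:
        logger.warning("no background model for this medium; assuming zero background")
        bg = {}
    else:
        bg = background.per_species_background
    out = {}
    for sp, value in per_species.items():
        corrected = value - bg.get(sp, 0.0)
        if corrected < 0:
            logger.info("co-culture correction for %s clamped to 0", sp)
        out[sp] = max(0.0, corrected)
    return out


def build_background(medium: str,
                     sterile_samples: list[tuple[SampleMeta, ClusterSet, int]],
                     clf: ClusterClassifier) -> BackgroundModel:
    """Estimate a medium's background by classifying its sterile clusters.

    ``sterile_samples``: (meta, clusterset, retained_count) for each sterile
    replicate of the medium; replicates are pooled by averaging their totals.
    Below-detection controls contribute zero background.
    """
    totals, per_species_runs = [], []
    for meta, cs, retained in sterile_samples:
        total = absolute_total(retained, meta)
        split = {sp: 0.0 for sp in SPECIES}
        if not cs.below_detection and cs.clusters:
            for pred, cluster in zip(predict(clf, cs), cs.clusters):
                split[pred.species] += cluster.weight * total
        else:
            total = 0.0
        totals.append(total)
        per_species_runs.append(split)
    if not totals:
        return BackgroundModel(medium, {sp: 0.0 for sp in SPECIES}, 0.0)
    pooled = {
        sp: float(np.mean([run[sp] for run in per_species_runs])) for sp in SPECIES
    }
    return BackgroundModel(medium, pooled, float(np.mean(totals)))


def profile_sample(meta: SampleMeta, clusterset: ClusterSet, retained_count: int,
                   clf: ClusterClassifier,
                   background: BackgroundModel | None = None) -> AbundanceProfile:
    """Full abundance accounting for one sample.

    The absolute total always uses the full gated event count (never the
    clustering subsample); proportions come from the mixture weights.
    Monocultures subtract the background total from their seeded species;
    co-cultures subtract per-species backgrounds.
    """
    total = absolute_total(retained_count, meta)
    if clusterset.below_detection or not clusterset.clusters:
        zero = {sp: 0.0 for sp in SPECIES}
        return AbundanceProfile(meta.sample_id, relative=zero, absolute=zero,
                                total_absolute=0.0, corrected=background is not None,
                                background_ref=background.medium if background else None)

    preds = predict(clf, clusterset)
    rel = relative_abundance(preds, clusterset)
    raw_abs = {sp: rel[sp] * total for sp in SPECIES}

    if background is None:
        return AbundanceProfile(meta.sample_id, relative=rel, absolute=raw_abs,
                                total_absolute=total, corrected=False)

    if meta.culture_type.startswith("mono:"):
        sp = meta.species
        corrected_total = correct_monoculture(total, background.total_background)
        corr = {s: 0.0 for s in SPECIES}
        corr[sp] = corrected_total
    else:
        corr = correct_coculture(raw_abs, background)
        corrected_total = sum(corr.values())
    return AbundanceProfile(meta.sample_id, relative=rel, absolute=corr,
                            total_absolute=corrected_total, corrected=True,
                            background_ref=background.medium)
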