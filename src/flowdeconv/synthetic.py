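"""Synthetic cytometry experiments with known ground truth.

The study system is a four-member *Bacteroides* community in which each
species carries a distinct fluorescence signature: B. vulgatus (Bv) expresses
both GFP and mCherry, B. theta (Bt) GFP only, B. fragilis (Bf) mCherry only,
and wild-type B. ovatus (Bo) autofluoresces weakly in both channels. Because
reporter proteins mature incompletely, a monoculture can present several
event clusters (Bv up to four: double-positive, GFP-only, mCherry-only,
dark); the generator reproduces this subcluster structure, plus a debris
component that the nucleic-acid-stain gate is meant to remove, and the full
factorial sampling design (culture type x medium x replicate x timepoint).

Intensities are drawn on the instrument's linear arbitrary-unit scale; no
transform is baked in. All randomness flows from explicit integer seeds, and
per-medium condition shifts (fluorescence intensities drift with growth
condition) are derived deterministically from the medium name so that
monocultures and co-cultures in the same medium drift together.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import CHANNELS, CULTURE_TYPES, SPECIES, TRUE_LABEL_COLUMN, EventTable, SampleMeta

# ---------------------------------------------------------------------------
# Species archetypes
# ---------------------------------------------------------------------------

#: Per-species scatter and stain baselines (a.u.): cell size, granularity and
#: nucleic-acid content differ between species, so forward/side scatter and
#: SYTO intensity carry species signal alongside the reporters.
_SCATTER_BASE = {
    "Bo": (3200.0, 2600.0, 3100.0),
    "Bt": (3000.0, 2700.0, 3050.0),
    "Bf": (2800.0, 2300.0, 2950.0),
    "Bv": (2600.0, 2150.0, 2900.0),
}
_SCATTER_SD = (300.0, 280.0)
_SYTO_SD = 350.0

#: Maximum subcluster counts per species (Bv's dual reporter yields up to 4
#: maturation states; the single-reporter species at most 2).
SUBCLUSTER_CAPS = {"Bo": 2, "Bf": 2, "Bt": 2, "Bv": 4}


@dataclass(frozen=True)
class Subcluster:
    """One maturation state: a 5-D Gaussian with a within-species weight."""

    mean: np.ndarray  # (5,) in canonical channel order
    cov: np.ndarray  # (5, 5)
    weight: float


@dataclass(frozen=True)
class SpeciesArchetype:
    species_id: str
    subclusters: tuple[Subcluster, ...]
    baseline_density: float = 2.5e7  # cells/ml under permissive growth

    def __post_init__(self) -> None:
        if self.species_id not in SPECIES:
            raise ValueError(f"unknown species {self.species_id!r}")
        cap = SUBCLUSTER_CAPS[self.species_id]
        if not 1 <= len(self.subclusters) <= cap:
            raise ValueError(
                f"{self.species_id} allows 1..{cap} subclusters, got {len(self.subclusters)}"
            )
        total = sum(s.weight for s in self.subclusters)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.species_id} maturation weights sum to {total}, not 1")
        if self.baseline_density < 0:
            raise ValueError("baseline density must be >= 0")

    @property
    def main_mean(self) -> np.ndarray:
        return max(self.subclusters, key=lambda s: s.weight).mean


def _sub(species: str, gfp: float, mch: float, weight: float,
         sd_scale: float) -> Subcluster:
    """Build a subcluster at the species' scatter/stain baseline.

    Fluorescence SD follows a constant-CV rule (12% of the mean, floored at
    60 a.u.); the separation-scenario factor scales every channel's SD so
    that "heavy overlap" really blurs all the information channels.
    """
    fsc, ssc, syto = _SCATTER_BASE[species]
    mean = np.array([fsc, ssc, gfp, mch, syto])
    sds = sd_scale * np.array(
        [
            _SCATTER_SD[0],
            _SCATTER_SD[1],
            max(0.12 * gfp, 60.0),
            max(0.12 * mch, 60.0),
            _SYTO_SD,
        ]
    )
    return Subcluster(mean=mean, cov=np.diag(sds**2), weight=weight)


def make_archetypes(sd_scale: float = 1.0,
                    baseline_density: float = 2.5e7) -> dict[str, SpeciesArchetype]:
    """The four-species fluorescence archetypes.

    ``sd_scale`` widens or narrows the clouds in every channel; 1.0 is the
    default, realistically overlapping geometry.
    """
    s = sd_scale
    return {
        "Bo": SpeciesArchetype("Bo", (
            _sub("Bo", 600.0, 500.0, 0.85, s),   # autofluorescent main population
            _sub("Bo", 350.0, 300.0, 0.15, s),   # dimmer physiological state
        ), baseline_density),
        "Bt": SpeciesArchetype("Bt", (
            _sub("Bt", 12000.0, 150.0, 0.85, s),  # GFP-positive
            _sub("Bt", 1500.0, 150.0, 0.15, s),   # immature GFP
        ), baseline_density),
        "Bf": SpeciesArchetype("Bf", (
            _sub("Bf", 180.0, 10000.0, 0.85, s),  # mCherry-positive
            _sub("Bf", 180.0, 1300.0, 0.15, s),   # immature mCherry
        ), baseline_density),
        "Bv": SpeciesArchetype("Bv", (
            _sub("Bv", 5000.0, 4000.0, 0.70, s),  # GFP+ mCherry+
            _sub("Bv", 5000.0, 160.0, 0.10, s),   # GFP only
            _sub("Bv", 180.0, 4000.0, 0.10, s),   # mCherry only
            _sub("Bv", 150.0, 120.0, 0.10, s),    # dark (neither folded)
        ), baseline_density),
    }


#: Debris / background model. Most debris is unstained (SYTO far below the
#: gate) but a minority binds the stain and autofluoresces like B. ovatus —
#: the species-specific background the study subtracts.
_DEBRIS_SUBCLUSTERS = (
    Subcluster(np.array([400.0, 350.0, 250.0, 220.0, 150.0]),
               np.diag(np.array([150.0, 140.0, 120.0, 110.0, 80.0]) ** 2), 0.8),
    Subcluster(np.array([700.0, 600.0, 600.0, 500.0, 1200.0]),
               np.diag(np.array([200.0, 180.0, 90.0, 80.0, 250.0]) ** 2), 0.2),
)


def pairwise_separation(archetypes: dict[str, SpeciesArchetype]) -> float:
    """Minimum inter-species main-centroid distance in pooled-SD units.

    Pooled SD is the across-species mean of sqrt(trace(cov)/5) of the main
    subcluster — a single isotropic yardstick for "how wide are the clouds".
    """
    mains = [max(a.subclusters, key=lambda s: s.weight) for a in archetypes.values()]
    pooled = float(np.mean([np.sqrt(np.trace(sc.cov) / len(CHANNELS)) for sc in mains]))
    dmin = np.inf
    for i in range(len(mains)):
        for j in range(i + 1, len(mains)):
            dmin = min(dmin, float(np.linalg.norm(mains[i].mean - mains[j].mean)))
    return dmin / pooled


def separation_scenarios() -> list[tuple[str, dict[str, SpeciesArchetype]]]:
    """Named archetype sets with decreasing inter-species separation.

    well_separated: clouds ≥5 pooled SD apart; default: the realistic
    geometry with partial overlap; heavy_overlap: clouds within ~1 pooled SD.
    """
    return [
        ("well_separated", make_archetypes(sd_scale=0.5)),
        ("default_overlap", make_archetypes(sd_scale=1.0)),
        ("heavy_overlap", make_archetypes(sd_scale=15.0)),
    ]


# ---------------------------------------------------------------------------
# Factorial design
# ---------------------------------------------------------------------------

SIMPLE_SUBSTRATES = (
    "arabinose", "cellobiose", "fructose", "galactose", "glucose", "lactose",
    "maltose", "mannose", "ribose", "sucrose", "xylose",
)
COMPLEX_SUBSTRATES = (
    "amylopectin", "arabinan", "arabinogalactan", "arabinoxylan",
    "chondroitin sulfate", "dextran", "fructooligosaccharides L90",
    "galactomannan", "glucomannan", "glycogen", "heparin", "inulin (Sigma)",
    "inulin (Alfa Aesar)", "laminarin", "levan", "mucin", "pectin",
    "pullulan", "starch (rice)", "xylan",
)
RICH_CONTROL = "mGAM"
MINIMAL_CONTROL = "Water"
DEFAULT_MEDIA = SIMPLE_SUBSTRATES + COMPLEX_SUBSTRATES + (RICH_CONTROL, MINIMAL_CONTROL)
DEFAULT_TIMEPOINTS = (24.0, 48.0, 72.0, 102.0)


def substrate_class(medium: str) -> str:
    if medium in SIMPLE_SUBSTRATES:
        return "simple"
    if medium in COMPLEX_SUBSTRATES:
        return "complex"
    return "control"


@dataclass(frozen=True)
class DesignGrid:
    """Factorial design: media x culture types x replicates x timepoints."""

    media: tuple[str, ...] = DEFAULT_MEDIA
    culture_types: tuple[str, ...] = ("mono:Bo", "mono:Bf", "mono:Bt", "mono:Bv", "co")
    replicates: int = 2
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if not (self.media and self.culture_types and self.timepoints):
            raise ValueError("design grid has an empty dimension")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        unknown = set(self.culture_types) - set(CULTURE_TYPES)
        if unknown:
            raise ValueError(f"unknown culture types: {sorted(unknown)}")


def enumerate_design(grid: DesignGrid,
                     acquisition_volume_ul: float = 3.0,
                     dilution_factor: float = 5.0) -> list[SampleMeta]:
    """One SampleMeta per factorial cell, in deterministic order."""
    out: list[SampleMeta] = []
    for culture in grid.culture_types:
        for medium in grid.media:
            for rep in range(1, grid.replicates + 1):
                for tp in grid.timepoints:
                    sid = f"{culture}|{medium}|r{rep}|t{tp:g}"
                    out.append(SampleMeta(
                        sample_id=sid, culture_type=culture, medium=medium,
                        substrate_class=substrate_class(medium), replicate=rep,
                        timepoint=tp, acquisition_volume_ul=acquisition_volume_ul,
                        dilution_factor=dilution_factor,
                    ))
    return out


def sterile_design(grid: DesignGrid, replicates: int = 2) -> list[SampleMeta]:
    """Duplicate sterile (uninoculated) controls of every medium, used to
    estimate background events. These sit outside the culture-sample count."""
    sterile_grid = DesignGrid(media=grid.media, culture_types=("sterile",),
                              replicates=replicates, timepoints=(grid.timepoints[0],))
    return enumerate_design(sterile_grid)


# ---------------------------------------------------------------------------
# Ground truth and event simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """What a simulated sample really contains.

    true_total_density counts all gate-visible particles (cells + debris) in
    cells/ml-equivalent units; debris_fraction is the fraction of those that
    are debris. Cell density is therefore (1 - debris_fraction) * total.
    """

    sample_id: str
    true_proportions: tuple[float, float, float, float]  # Bo, Bf, Bt, Bv
    true_total_density: float
    debris_fraction: float = 0.05

    def __post_init__(self) -> None:
        p = np.asarray(self.true_proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")
        if self.true_total_density < 0:
            raise ValueError("density must be >= 0")
        if not 0 <= self.debris_fraction <= 1:
            raise ValueError("debris fraction must be in [0, 1]")

    @property
    def cell_density(self) -> float:
        return self.true_total_density * (1.0 - self.debris_fraction)


def medium_shift(medium: str, sigma: float = 0.15) -> np.ndarray:
    """Per-medium multiplicative drift of the two reporter channels.

    Fluorescence intensities change with growth condition; the shift is a
    log-normal factor (default sigma 0.15) derived deterministically from the
    medium name, so every sample grown in a medium drifts identically.
    """
    if sigma == 0:
        return np.ones(2)
    rng = np.random.default_rng(zlib.crc32(medium.encode()) % (2**31))
    return np.exp(rng.normal(0.0, sigma, size=2))


def _draw(rng: np.random.Generator, sub: Subcluster, n: int,
          fluor_factor: np.ndarray, sample_factor: np.ndarray) -> np.ndarray:
    mean = sub.mean * sample_factor
    mean[2] *= fluor_factor[0]  # GFP-H
    mean[3] *= fluor_factor[1]  # mCherry-H
    return rng.multivariate_normal(mean, sub.cov, size=n)


def simulate_sample(meta: SampleMeta,
                    archetypes: dict[str, SpeciesArchetype],
                    truth: GroundTruth,
                    seed: int,
                    max_events: int = 25000,
                    shift_sigma: float = 0.15,
                    sample_jitter_sigma: float = 0.03) -> EventTable:
    """Draw one sample's events from the species/debris mixture.

    The event count is Poisson with mean true_total_density x acquisition
    volume / dilution factor (capped at ``max_events`` to keep full designs
    tractable). Cell intensities are floored at 1 a.u. (the instrument
    trigger threshold); debris clips at 0, so some debris events carry
    zero-signal channels and are removed by the nonzero gate. A per-sample
    log-normal factor (sigma ``sample_jitter_sigma``) on every channel mean
    emulates instrument/day drift between acquisitions.
    """
    rng = np.random.default_rng(seed)
    vol_ml = meta.acquisition_volume_ul * 1e-3
    n_total = int(rng.poisson(truth.true_total_density * vol_ml / meta.dilution_factor))
    n_total = min(n_total, max_events)

    n_debris = rng.binomial(n_total, truth.debris_fraction) if n_total else 0
    n_cells = n_total - n_debris
    fluor = medium_shift(meta.medium, shift_sigma)
    jitter = np.exp(rng.normal(0.0, sample_jitter_sigma, size=len(CHANNELS))) \
        if sample_jitter_sigma else np.ones(len(CHANNELS))

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    counts = rng.multinomial(n_cells, truth.true_proportions) if n_cells else [0] * 4
    for sp, n_sp in zip(SPECIES, counts):
        if n_sp == 0:
            continue
        arch = archetypes[sp]
        sub_counts = rng.multinomial(n_sp, [s.weight for s in arch.subclusters])
        for sub, n_sub in zip(arch.subclusters, sub_counts):
            if n_sub:
                blocks.append(np.maximum(_draw(rng, sub, n_sub, fluor, jitter), 1.0))
                labels.extend([sp] * n_sub)
    if n_debris:
        d_counts = rng.multinomial(n_debris, [s.weight for s in _DEBRIS_SUBCLUSTERS])
        for sub, n_sub in zip(_DEBRIS_SUBCLUSTERS, d_counts):
            if n_sub:
                blocks.append(np.maximum(_draw(rng, sub, n_sub, np.ones(2), jitter), 0.0))
                labels.extend(["debris"] * n_sub)

    if blocks:
        mat = np.vstack(blocks)
        order = rng.permutation(len(mat))
        mat = mat[order]
        labels = [labels[i] for i in order]
    else:
        mat = np.empty((0, len(CHANNELS)))

    df = pd.DataFrame(mat, columns=list(CHANNELS))
    df[TRUE_LABEL_COLUMN] = labels
    return EventTable(df, sample_id=meta.sample_id)


def sample_seed(root_seed: int, sample_id: str) -> int:
    """Stable per-sample seed below 2**31, derived from a root seed."""
    return (zlib.crc32(f"{root_seed}:{sample_id}".encode()) ^ root_seed) % (2**31)


# ---------------------------------------------------------------------------
# Study-level ground truth (growth model for the demo experiment)
# ---------------------------------------------------------------------------

#: Fraction of the medium-specific carrying capacity reached at each sampled
#: timepoint (batch growth, 48 h passage, partial regrowth).
_GROWTH_CURVE = {24.0: 0.6, 48.0: 1.0, 72.0: 0.9, 102.0: 0.8}

#: Relative yield by substrate class for monocultures: species convert simple
#: sugars to biomass more efficiently than complex sugars in short batch
#: culture; water supports almost no growth.
_MONO_YIELD = {"simple": 1.2, "complex": 0.8}

#: Co-culture totals relative to the best monoculture: competition depresses
#: yields on simple sugars (~30% down); complex sugars are near-neutral.
_CO_FACTOR = {"simple": 0.70, "complex": 1.0}

#: Sterile-media background particle density as a fraction of the mean
#: permissive-growth cell density (~2e6/ml against 2.5e7/ml cultures).
STERILE_BACKGROUND_FRACTION = 0.08


def make_ground_truth(meta: SampleMeta, archetypes: dict[str, SpeciesArchetype],
                      seed: int, debris_fraction: float = 0.05,
                      noise_sd: float = 0.05) -> GroundTruth:
    """Plausible ground truth for one design cell.

    Encodes the study's qualitative ecology: monocultures yield more on
    simple than complex sugars, co-culture totals are depressed ~30% on
    simple sugars (competition) and unchanged on complex sugars, co-cultures
    tend to be Bv-dominated, and sterile samples contain only background.
    """
    rng = np.random.default_rng(sample_seed(seed, "truth:" + meta.sample_id))
    base = float(np.mean([a.baseline_density for a in archetypes.values()]))
    if meta.culture_type == "sterile":
        return GroundTruth(meta.sample_id, (0.25, 0.25, 0.25, 0.25),
                           base * STERILE_BACKGROUND_FRACTION, debris_fraction=1.0)
    if meta.medium == RICH_CONTROL:
        yield_factor = 1.5
    elif meta.medium == MINIMAL_CONTROL:
        yield_factor = 0.04
    else:
        yield_factor = _MONO_YIELD[meta.substrate_class]
    growth = _GROWTH_CURVE.get(meta.timepoint, 1.0)
    noise = float(np.exp(rng.normal(0.0, noise_sd)))

    if meta.culture_type == "co":
        co = _CO_FACTOR.get(meta.substrate_class, 1.0)
        density = base * yield_factor * growth * co * noise
        # Composition is stable within a medium across reps/timepoints and
        # encodes the study's working model of the diversity-productivity
        # trade-off: the more productive a condition, the more Bv dominates
        # it (Bv drove both competition and cross-feeding gains), so less
        # productive communities stay more even.
        density_factor = yield_factor * co
        bv_share = 0.28 + 0.55 * min(density_factor / 1.5, 1.0)
        prng = np.random.default_rng(sample_seed(seed, "props:" + meta.medium))
        rest = prng.dirichlet((8.0, 8.0, 8.0)) * (1.0 - bv_share)
        props = np.array([rest[0], rest[1], rest[2], bv_share])
        proportions = tuple(props / props.sum())
    else:
        sp = meta.species
        density = archetypes[sp].baseline_density * yield_factor * growth * noise
        proportions = tuple(1.0 if s == sp else 0.0 for s in SPECIES)

    cell_density = max(density, 0.0)
    total = cell_density / (1.0 - debris_fraction)
    return GroundTruth(meta.sample_id, proportions, total, debris_fraction)


def majority_labels(responsibilities: np.ndarray, labels) -> list[str]:
    """Per-cluster majority ground-truth label.

    ``responsibilities``: (n_events, k) posterior matrix; events vote for
    their argmax component with their true generating label.
    """
    labels = np.asarray(labels)
    assign = np.argmax(responsibilities, axis=1)
    out = []
    for j in range(responsibilities.shape[1]):
        members = labels[assign == j]
        if members.size == 0:
            out.append("empty")
        else:
            vals, counts = np.unique(members, return_counts=True)
            out.append(str(vals[np.argmax(counts)]))
    return out
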