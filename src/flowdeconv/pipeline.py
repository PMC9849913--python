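"""End-to-end orchestration: generate -> gate -> cluster -> train ->
classify -> quantify -> ecology -> stats.

Every stage is callable on its own; :func:`run_pipeline` chains them with a
single root seed from which all per-sample seeds derive, so identical
configurations reproduce byte-identical outputs. A manifest records event
conservation (input = retained + removed per sample), every clamped
abundance, and every below-detection control.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import classifier as cl
from . import ecology as eco
from . import stats as st
from .clustering import ClusterConfig, ClusterSet, DEFAULT_CAPS, cluster_sample
from .events import SPECIES, EventTable, SampleMeta
from .gating import GateConfig, gate_events
from .io import write_csv, write_fcs
from .synthetic import (
    DesignGrid, GroundTruth, MINIMAL_CONTROL, enumerate_design, make_archetypes,
    make_ground_truth, sample_seed, simulate_sample, sterile_design,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Knobs for a full synthetic-study run.

    Defaults mirror the study conditions: SYTO gate at 450 a.u., 10,000-event
    clustering subsample with an 80:20 split, cluster caps 2/2/2/4/10/1,
    1,000-tree forest, 3 µl acquisition volume with 5-fold dilution, 2x
    growth threshold, ±20% interaction margin.
    """

    grid: DesignGrid = field(default_factory=DesignGrid)
    seed: int = 0
    gate: GateConfig = field(default_factory=GateConfig)
    caps: dict = field(default_factory=lambda: dict(DEFAULT_CAPS))
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    n_trees: int = 1000
    separation_scale: float = 1.0
    baseline_density: float = 2.5e7  # cells/ml at permissive growth
    max_events: int = 25000
    shift_sigma: float = 0.15
    debris_fraction: float = 0.05
    growth_factor: float = eco.GROWTH_FACTOR
    interaction_margin: float = eco.INTERACTION_MARGIN

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"]["media"] = list(self.grid.media)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        grid = DesignGrid(media=tuple(d["grid"]["media"]),
                          culture_types=tuple(d["grid"]["culture_types"]),
                          replicates=int(d["grid"]["replicates"]),
                          timepoints=tuple(float(t) for t in d["grid"]["timepoints"]))
        gate = GateConfig(**d["gate"])
        cluster = ClusterConfig(**d["cluster"])
        keys = ("seed", "n_trees", "separation_scale", "baseline_density",
                "max_events", "shift_sigma", "debris_fraction",
                "growth_factor", "interaction_margin")
        return RunConfig(grid=grid, gate=gate, cluster=cluster,
                         caps={k: int(v) for k, v in d["caps"].items()},
                         **{k: d[k] for k in keys if k in d})


# ---------------------------------------------------------------------------
# Synthetic study generation
# ---------------------------------------------------------------------------

def generate_study(config: RunConfig) -> list[tuple[SampleMeta, GroundTruth, EventTable]]:
    """Simulate every sample of the design (cultures + sterile controls)."""
    archetypes = make_archetypes(config.separation_scale,
                                 baseline_density=config.baseline_density)
    metas = enumerate_design(config.grid) + sterile_design(config.grid)
    out = []
    for meta in metas:
        truth = make_ground_truth(meta, archetypes, config.seed,
                                  debris_fraction=config.debris_fraction)
        table = simulate_sample(meta, archetypes, truth,
                                seed=sample_seed(config.seed, meta.sample_id),
                                max_events=config.max_events,
                                shift_sigma=config.shift_sigma)
        out.append((meta, truth, table))
    return out


def make_demo_experiment(seed: int, outdir, grid: DesignGrid | None = None,
                         max_events: int = 2000, fmt: str = "csv") -> pd.DataFrame:
    """Write a miniature synthetic study to disk with its ground truth.

    Emits one event file per sample (CSV by default, FCS optional),
    samples.csv with metadata, ground_truth.csv, and config.yaml recording
    the seed. Returns the metadata frame.
    """
    outdir = Path(outdir)
    (outdir / "events").mkdir(parents=True, exist_ok=True)
    config = RunConfig(grid=grid or DesignGrid(), seed=seed, max_events=max_events)
    study = generate_study(config)

    meta_rows, truth_rows = [], []
    for meta, truth, table in study:
        fname = f"{_safe_name(meta.sample_id)}.{fmt}"
        path = outdir / "events" / fname
        if fmt == "csv":
            write_csv(table, path)
        elif fmt == "fcs":
            write_fcs(table, path)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        meta_rows.append({**dataclasses.asdict(meta), "events_file": f"events/{fname}"})
        truth_rows.append({
            "sample_id": truth.sample_id,
            **{f"p_{sp}": p for sp, p in zip(SPECIES, truth.true_proportions)},
            "true_total_density": truth.true_total_density,
            "debris_fraction": truth.debris_fraction,
        })
    meta_df = pd.DataFrame(meta_rows)
    meta_df.to_csv(outdir / "samples.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return meta_df


def _safe_name(sample_id: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in sample_id)


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _cluster_all(gated, config: RunConfig) -> dict[str, ClusterSet]:
    out = {}
    for meta, table, _ in gated:
        out[meta.sample_id] = cluster_sample(
            table, meta, caps=config.caps, cfg=config.cluster,
            seed=sample_seed(config.seed, "cluster:" + meta.sample_id))
    return out


def train_from_monocultures(metas, clustersets, n_trees: int, seed: int,
                            replicate: int | None = None) -> cl.ClusterClassifier:
    """Train on monoculture clusters (optionally a single replicate)."""
    labeled = []
    for meta in metas:
        if not meta.culture_type.startswith("mono:"):
            continue
        if replicate is not None and meta.replicate != replicate:
            continue
        cs = clustersets[meta.sample_id]
        if cs.clusters:
            labeled.append((cs, meta.species))
    return cl.train(labeled, n_trees=n_trees, seed=seed)


@dataclass
class RunResult:
    manifest: dict
    abundance: pd.DataFrame  # tidy per-sample per-species table
    ecology: pd.DataFrame
    evenness: pd.DataFrame
    stats: dict
    classifier: cl.ClusterClassifier
    evaluation: cl.EvaluationReport | None


def run_pipeline(config: RunConfig, outdir=None) -> RunResult:
    """Execute the full pipeline on a synthetic study; optionally write CSVs."""
    study = generate_study(config)
    metas = [m for m, _, _ in study]

    # gate
    gated = []
    conservation = []
    for meta, truth, table in study:
        gtable, retained = gate_events(table, config.gate)
        gated.append((meta, gtable, retained))
        conservation.append({"sample_id": meta.sample_id,
                             "input": table.n_events,
                             "retained": retained,
                             "removed": table.n_events - retained})

    # cluster
    clustersets = _cluster_all(gated, config)

    # train (final model on ALL monoculture clusters; evaluation via the
    # replicate split when both replicates exist)
    train_seed = sample_seed(config.seed, "train")
    clf = train_from_monocultures(metas, clustersets, config.n_trees, train_seed)
    evaluation = None
    if config.grid.replicates >= 2:
        clf_r1 = train_from_monocultures(metas, clustersets, config.n_trees,
                                         train_seed, replicate=1)
        heldout = [(clustersets[m.sample_id], m.species) for m in metas
                   if m.culture_type.startswith("mono:") and m.replicate == 2
                   and clustersets[m.sample_id].clusters]
        if heldout:
            evaluation = cl.evaluate(clf_r1, heldout)

    # backgrounds per medium from sterile controls
    backgrounds = {}
    for medium in config.grid.media:
        steriles = [(m, clustersets[m.sample_id], retained)
                    for m, _, retained in gated
                    if m.culture_type == "sterile" and m.medium == medium]
        backgrounds[medium] = ab.build_background(medium, steriles, clf)

    # quantify
    rows = []
    for meta, gtable, retained in gated:
        if meta.culture_type == "sterile":
            continue
        profile = ab.profile_sample(meta, clustersets[meta.sample_id], retained,
                                    clf, background=backgrounds.get(meta.medium))
        for sp in SPECIES:
            rows.append({
                "sample_id": meta.sample_id, "culture_type": meta.culture_type,
                "medium": meta.medium, "substrate_class": meta.substrate_class,
                "replicate": meta.replicate, "timepoint": meta.timepoint,
                "species": sp, "relative": profile.relative.get(sp, 0.0),
                "absolute_cells_per_ml": profile.absolute.get(sp, 0.0),
                "corrected": profile.corrected,
            })
    abundance_df = pd.DataFrame(rows)

    # ecology per substrate medium
    eco_rows, even_rows = [], []
    water_mono = _mono_series(abundance_df, MINIMAL_CONTROL)
    for medium in config.grid.media:
        sub_class = next(m.substrate_class for m in metas if m.medium == medium)
        mono = _mono_series(abundance_df, medium)
        co = _co_series(abundance_df, medium)
        if mono.empty or co.empty:
            continue
        summary = eco.summarize_medium(
            medium, sub_class, mono, co,
            water_mono_series=None if medium == MINIMAL_CONTROL or water_mono.empty else water_mono,
            margin=config.interaction_margin, growth_factor=config.growth_factor)
        eco_rows.append({
            "medium": medium, "substrate_class": sub_class,
            "max_mono_productivity": summary.max_mono_productivity,
            "max_co_productivity": summary.max_co_productivity,
            "interaction_call": summary.interaction_call,
            **{f"growth_{sp}": summary.growth_calls.get(sp) for sp in SPECIES},
            **{f"benefit_{sp}": summary.species_benefit.get(sp) for sp in SPECIES},
        })
    ecology_df = pd.DataFrame(eco_rows)

    # evenness per co-culture sample
    co_ab = abundance_df[abundance_df["culture_type"] == "co"]
    for sid, grp in co_ab.groupby("sample_id"):
        rel = dict(zip(grp["species"], grp["relative"]))
        total = float(grp["absolute_cells_per_ml"].sum())
        if sum(rel.values()) > 0:
            even_rows.append({
                "sample_id": sid, "medium": grp["medium"].iloc[0],
                "substrate_class": grp["substrate_class"].iloc[0],
                "evenness": eco.simpson_evenness(rel),
                "total_cells_per_ml": total,
            })
    evenness_df = pd.DataFrame(even_rows)

    stats_out = _run_stats(ecology_df, evenness_df)

    manifest = {
        "config_digest": config.digest(),
        "software_version": __version__,
        "seed": config.seed,
        "n_samples": len(study),
        "n_culture_samples": sum(1 for m in metas if m.culture_type != "sterile"),
        "n_sterile_samples": sum(1 for m in metas if m.culture_type == "sterile"),
        "event_conservation": conservation,
        "n_below_detection": sum(cs.below_detection for cs in clustersets.values()),
        "classifier_report": clf.training_report,
        "evaluation_error": None if evaluation is None else evaluation.overall_error,
    }

    result = RunResult(manifest=manifest, abundance=abundance_df,
                       ecology=ecology_df, evenness=evenness_df,
                       stats=stats_out, classifier=clf, evaluation=evaluation)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _mono_series(abundance_df: pd.DataFrame, medium: str) -> pd.DataFrame:
    """Per-species monoculture growth series: each species' corrected total
    in its own monoculture on the medium."""
    rows = []
    df = abundance_df[(abundance_df["medium"] == medium)
                      & abundance_df["culture_type"].str.startswith("mono:")]
    for _, r in df.iterrows():
        if r["culture_type"] == f"mono:{r['species']}":
            rows.append({"species": r["species"], "timepoint": r["timepoint"],
                         "replicate": r["replicate"],
                         "abundance": r["absolute_cells_per_ml"]})
    return pd.DataFrame(rows, columns=list(eco.SERIES_COLUMNS))


def _co_series(abundance_df: pd.DataFrame, medium: str) -> pd.DataFrame:
    df = abundance_df[(abundance_df["medium"] == medium)
                      & (abundance_df["culture_type"] == "co")]
    return df.rename(columns={"absolute_cells_per_ml": "abundance"})[
        list(eco.SERIES_COLUMNS)]


def _run_stats(ecology_df: pd.DataFrame, evenness_df: pd.DataFrame) -> dict:
    out: dict = {}
    simple = ecology_df.loc[ecology_df["substrate_class"] == "simple",
                            "max_mono_productivity"]
    complex_ = ecology_df.loc[ecology_df["substrate_class"] == "complex",
                              "max_mono_productivity"]
    if len(simple) >= 3 and len(complex_) >= 3:
        res = st.mann_whitney(simple, complex_, n_comparisons=2)
        out["mono_simple_vs_complex"] = dataclasses.asdict(res)
    if len(evenness_df) >= 10:
        e = evenness_df["evenness"].clip(1e-6, 1 - 1e-6)
        prod = evenness_df["total_cells_per_ml"]
        keep = prod > 0
        if keep.sum() >= 10 and np.ptp(np.log10(prod[keep])) > 0:
            fit = st.evenness_glm(e[keep], prod[keep])
            out["evenness_vs_productivity"] = dataclasses.asdict(fit)
    return out


def _write_outputs(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.abundance.to_csv(outdir / "abundance.csv", index=False)
    result.ecology.to_csv(outdir / "ecology.csv", index=False)
    result.evenness.to_csv(outdir / "evenness.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, default=str)
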