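"""Relative/absolute abundance accounting and background correction."""

import numpy as np
import pytest

from flowdeconv import abundance as ab
from flowdeconv import classifier as cl
from flowdeconv.clustering import Cluster, ClusterSet, cluster_sample
from flowdeconv.events import CHANNELS, SPECIES, SampleMeta
from flowdeconv.gating import gate_events
from flowdeconv.synthetic import (
    GroundTruth, make_archetypes, simulate_sample,
)


def _pred(species, weight, i=0, sid="s"):
    return cl.ClusterPrediction(sample_id=sid, cluster_index=i,
                                species=species, probability=0.9, weight=weight)


def _cs(weights, sid="s"):
    clusters = [Cluster(mean=np.full(5, 100.0), cov=np.eye(5), weight=w,
                        sample_id=sid) for w in weights]
    return ClusterSet(clusters=clusters, sample_id=sid, n_events_used=1000)


class TestRelative:
    def test_direct_weight_sum(self):
        cs = _cs([0.6, 0.4])
        rel = ab.relative_abundance([_pred("Bv", 0.6, 0), _pred("Bt", 0.4, 1)], cs)
        assert rel == {"Bo": 0.0, "Bf": 0.0, "Bt": 0.4, "Bv": 0.6}

    def test_same_species_aggregates(self):
        cs = _cs([0.5, 0.5])
        rel = ab.relative_abundance([_pred("Bf", 0.5, 0), _pred("Bf", 0.5, 1)], cs)
        assert rel["Bf"] == pytest.approx(1.0)

    def test_missing_prediction_rejected(self):
        with pytest.raises(ValueError):
            ab.relative_abundance([_pred("Bf", 0.5, 0)], _cs([0.5, 0.5]))


class TestAbsolute:
    def test_volumetric_arithmetic(self):
        """6,000 retained events in 3 µl at 5x dilution -> 1.0e7 cells/ml."""
        meta = SampleMeta("s", "co", "glucose", "simple")
        assert ab.absolute_total(6000, meta) == pytest.approx(1.0e7)

    def test_zero_events(self):
        meta = SampleMeta("s", "co", "glucose", "simple")
        assert ab.absolute_total(0, meta) == 0.0

    def test_linearity_in_dilution(self):
        m1 = SampleMeta("s", "co", "glucose", "simple", dilution_factor=5)
        m2 = SampleMeta("s", "co", "glucose", "simple", dilution_factor=10)
        assert ab.absolute_total(100, m2) == pytest.approx(2 * ab.absolute_total(100, m1))

    def test_negative_count_rejected(self):
        meta = SampleMeta("s", "co", "glucose", "simple")
        with pytest.raises(ValueError):
            ab.absolute_total(-1, meta)


class TestCorrections:
    def test_monoculture_subtraction(self):
        assert ab.correct_monoculture(1.0e6, 0.1e6) == pytest.approx(0.9e6)

    def test_monoculture_clamp(self):
        assert ab.correct_monoculture(0.05e6, 0.1e6) == 0.0

    def test_coculture_species_specific(self):
        bg = ab.BackgroundModel("glucose", {"Bv": 0.1e6, "Bo": 0.2e6}, 0.3e6)
        out = ab.correct_coculture({"Bv": 2.0e6, "Bo": 0.05e6, "Bt": 1.0e6, "Bf": 0.0},
                                   bg)
        assert out["Bv"] == pytest.approx(1.9e6)
        assert out["Bo"] == 0.0  # clamped
        assert out["Bt"] == pytest.approx(1.0e6)

    def test_missing_background_warns_and_passes_through(self, caplog):
        out = ab.correct_coculture({"Bv": 1.0e6}, None)
        assert out["Bv"] == pytest.approx(1.0e6)


class TestProfiles:
    def test_conservation_precorrection(self, trained_benchmark):
        """Sum of per-species absolute abundances equals the volumetric total."""
        tb = trained_benchmark
        meta = next(m for m in tb.metas if tb.clustersets[m.sample_id].clusters)
        profile = ab.profile_sample(meta, tb.clustersets[meta.sample_id], 6000,
                                    tb.classifier, background=None)
        assert sum(profile.absolute.values()) == pytest.approx(profile.total_absolute)
        assert sum(profile.relative.values()) == pytest.approx(1.0, abs=1e-9)

    def test_sterile_self_subtraction(self, trained_benchmark, archetypes):
        """A sterile fixture profiled against its own medium's background
        nets out to ~0 (<= 5% of a growth-positive sample)."""
        tb = trained_benchmark
        growth_total = 1.0e7

        def sterile(rep_seed, sid):
            meta = SampleMeta(sid, "sterile", "glucose", "simple")
            truth = GroundTruth(sid, (0.25,) * 4, 2.0e6, debris_fraction=1.0)
            table = simulate_sample(meta, archetypes, truth, seed=rep_seed)
            gated, retained = gate_events(table)
            cs = cluster_sample(gated, meta, seed=rep_seed)
            return meta, cs, retained

        m1, cs1, r1 = sterile(100, "st1")
        m2, cs2, r2 = sterile(101, "st2")
        bg = ab.build_background("glucose", [(m1, cs1, r1), (m2, cs2, r2)],
                                 tb.classifier)
        assert bg.total_background > 0
        # re-profile one replicate as if it were a culture sample
        m_as_mono = m1.with_(culture_type="mono:Bo")
        profile = ab.profile_sample(m_as_mono, cs1, r1, tb.classifier, background=bg)
        assert profile.total_absolute <= 0.05 * growth_total

    def test_below_detection_profile_is_zero(self, trained_benchmark):
        meta = SampleMeta("bd", "sterile", "glucose", "simple")
        empty = ClusterSet(clusters=[], sample_id="bd", below_detection=True)
        profile = ab.profile_sample(meta, empty, 10, trained_benchmark.classifier)
        assert profile.total_absolute == 0.0
        assert all(v == 0.0 for v in profile.absolute.values())

    def test_absolute_uses_full_gated_count_not_subsample(self, trained_benchmark):
        """Counts come from all gated events even when clustering subsampled."""
        tb = trained_benchmark
        meta = next(m for m in tb.metas if tb.clustersets[m.sample_id].clusters)
        cs = tb.clustersets[meta.sample_id]
        p1 = ab.profile_sample(meta, cs, 12000, tb.classifier)
        p2 = ab.profile_sample(meta, cs, 6000, tb.classifier)
        assert p1.total_absolute == pytest.approx(2 * p2.total_absolute)

    def test_background_recovery_removes_autofluorescent_bias(
            self, trained_benchmark, archetypes):
        """Injected gate-passing background biases one species; subtracting
        the classified sterile background removes most of the bias."""
        tb = trained_benchmark
        medium = "glucose"
        debris_density = 6.0e6  # heavy particulate load
        cell_density = 1.5e7
        total = cell_density + debris_density
        truth = GroundTruth("bgco", (0.25,) * 4, total,
                            debris_fraction=debris_density / total)
        meta = SampleMeta("bgco", "co", medium, "simple")
        table = simulate_sample(meta, archetypes, truth, seed=7, max_events=20000)
        gated, retained = gate_events(table)
        cs = cluster_sample(gated, meta, seed=7)

        sterile_meta = SampleMeta("bgst", "sterile", medium, "simple")
        sterile_truth = GroundTruth("bgst", (0.25,) * 4, debris_density,
                                    debris_fraction=1.0)
        st_table = simulate_sample(sterile_meta, archetypes, sterile_truth, seed=8)
        st_gated, st_retained = gate_events(st_table)
        st_cs = cluster_sample(st_gated, sterile_meta, seed=8)
        bg = ab.build_background(medium, [(sterile_meta, st_cs, st_retained)],
                                 tb.classifier)
        assert bg.total_background > 0

        raw = ab.profile_sample(meta, cs, retained, tb.classifier, background=None)
        corr = ab.profile_sample(meta, cs, retained, tb.classifier, background=bg)
        true_per_species = cell_density / 4
        raw_bias = sum(abs(raw.absolute[sp] - true_per_species) for sp in SPECIES)
        corr_bias = sum(abs(corr.absolute[sp] - true_per_species) for sp in SPECIES)
        assert corr_bias <= raw_bias
        # the amount subtracted matches the injected gate-passing background
        # (20% of the debris load) to within 10%
        injected = 0.2 * debris_density
        removed = sum(raw.absolute[sp] - corr.absolute[sp] for sp in SPECIES)
        assert removed == pytest.approx(injected, rel=0.10)
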