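"""Stages 2-3: cluster featurization, forest training, prediction, evaluation."""

import numpy as np
import pytest

from flowdeconv import benchmark as bm
from flowdeconv import classifier as cl
from flowdeconv.clustering import Cluster, ClusterSet
from flowdeconv.events import CHANNELS


def _cluster(mean, weight=0.5, sample_id="x", sd=50.0):
    return Cluster(mean=np.asarray(mean, dtype=float),
                   cov=np.eye(len(CHANNELS)) * sd**2,
                   weight=weight, sample_id=sample_id)


def _clusterset(means_weights, sample_id="x", n_events=1000):
    clusters = [_cluster(m, w, sample_id) for m, w in means_weights]
    return ClusterSet(clusters=clusters, sample_id=sample_id,
                      n_events_used=n_events)


def balanced_subset(tb, per_species=5):
    """A small class-balanced labeled subset of the benchmark clustersets."""
    by_species = {}
    for m in tb.metas:
        cs = tb.clustersets[m.sample_id]
        if cs.clusters:
            by_species.setdefault(m.species, []).append((cs, m.species))
    out = []
    for sp in sorted(by_species):
        out.extend(by_species[sp][:per_species])
    return out


class TestFeaturize:
    def test_channel_means_at_schema_positions(self):
        c = _cluster([3000, 2500, 10000, 50, 2900])
        feats = cl.featurize(c)
        names = cl.feature_names()
        assert feats[names.index("GFP-H mean")] == 10000
        assert feats[names.index("mCherry-H mean")] == 50

    def test_deterministic(self):
        a = _cluster([1, 2, 3, 4, 5])
        b = _cluster([1, 2, 3, 4, 5])
        np.testing.assert_array_equal(cl.featurize(a), cl.featurize(b))

    def test_optional_weight_and_sd_features(self):
        c = _cluster([1, 2, 3, 4, 5], weight=0.25, sd=60.0)
        feats = cl.featurize(c, include_weight=True, include_sd=True)
        assert len(feats) == 11
        assert feats[5] == 0.25
        np.testing.assert_allclose(feats[6:], 60.0)

    def test_bv_brighter_than_bo(self, archetypes):
        """Fixture Bv main cluster exceeds Bo in both reporter channels."""
        bv = _cluster(archetypes["Bv"].main_mean)
        bo = _cluster(archetypes["Bo"].main_mean)
        names = cl.feature_names()
        for ch in ("GFP-H mean", "mCherry-H mean"):
            i = names.index(ch)
            assert cl.featurize(bv)[i] > cl.featurize(bo)[i]


class TestTrainPredict:
    def test_single_class_rejected(self):
        labeled = [(_clusterset([([1, 1, 1, 1, 1], 1.0)]), "Bo")]
        with pytest.raises(ValueError, match="2 species"):
            cl.train(labeled, n_trees=10, seed=0)

    def test_training_determinism(self, trained_benchmark):
        """Same seed + data -> identical predictions on a probe set."""
        tb = trained_benchmark
        labeled = balanced_subset(tb)
        clf1 = cl.train(labeled, n_trees=50, seed=3)
        clf2 = cl.train(labeled, n_trees=50, seed=3)
        probe = labeled[0][0]
        p1 = [p.species for p in cl.predict(clf1, probe)]
        p2 = [p.species for p in cl.predict(clf2, probe)]
        assert p1 == p2

    def test_fluorescence_features_dominate(self, trained_benchmark):
        """Reporter-channel importances exceed the SYTO stain's."""
        imp = trained_benchmark.classifier.training_report["feature_importances"]
        assert imp["GFP-H mean"] + imp["mCherry-H mean"] > imp["SYTO-H mean"]

    def test_every_cluster_assigned_with_valid_probability(self, trained_benchmark):
        tb = trained_benchmark
        cs = next(tb.clustersets[m.sample_id] for m in tb.metas
                  if tb.clustersets[m.sample_id].clusters)
        preds = cl.predict(tb.classifier, cs)
        assert len(preds) == cs.k
        assert all(0.0 <= p.probability <= 1.0 for p in preds)

    def test_class_probabilities_sum_to_one(self, trained_benchmark):
        tb = trained_benchmark
        cs = next(tb.clustersets[m.sample_id] for m in tb.metas
                  if tb.clustersets[m.sample_id].clusters)
        proba = cl.class_probabilities(tb.classifier, cs)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_clusterset_empty_predictions(self, trained_benchmark):
        empty = ClusterSet(clusters=[], sample_id="empty")
        assert cl.predict(trained_benchmark.classifier, empty) == []

    def test_schema_mismatch_rejected(self, trained_benchmark):
        tb = trained_benchmark
        labeled = balanced_subset(tb)
        clf_sd = cl.train(labeled, n_trees=10, seed=0, include_sd=True)
        # model trained with SD features refuses means-only prediction path
        clf_sd2 = cl.ClusterClassifier(model=clf_sd.model,
                                       class_labels=clf_sd.class_labels,
                                       feature_names=clf_sd.feature_names,
                                       include_weight=False, include_sd=False)
        with pytest.raises(ValueError, match="schema"):
            cl.predict(clf_sd2, labeled[0][0])

    def test_ambiguous_midpoint_probe_has_split_vote(self, trained_benchmark):
        """A cluster halfway between two species' archetype clusters cannot
        be called with near-certainty."""
        tb = trained_benchmark
        bt_like, bv_like = None, None
        for m in tb.metas:
            cs = tb.clustersets[m.sample_id]
            if not cs.clusters:
                continue
            if m.species == "Bt" and bt_like is None:
                bt_like = cs.clusters[0].mean
            if m.species == "Bv" and bv_like is None:
                bv_like = cs.clusters[0].mean
        probe = _clusterset([((bt_like + bv_like) / 2.0, 1.0)])
        pred = cl.predict(tb.classifier, probe)[0]
        assert pred.probability <= 0.75


class TestEvaluate:
    def test_all_correct_zero_error(self, trained_benchmark):
        tb = trained_benchmark
        labeled = balanced_subset(tb, per_species=2)
        # score the final model on its own training clusters: error ~ 0
        report = cl.evaluate(tb.classifier, labeled)
        assert report.overall_error == pytest.approx(0.0, abs=0.05)

    def test_error_arithmetic_one_wrong_in_twenty(self, trained_benchmark):
        """Mislabeling exactly one of 20 clusters gives 5% unweighted error."""
        tb = trained_benchmark
        singles = []
        for m in tb.metas:
            cs = tb.clustersets[m.sample_id]
            for c in cs.clusters:
                singles.append((ClusterSet(clusters=[Cluster(c.mean, c.cov, 1.0, "s")],
                                           sample_id=m.sample_id, n_events_used=100),
                                m.species))
            if len(singles) >= 20:
                break
        singles = singles[:20]
        report = cl.evaluate(tb.classifier, singles)
        base_wrong = round(report.overall_error * 20)
        flipped = list(singles)
        cs0, true0 = flipped[0]
        wrong_label = "Bo" if true0 != "Bo" else "Bf"
        flipped[0] = (cs0, wrong_label)
        report2 = cl.evaluate(tb.classifier, flipped)
        assert round(report2.overall_error * 20) == base_wrong + 1

    def test_empty_heldout_rejected(self, trained_benchmark):
        with pytest.raises(ValueError):
            cl.evaluate(trained_benchmark.classifier, [])

    def test_replicate_split_error_small(self, trained_benchmark):
        """Train on replicate 1, test on replicate 2: error stays in the
        few-percent range seen for this kind of system."""
        assert trained_benchmark.evaluation.overall_error <= 0.10

    def test_weight_filter_does_not_hurt(self, trained_benchmark):
        """Dropping low-weight clusters preserves or improves accuracy."""
        tb = trained_benchmark
        table = tb.evaluation.table
        full_acc = table["correct"].mean()
        heavy = table[table["weight"] >= 0.2]
        assert heavy["correct"].mean() >= full_acc - 1e-12


class TestSeparationMonotonicity:
    def test_deconvolution_error_antitone_in_separation(self):
        """Median co-culture abundance-recovery error grows as archetype
        separation shrinks: well-separated <= default <= heavy overlap
        (5 seeds per scenario, reduced sizes).

        The deployment task is what overlap degrades: monoculture cluster
        *means* stay species-separated even when event clouds blur, but
        co-culture mixtures can no longer be resolved into per-species
        components.
        """
        import flowdeconv.pipeline as pl
        from flowdeconv.abundance import relative_abundance
        from flowdeconv.clustering import ClusterConfig, cluster_sample
        from flowdeconv.events import SPECIES, TRUE_LABEL_COLUMN, SampleMeta
        from flowdeconv.gating import gate_events
        from flowdeconv.pipeline import RunConfig
        from flowdeconv.synthetic import (
            DesignGrid, GroundTruth, make_archetypes, sample_seed,
            simulate_sample,
        )

        def median_mae(scale):
            maes = []
            for seed in range(5):
                grid = DesignGrid(media=("glucose", "xylan"), timepoints=(24.0,),
                                  culture_types=("mono:Bo", "mono:Bf",
                                                 "mono:Bt", "mono:Bv"))
                ccfg = ClusterConfig(subsample_n=3000, n_restarts=2)
                cfg = RunConfig(grid=grid, seed=seed, n_trees=200,
                                separation_scale=scale, max_events=5000,
                                cluster=ccfg)
                study = pl.generate_study(cfg)
                metas, csets = [], {}
                for meta, _, table in study:
                    if meta.culture_type == "sterile":
                        continue
                    gated, _ = gate_events(table)
                    csets[meta.sample_id] = cluster_sample(
                        gated, meta, cfg=ccfg,
                        seed=sample_seed(seed, meta.sample_id))
                    metas.append(meta)
                clf = pl.train_from_monocultures(metas, csets, 200,
                                                 sample_seed(seed, "t"))
                arch = make_archetypes(scale)
                for j in range(3):
                    medium = ("glucose", "xylan")[j % 2]
                    rng = np.random.default_rng(1000 * seed + j)
                    props = tuple(rng.dirichlet((2.0,) * 4))
                    meta = SampleMeta(f"co{j}", "co", medium, "simple")
                    truth = GroundTruth(meta.sample_id, props, 2.5e7, 0.05)
                    table = simulate_sample(meta, arch, truth,
                                            seed=sample_seed(seed, f"co{j}"),
                                            max_events=5000)
                    gated, _ = gate_events(table)
                    cs = cluster_sample(gated, meta, cfg=ccfg,
                                        seed=sample_seed(seed, f"cl{j}"))
                    rel = relative_abundance(cl.predict(clf, cs), cs)
                    labels = gated.data[TRUE_LABEL_COLUMN]
                    cells = (labels != "debris").mean()
                    maes.append(float(np.mean(
                        [abs(rel[sp] - (labels == sp).mean() / cells)
                         for sp in SPECIES])))
            return float(np.median(maes))

        mae_well = median_mae(0.5)
        mae_default = median_mae(1.0)
        mae_heavy = median_mae(15.0)
        assert mae_well <= mae_default + 1e-9
        assert mae_default <= mae_heavy + 1e-9
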