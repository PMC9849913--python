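# Methods

## The measurement problem

Four *Bacteroides* species carrying chromosomally integrated fluorescence
reporters are grown alone and together on single carbon substrates, and
their absolute abundances are read out by multicolor flow cytometry:
*B. vulgatus* (Bv) expresses GFP and mCherry, *B. thetaiotaomicron* (Bt)
GFP only, *B. fragilis* (Bf) mCherry only, and wild-type *B. ovatus* (Bo)
only autofluoresces. Because reporter proteins fold incompletely (oxygen
dependence, physiological state), one species can produce several event
clusters — Bv up to four (double-positive, GFP-only, mCherry-only, dark) —
and cluster positions drift with growth condition, so fixed manual gates
cannot assign clusters to species. `flowdeconv` implements the three-stage
alternative:

1. **Within-sample clustering.** 10,000 randomly selected gated events per
   sample are split 80:20; full-covariance Gaussian mixtures with
   k = 1..k_max are fitted on the training split and scored by the Bayesian
   Information Criterion on the held-out split. The k minimizing held-out
   BIC wins and the mixture is refitted on all sampled events. k_max depends
   on culture type: 2 for Bo/Bf/Bt monocultures, 4 for Bv, 10 for
   co-cultures, and exactly 1 for sterile controls with at least 100 events
   (below that a sample is flagged below detection).
2. **Cluster classification.** A 1,000-tree random forest is trained on
   monoculture clusters, whose species labels are known by construction,
   and predicts a species (with class probability) for every co-culture and
   sterile-background cluster.
3. **Abundance accounting.** A species' relative abundance is the summed
   weight of its clusters. Absolute totals come from volumetric counting:
   events are acquired from a fixed 3 µl injection, so
   cells/ml = retained events / 0.003 ml × 5 (the 5-fold pre-acquisition
   dilution). Monoculture totals subtract the sterile-media total;
   co-cultures subtract *species-specific* backgrounds obtained by
   classifying the sterile clusters, because background particles
   autofluoresce and would otherwise bias individual species. Negative
   corrected values clamp to zero and are logged.

On a BIC sign note: selection maximizes held-out goodness of fit, which
under the standard definition BIC = p·ln n − 2·ln L̂ means *minimizing* BIC;
the full per-k trace is stored in every `ClusterSet` so the selection can be
audited under either sign convention. The held-out n is used in the penalty
term. The 80:20 split is simple random (unstratified).

## Gating

Events are retained when all five channels (FSC-H, SSC-H, GFP-H, mCherry-H,
SYTO-H) are nonzero and the SYTO 40 nucleic-acid stain signal exceeds 450
arbitrary units. "Above the threshold" is read strictly; the inclusive
variant is configurable and differs only on a measure-zero set for
continuous data. Sterile controls pass through the same gate with no
special-casing. Channel aliases (B1-H→GFP-H, Y2-H→mCherry-H, V1-H→SYTO-H)
map instrument exports onto canonical names.

## Classifier features

Clusters are featurized by their five channel means. The mixture weight and
per-channel SDs are available behind flags but are off by default: training
weights are stereotyped by monoculture subcluster structure (≈0.85/0.15 for
single-reporter species, ≈0.7/0.1/0.1/0.1 for Bv) while deployment weights
reflect community composition, an out-of-distribution shift that measurably
degrades co-culture predictions when weight is included. Cluster-level
error is reported unweighted (each cluster counts once) with a
weight-weighted variant alongside; the evaluation table carries weight,
estimated cell count, and prediction probability per cluster so failure
modes (low-weight, low-count clusters) can be diagnosed.

## Ecology layer

Per medium: *maximum monoculture productivity* is the largest replicate-mean
abundance reached by any species at any timepoint; *maximum co-culture
productivity* the largest replicate-mean total. Replicates are averaged at
each timepoint before maxima (the alternative, max-then-mean, is provided
behind `max_per_replicate_then_mean`). Growth on a substrate is positive
when a species' maximum is at least 2× its maximum on the water control
(inclusive; a zero control yields positive iff any growth, logged).
Co-culture totals at least 20% below the monoculture maximum are called
competition; at least 20% above, cross-feeding; otherwise neutral — both
thresholds inclusive, matching "at least". The same +20% margin defines
per-species benefit, with the convention that a species absent in
monoculture but present in co-culture benefits (infinite ratio; the
cross-fed-growth case). Simpson's evenness is E = (1/Σ pᵢ²)/S with S fixed
at the seeded richness (4), not the detected richness, so the index is
continuous as species cross the detection limit. Substrate classes
(simple/complex) are input metadata, never inferred.

## Statistics

Mann–Whitney U uses the exact null distribution for tie-free samples with
combined n ≤ 12 and the tie-corrected normal approximation otherwise;
Spearman's ρ uses average ranks. Multiple-comparison correction defaults to
plain Bonferroni, p_adj = min(1, m·p) with caller-supplied m (the study's
comparison families are not enumerable from the outside); Holm and
Benjamini–Hochberg are selectable. The diversity–productivity association
is fitted as mean(evenness) = logit⁻¹(a + b·log10(productivity)) under a
gaussian family — a fractional-response mean model, not binomial logistic
regression, because evenness is continuous in (0, 1); the logit link keeps
fitted means inside the unit interval. Two-sided alternatives throughout.

## The synthetic-data generator

No real cytometry files ship with the package; a generator emulates the
study system so every stage is testable against ground truth.

* **Design.** 33 media (31 carbon substrates — 11 simple, 20 complex,
  including both inulin formulations — plus a rich mGAM control and a water
  control) × 5 culture types × 2 replicates × 4 timepoints
  (24/48/72/102 h) = 1,320 culture samples, of which 1,056 are
  monocultures; duplicate sterile controls per medium sit outside that
  count. The design's printed totals are consistent with 33 media; a figure
  caption counting "34 tested media" can be read as counting the two inulin
  vendors separately, and the 33-media grid is kept as the default.
* **Archetypes.** Each species is a mixture of up to 4 (Bv) or 2 (others)
  5-D Gaussian subclusters on the linear arbitrary-unit scale. Fluorescence
  means encode the reporter logic above; fluorescence SD follows a 12%
  constant-CV rule floored at 60 a.u. Scatter and stain baselines differ by
  species (cell size/granularity/nucleic-acid content), which is what makes
  forward/side scatter informative for classification, as it is on the real
  instrument.
* **Condition effects.** Reporter intensities drift with growth medium: a
  log-normal factor (σ = 0.15) per medium and channel, derived
  deterministically from the medium name so monocultures and co-cultures
  drift together. A per-sample log-normal jitter (σ = 0.03) on all channel
  means emulates instrument/day drift. These two effects are why a trained
  classifier, not a fixed gate, is needed — and why classifier training
  must span many conditions.
* **Debris and background.** Debris is a separate component, not
  per-species noise: 80% unstained (SYTO far below the gate, some channels
  clipping to zero so the nonzero-channel gate has work) and 20% stained
  particulates that pass the gate and autofluoresce like Bo — the
  species-specific background that the correction stage exists to remove.
  Sterile media carry background at 8% of the permissive-growth cell
  density (≈2×10⁶ particles/ml against 2.5×10⁷ cells/ml cultures).
* **Growth model.** Per-medium carrying capacities: simple sugars 1.2× and
  complex 0.8× the 2.5×10⁷ cells/ml baseline, rich medium 1.5×, water
  0.04×; a batch growth curve over the four timepoints (0.6/1.0/0.9/0.8 of
  capacity); 5% log-normal noise. Co-culture totals are 70% of the
  monoculture level on simple sugars (competition) and at parity on complex
  sugars. Co-culture composition is stable per medium with Bv's share
  rising with medium productivity — the study-system working model in which
  Bv drives both competition and cross-feeding gains, so less productive
  communities stay more even.
* **Separation scenarios.** Three named archetype sets scale every
  channel's SD: well-separated (0.5×, minimum inter-species centroid
  distance ≥ 5 pooled SD), the default realistic overlap (1×), and heavy
  overlap (15×, ≤ 1 pooled SD, which blurs scatter as well as fluorescence
  so no channel rescues the classifier).
* **Event counts.** The expected event count is density × 0.0006 ml
  (3 µl / 5-fold dilution), Poisson-perturbed and capped (default 25,000)
  to keep full designs tractable; cell intensities floor at 1 a.u. (the
  instrument trigger threshold), debris at 0. Everything is reproducible
  from one integer seed via per-sample seed derivation.

### What the generator does not emulate

Spillover/compensation between fluorescence channels, doublets,
non-Gaussian cluster shapes, time-dependent drift within an acquisition,
and count-dependent acquisition artifacts. Passing recovery benchmarks on
this generator therefore shows the algorithm is correct and calibrated on
Gaussian-mixture data with realistic overlap, drift, and background — not
that the trained forest would transfer to another instrument's raw files.

## Benchmarks and problem sizes

The built-in benchmarks (`flowdeconv.benchmark`) use a width-reduced study:
8 training media × 4 timepoints × 2 replicates of each monoculture
(256 samples) at 15,000 events per sample with the full 10,000-event
clustering subsample, then 30 co-cultures (10 independent seed batches × 3)
with Dirichlet(1.5) compositions. Typical results: replicate-split cluster
error below 2%, co-culture cluster error ≈ 3%, relative-abundance MAE
≈ 0.025. Component-count recovery uses 12 runs of 1–4 well-separated
components at 2,000 events. GLM calibration uses n = 200 per fit with noise
SD 0.05 (slope recovery) and 500 null replicates (type-I error). These
sizes are the package's chosen defaults for routine verification; wider
designs only improve the classifier, as training breadth is what covers the
per-sample drift.

## Numerical choices and edge cases

* GMM: full covariance, ridge 10⁻⁶ on the diagonal, EM with 5 random
  restarts keeping the best train likelihood; ties in k-selection break
  toward smaller k. Events are clustered on raw intensities; an asinh
  transform is available but off by default.
* Minimum events: 50 to attempt clustering (below: flagged unclustered),
  100 for a sterile control to count as detected.
* Weight normalization is enforced to 10⁻⁹; relative abundances inherit it.
* Background models pool the duplicate sterile replicates per medium;
  backgrounds are not built per timepoint.
* Absolute counts always use the full gated event count, never the
  clustering subsample.
* A low-biomass co-culture (e.g. on water) often under-resolves to a single
  cluster, collapsing measured evenness to 0.25 regardless of the true
  composition; this measurement artifact attenuates — and at the low end
  can invert — the diversity–productivity association in small synthetic
  studies.

## Known limitations

The classifier only ever answers with the four trained species (no reject
class; an optional probability floor can route low-confidence clusters to
"unassigned" but defaults to off). Cluster blends — mixture components that
straddle two species when the component cap binds (a four-species
co-culture has up to 10 true subclusters plus background against a cap of
10) — are the dominant residual error source. FCS support covers the
single-dataset list-mode float layout this package writes plus standard
3.0/3.1 reads of that layout, not every vendor extension.
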