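# flowdeconv

Species deconvolution of multicolor flow cytometry for defined microbial
communities.

## The problem

Bottom-up microbial ecology needs a fast, cheap way to count *each* member
of a synthetic community, not just total cells. For a four-member
*Bacteroides* community tagged with fluorescent reporters — *B. vulgatus*
(GFP + mCherry), *B. theta* (GFP), *B. fragilis* (mCherry), *B. ovatus*
(autofluorescent wild type) — multicolor flow cytometry can in principle
resolve all four species in one 3 µl injection. In practice fixed gates
fail: incomplete reporter maturation splits one species into several event
clusters (*B. vulgatus* into up to four), and cluster positions drift with
the growth medium. `flowdeconv` implements the machine-learning alternative
and the downstream community-ecology analysis, for anyone building
fluorescently barcoded consortia and screening them across many conditions.

## The method

Events `x ∈ ℝ⁵` (FSC-H, SSC-H, GFP-H, mCherry-H, SYTO-H) are gated
(all channels nonzero, SYTO-H > 450 a.u.), then processed in three stages:

1. **Clustering.** Per sample, 10,000 events are modeled as a Gaussian
   mixture `p(x) = Σₖ wₖ N(x; μₖ, Σₖ)` with full covariances. The component
   count is chosen by minimizing BIC = p·ln n − 2·ln L̂ on a held-out 20%
   split, under culture-type caps (mono 2, *B. vulgatus* 4, co-culture 10,
   sterile 1).
2. **Classification.** A 1,000-tree random forest maps cluster mean vectors
   to species, trained on monoculture clusters whose labels are known by
   construction.
3. **Quantification.** Relative abundance of species s is `Σ_{k→s} wₖ`;
   absolute abundance is `retained events / 0.003 ml × 5` (volumetric
   counting with 5-fold dilution), background-corrected per species using
   classified sterile-media clusters.

An ecology layer computes maximum mono/co-culture productivity, 2× growth
calls against the water control, ±20% competition/cross-feeding calls,
Simpson's evenness `E = (1/Σpᵢ²)/S`, and the supporting statistics
(Mann–Whitney U, Spearman's ρ, Bonferroni correction, gaussian-family
logit-link GLM of evenness on log₁₀ productivity). A synthetic-event
generator with known ground truth (the full 1,320-sample factorial design)
makes every stage testable end to end; see `docs/methods.md`.

## Worked example

```python
from flowdeconv import RunConfig, run_pipeline, DesignGrid
from flowdeconv.clustering import ClusterConfig

grid = DesignGrid(media=("glucose", "fructose", "maltose", "cellobiose",
                         "inulin (Sigma)", "xylan", "pectin", "laminarin",
                         "mGAM", "Water"),
                  timepoints=(24.0, 48.0))
config = RunConfig(grid=grid, seed=3, baseline_density=6e6, max_events=5000,
                   cluster=ClusterConfig(subsample_n=2500, n_restarts=3),
                   n_trees=300)
result = run_pipeline(config, outdir="scratch/demo")

print(result.evaluation.overall_error)
print(result.ecology[["medium", "substrate_class", "interaction_call"]])
```

Output (abridged):

```
0.0053
            medium substrate_class interaction_call
           glucose          simple      competition
          fructose          simple      competition
           maltose          simple      competition
    inulin (Sigma)         complex          neutral
             xylan         complex          neutral
            pectin         complex          neutral
```

The `0.0053` is the cluster-classification error when the forest is trained
on replicate 1 of every monoculture and scored on replicate 2 — about half
a percent of held-out clusters get the wrong species. The interaction calls
reproduce the generator's built-in ecology: co-culture totals at least 20%
below the best monoculture on simple sugars (resource competition), parity
on complex sugars. `scratch/demo/` receives tidy `abundance.csv`,
`ecology.csv`, `evenness.csv`, a stats JSON, and a run manifest with event
conservation per sample.

The same pipeline is scriptable from the shell:

```bash
flowdeconv gen --seed 1 --out scratch/study --media 4
flowdeconv run-all --seed 1 --out scratch/run --media 4
flowdeconv gate --in scratch/study/events/co_arabinose_r1_t24.csv \
                --out scratch/gated.csv --syto-threshold 450
```

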