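# rpa — read-profile analysis of small RNA processing

`rpa` detects **differential** and **coherent post-transcriptional
processing** of small RNAs from multi-sample short RNA-seq data. It works on
*read profiles* (block groups): the ordered stacks of reads left at a
genomic locus by processed RNA fragments — the two arms of a pre-miRNA
hairpin, tRNA halves, snoRNA-derived fragments, TSS-associated ~17-nt RNAs.
When a subset of cell lines or tissues expresses one end of a locus and the
rest express the other end (miRNA *arm switching* being the classic case),
the profile shape changes even though overall expression may not — a signal
invisible to count-based differential expression.

It is a library first (`import rpa`, see `examples/`), with a thin `rpa`
command-line interface for shell use.

## Method

For every genomic locus with a read profile in all *N* samples:

1. **Block grouping.** Reads closer than 50 nt share a locus; blocks are
   detected by an iterative Gaussian-peak procedure (σ = 0.5 × read length,
   count-weighted); groups need ≥ 10 reads and blocks ≥ 10% of the group
   (a relative cut-off, so depth does not change profile shape).
2. **Harmonization.** Consensus block coordinates (reciprocal overlap
   ≥ 90% merges) are imposed on every sample; each consensus block gets a
   single dummy pseudoread plus the sample's raw reads, and single-block
   loci receive a shared neutral dummy block so profiles always have ≥ 2
   blocks.
3. **Alignment score matrix.** All profiles at the locus are aligned
   all-vs-all; the score *S* ∈ [0, 1] compares depth-normalized block
   heights and within-block read arrangements under an order-preserving
   match/skip alignment.
4. **Bootstrap clustering & cluster score.** Profiles are clustered
   (1 − Pearson correlation, average linkage) with multiscale bootstrap
   resampling; clusters with approximately-unbiased support p < 0.05 are
   scored X_k = max(0, S̄_in − S̄_out) and the locus cluster score is
   X = mean_k X_k. Loci with **X ≥ 0.15** are candidate differentially
   processed loci (DPL). With replicates, both replicates of a line must
   co-cluster and a supported cluster needs ≥ 4 profiles.
5. **Validation.** Per-sample size factors s_j (median of ratios to a
   geometric-mean pseudo-reference) normalize block counts; every sample
   pair is compared with an exact m × 2 test of independence on normalized
   block expressions, and a candidate is a validated DPL only if, in some
   supported cluster, > 50% of in-cluster samples are significant
   (p < 0.05) against *every* out-of-cluster sample — so depth artifacts
   can never validate.
6. **Coherence.** Loci with mean pairwise alignment score **≥ 0.8** are
   coherently processed loci (CPL); profiles with one block, entropy ≤ 2
   bits and span ≤ 40 nt are flagged *short and precise*.
7. **Enrichment.** Loci are labelled against ncRNA/region annotations;
   enrichment in genomic features uses a binomial dart-throwing null, and a
   strand-aware TSS metaprofile bins percent overlap in 20-nt bins across
   ±1000 nt.

A built-in simulator (`rpa.simulate`) generates replicated multi-sample
datasets with known truth — arm switching, arm loss, coherent one/two-block
loci, noise, and depth-only negative controls — so the whole pipeline is
testable without sequencing data.

## Worked example

```python
from rpa import PipelineConfig, run_pipeline
from rpa.simulate import benchmark_scenarios, simulate_dataset

scenarios = benchmark_scenarios(n_arm_switch=4, n_coherent=4,
                                n_noise=0, n_depth_controls=2)
ds = simulate_dataset(scenarios, seed=7)
res = run_pipeline(ds.reads_by_sample, ds.replicate_map,
                   PipelineConfig(n_boot=200, seed=7))
print(res.summary.merge(ds.truth, on="locus_id")[
    ["locus_id", "scenario", "cluster_score", "validated_dpl",
     "mean_alignment_score", "cpl"]].to_string(index=False))
```

prints (seed 7):

```
 locus_id           scenario  cluster_score  validated_dpl  mean_alignment_score   cpl
        1         arm_switch       0.381894           True              0.681364 False
        2         arm_switch       0.365171           True              0.675654 False
        3         arm_switch       0.363423           True              0.672109 False
        4         arm_switch       0.372610           True              0.678343 False
        5 coherent_one_block       0.000000          False              0.961790  True
        6 coherent_one_block       0.011517          False              0.967382  True
        7 coherent_two_block       0.039941          False              0.869376  True
        8 coherent_two_block       0.041792          False              0.873807  True
        9    depth_imbalance       0.044040          False              0.887186  True
       10    depth_imbalance       0.000000          False              0.893781  True
```

The four arm-switch loci score X ≈ 0.37 (≥ 0.15) and survive expression
validation; the coherent loci have X near 0 and mean S ≥ 0.8 (CPL); the
depth-only controls — identical shape, 5× depth imbalance — are called
neither. The same run is available from the shell:

```bash
rpa simulate --out sim --seed 7
rpa run --samples sim/samples.tsv --nboot 500 --seed 7 --out results/
```

See `examples/` for one short script per capability (block grouping,
profile alignment and entropy, the differential scan, coherence calls,
enrichment statistics, the simulator).

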