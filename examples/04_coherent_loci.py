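"""Coherent-processing calls and the short/precise profile signature.

A locus whose profiles are alike in every sample (mean pairwise alignment
score >= 0.8) is a coherently processed locus (CPL).  Many CPL profiles are
"short and precise": one block, entropy <= 2 bits, span <= 40 nt — the
signature of small processed RNAs such as ~17-nt TSS-associated RNAs.
"""

from rpa import (PipelineConfig, call_cpl, classify_short_precise,
                 compute_score_matrix, run_pipeline)
from rpa.simulate import benchmark_scenarios, simulate_dataset

scenarios = benchmark_scenarios(n_arm_switch=2, n_coherent=4, n_noise=0,
                                n_depth_controls=0)
ds = simulate_dataset(scenarios, seed=3)
res = run_pipeline(ds.reads_by_sample, ds.replicate_map,
                   PipelineConfig(n_boot=0, boot_method="bp", seed=3))

for lr in res.loci:
    scenario = ds.truth.loc[ds.truth.locus_id == lr.locus.locus_id,
                            "scenario"].item()
    print(f"locus {lr.locus.locus_id:2d} [{scenario:>18s}] "
          f"mean S = {lr.cp_call.mean_score:.3f}  CPL = {lr.cp_call.is_cpl}  "
          f"short/precise fraction = {lr.short_precise_fraction:.2f}")

# The ~17-nt one-block loci are CPL with a short/precise fraction of 1.0;
# arm-switch loci fall well below the 0.8 coherence threshold.
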