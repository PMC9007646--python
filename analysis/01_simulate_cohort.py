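"""Generate the synthetic two-risk-group cohort that every later step consumes.

Writes count matrices (mRNA/lncRNA/miRNA), miRNA->target interaction
tables, the clinical table with survival endpoints, gene sets, and the
planted-truth manifest under results/inputs/.
"""

from _workspace import INPUTS

from spongecerna.synthetic import SimParams, simulate_cohort

params = SimParams(seed=1)
cohort = simulate_cohort(params)
cohort.write(INPUTS)

n = params.n_low + params.n_high
print(f"simulated {n} samples ({params.n_low} low-risk, {params.n_high} high-risk)")
print(f"matrices: mRNA {cohort.expression['mRNA'].shape}, "
      f"lncRNA {cohort.expression['lncRNA'].shape}, "
      f"miRNA {cohort.expression['miRNA'].shape}")
print(f"planted: {len(cohort.truth.de_genes)} DE genes, "
      f"{len(cohort.truth.triplets)} sponge triplets, "
      f"{len(cohort.truth.prognostic_hubs)} prognostic hubs")
print(f"observed censoring fraction: {1 - cohort.clinical['os_event'].mean():.3f}")
print(f"wrote inputs to {INPUTS}")
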