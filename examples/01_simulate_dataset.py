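"""Generate a synthetic genotype-environment scenario and inspect it.

Builds the default demo study: 40 sites on an east-west gradient grouped
into 4 drift regions, 20 diploids per site, 1000 biallelic loci of which 20
track the "temperature" gradient with effect size |beta| = 1.5 on the
logit of site allele frequency.  Prints the dataset dimensions and how the
planted loci are labelled.
"""

import numpy as np

from adaptscape import default_config, make_scenario

bundle = make_scenario(default_config(seed=42), out_dir="scratch/demo_scenario")

G = bundle.genotypes
print(f"individuals: {G.n_individuals}, loci: {G.n_loci}")
print(f"missing genotype fraction: {np.isnan(G.dosages).mean():.3f}")
print(f"sites: {len(bundle.site_table.site_ids)}, "
      f"waterways: {bundle.site_table.table['waterway_id'].nunique()}")
print(f"environment variables: {bundle.env_current.variables}")
print(f"planted adaptive loci: {bundle.truth['adaptive'].sum()} "
      f"(causal variable: {bundle.config.causal_variable})")
print("files written to scratch/demo_scenario/")
# The truth table ties each adaptive locus to its causal variable and effect
# size, which downstream examples use to score outlier-detection accuracy.
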