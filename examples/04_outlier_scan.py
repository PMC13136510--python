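"""Detect loci associated with environmental gradients and score accuracy.

Runs the GEA core on the demo scenario: partial RDA of genotypes on
environment conditioned on neutral-structure PCs, Mahalanobis distances of
locus loadings over the first two axes, inflation-factor correction,
chi-square p-values, and a 1% Bonferroni threshold.  Because the data are
synthetic, the planted truth scores recall and empirical false discovery.
"""

from adaptscape import default_config, make_scenario
from adaptscape.pipeline import gea_scan

bundle = make_scenario(default_config(seed=42))
res = gea_scan(bundle.genotypes, bundle.env_current,
               keep_list=[bundle.config.causal_variable])
report = res["report"]

truth = bundle.truth.set_index("locus_id")["adaptive"]
planted = set(truth.index[truth])
flagged = set(report.outlier_ids)

print(f"loci scanned: {report.n_loci}")
print(f"inflation factor lambda: {report.inflation_factor:.3f}")
print(f"flagged outliers: {len(flagged)} at Bonferroni alpha=0.01")
print(f"recall of planted loci: {len(flagged & planted) / len(planted):.2f}")
print(f"empirical FDR: {len(flagged - planted) / max(len(flagged), 1):.2f}")
print(f"variables dropped by |r|>0.7 pruning: {list(res['dropped']['variable'])}")
# lambda near 1 means the chi-square null calibration holds after
# correction; recall near 1 and FDR near 0 mean the scan separates the
# planted environmental signal from hierarchical drift.
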