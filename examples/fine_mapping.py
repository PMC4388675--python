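"""Stepwise conditional fine-mapping of a simulated disease locus.

Builds a locus with three protective missense variants on distinct
haplotype backgrounds (ORs 0.66 / 0.53 / 0.86 at MAFs 3.4% / 0.8% / 8%),
simulates a case-control cohort, and runs the forward conditional scan.
Each selected round's p-value is the variant's association conditional on
the previously selected variants; the scan stops when no remaining variant
reaches P < 0.01.
"""

import numpy as np

import finehap as fh

model = fh.build_locus_model(tag_maf=None)  # three independent signals + null commons
genotypes, subjects = fh.simulate_case_control(model, 7_222, 15_870, seed=3)
y = subjects["status"].to_numpy(float)
covariates = subjects[["age", "sex", "PC1", "PC2"]].to_numpy(float)

scan = fh.conditional_scan(genotypes, y, covariates, stop_p=0.01)
print("round  variant    OR      p")
for k, res in enumerate(scan.selected, start=1):
    print(f"{k:>5}  {res.variant_id:<9} {res.or_:.3f}  {res.p:.3g}")
print(f"stop: best remaining p = {scan.stop_best_p:.3g} (threshold 0.01)")
# The selected variants are the statistically independent signals at the
# locus; their round ORs estimate the planted per-allele effects.  Near
# the stopping threshold an occasional null variant can sneak in on a
# given seed - that is the scan's stated false-selection rate at work.
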