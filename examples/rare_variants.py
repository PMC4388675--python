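"""Rare-variant collapsing tests with a planted control-side cluster.

Appends a rare missense background to a sequencing-scale cohort (1,118
cases / 1,118 controls) with 7 damaging variants — 5 of them singletons —
concentrated in controls inside the kinase-1 domain, then runs the
gene-level tests and a 500 bp sliding-window scan.  One-sided tests run
per arm; the control arm should light up.
"""

import numpy as np

import finehap as fh
from finehap.rare import VariantMask, gene_test, window_scan
from finehap.synthetic import Enrichment

model = fh.build_locus_model()
genotypes, subjects = fh.simulate_case_control(model, 1_118, 1_118, seed=3)
genotypes = fh.simulate_rare_background(
    genotypes, model, seed=4, n_variants=7, singleton_fraction=5 / 7,
    enrichment=Enrichment(arm="control"), subjects=subjects,
)
y = subjects["status"].to_numpy(float)

print("gene-level tests (B = 2,000 permutations):")
for r in gene_test(genotypes, y, "TYK2", mask=VariantMask(damaging_only=True),
                   B=2_000, seed=5, n_genes_tested=11):
    print(f"  {r.method:<7} {r.arm:<9} stat={r.statistic:7.3f} "
          f"p_emp={r.p_empirical}  {r.note}")

track = window_scan(genotypes, y, "TYK2", cds_length=3564, window_bp=500,
                    mask=VariantMask(damaging_only=True), B=500, seed=6)
tested = track.dropna(subset=["p_empirical"])
best = tested.loc[tested["p_empirical"].idxmin()]
lo, hi = model.genes["TYK2"].domains["protein_kinase_1"]
print(f"\nwindow scan: min p = {best['p_empirical']:.4f} at CDS position "
      f"{int(best['cds_pos'])} (kinase-1 domain spans {lo}-{hi})")
# The empirical p is (r+1)/(B+1) from case-control label permutation; the
# minimum-p window localising inside the planted domain reproduces the
# control-enrichment cluster.
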