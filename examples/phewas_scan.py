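"""Phenome-wide scan across two synthetic EMR cohorts with meta-analysis.

Simulates a small and a large EMR cohort sharing one planted effect (an
"RA-like" phenotype protected by the strongest variant, OR 0.65), defines
cases by the two-event rule, filters phenotypes to >1% prevalence in both
cohorts, fits per-cohort logistic models and combines them by
inverse-variance meta-analysis.
"""

import numpy as np

import finehap as fh
from finehap.phewas import CodeMap, define_cases, phewas_scan, prevalence_filter
from finehap.synthetic import EmrModel, simulate_emr

model = fh.build_locus_model()
emr_model = EmrModel.default(40, include_infections=False)
emr_model.phenotype_prevalences["P001"] = 0.15  # the RA-like phenotype (enriched)
emr_model.planted_effects[("P1104A", "P001")] = np.log(0.65)

cohorts = {}
for name, (n_case, n_ctrl, seed) in {"small": (600, 2_405, 10),
                                     "large": (5_000, 21_372, 11)}.items():
    gm, subj = fh.simulate_case_control(model, n_case, n_ctrl, seed=seed)
    emr = simulate_emr(emr_model, gm, subj, seed=seed + 100)
    cmap = CodeMap(emr_model.code_map())
    status = define_cases(emr["events"], cmap, subject_ids=gm.subject_ids)
    covs = subj[["age", "sex", "PC1", "PC2"]].to_numpy(float)
    cohorts[name] = (gm.column("P1104A"), status, covs)

kept = prevalence_filter({k: v[1] for k, v in cohorts.items()}, min_prev=0.01)
rows = phewas_scan(
    {k: v[0] for k, v in cohorts.items()},
    {k: v[1][kept] for k, v in cohorts.items()},
    {k: v[2] for k, v in cohorts.items()},
    alpha=1e-4,
)
print(f"{len(kept)} phenotypes pass the 1% prevalence filter in both cohorts")
hits = [r for r in rows if r.meta is not None and r.meta.p < 1e-4]
print(f"{len(hits)} significant at P < 1e-4:")
for r in hits:
    print(f"  {r.phenotype}: OR_meta = {r.meta.or_:.2f}, P_meta = {r.meta.p:.2g}")
planted = {r.phenotype: r for r in rows}["P001"]
lo, hi = planted.meta.ci()
print(f"planted RA-like row: OR_meta = {planted.meta.or_:.2f} "
      f"[{lo:.2f}-{hi:.2f}], P_meta = {planted.meta.p:.2g}")
# Only the planted RA-like phenotype should surface; every other phenotype
# is a draw from the global null, and the planted CI should cover 0.65.
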