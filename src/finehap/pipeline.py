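"""End-to-end pipeline driver: simulate -> QC -> conditional scan ->
haplotype model -> rare-variant tests -> PheWAS -> power, with per-stage
toggles and a single run manifest.

The configuration is a plain dict (typically loaded from YAML); every
stage writes its result tables under the output directory and records them
in the manifest.  A stage failure halts the run with the stage name while
earlier outputs stay on disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, haplotype, phewas, power, qc, rare, synthetic, vcfio
from .containers import GenotypeMatrix

__all__ = ["pipeline_run", "DEFAULT_CONFIG", "haplotype_table"]

DEFAULT_CONFIG = {
    "seed": 0,
    "n_case": 1500,
    "n_control": 3000,
    "stages": {
        "qc": True, "condscan": True, "hap": True,
        "rare": True, "phewas": True, "power": True,
    },
    "condscan": {"stop_p": 0.01},
    "hap": {"min_freq": 1e-3},
    "rare": {"B": 1000, "gene": "TYK2"},
    "phewas": {"n_phenotypes": 30, "alpha": 1e-4, "min_prev": 0.01},
    "power": {"maf": 0.034, "n_total": 26372, "alpha": 1e-4},
}


def _covariate_matrix(subjects: pd.DataFrame) -> np.ndarray:
    cols = ["age", "sex"] + [c for c in subjects.columns if c.startswith("PC")]
    return subjects[cols].to_numpy(dtype=float)


def haplotype_table(fit: "haplotype.HaplotypeFit", variant_ids: list[str]) -> pd.DataFrame:
    """Haplotype summary table: one allele column per variant (minor allele
    as 1), frequency, OR with 95% CI, and p versus the reference."""
    rows = []
    for h, f in zip(fit.haplotypes, fit.frequencies):
        r = fit.results[h]
        lo, hi = r.ci() if r.se > 0 else (1.0, 1.0)
        row = {vid: a for vid, a in zip(variant_ids, h)}
        row.update(
            {
                "frequency": round(float(f), 5),
                "OR": round(r.or_, 4),
                "CI_low": round(lo, 4),
                "CI_high": round(hi, 4),
                "p": r.p,
                "reference": h == fit.reference,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def pipeline_run(config: dict | None = None, out_dir: str | Path = "finehap_out") -> dict:
    """Run the configured stages in the pipeline's canonical order.

    Returns a dict of in-memory results keyed by stage; tables are also
    written as TSV under ``out_dir`` together with ``manifest.json``.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    stages = {**DEFAULT_CONFIG["stages"], **cfg.get("stages", {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = vcfio.RunManifest(command="run", seed=cfg["seed"], config=cfg)
    results: dict = {}
    stage = "simulate"
    try:
        rng = np.random.default_rng(cfg["seed"])
        model = synthetic.build_locus_model()
        gm, subjects = synthetic.simulate_case_control(
            model, cfg["n_case"], cfg["n_control"], seed=int(rng.integers(2**31))
        )
        gm = synthetic.simulate_rare_background(
            gm, model, seed=int(rng.integers(2**31)), n_variants=10,
            singleton_fraction=0.5,
        )
        results["simulate"] = {"genotypes": gm, "subjects": subjects, "model": model}
        vcfio.write_vcf(gm, out / "genotypes.vcf")
        subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        vcfio.write_annotation_table(gm, out / "annotations.tsv")
        y = subjects["status"].to_numpy(dtype=float)
        covs = _covariate_matrix(subjects)

        if stages["qc"]:
            stage = "qc"
            report = qc.call_rate_filter(gm, controls=(y == 0))
            report.variant_table.to_csv(out / "qc_variants.tsv", sep="\t", index=False)
            report.sample_table.to_csv(out / "qc_samples.tsv", sep="\t", index=False)
            gm = report.genotypes
            results["qc"] = report

        common = [v.variant_id for j, v in enumerate(gm.variants) if gm.maf()[j] >= 0.005]
        gcommon = gm.subset_variants(common)

        if stages["condscan"]:
            stage = "condscan"
            scan = assoc.conditional_scan(
                gcommon, y, covs, stop_p=cfg["condscan"]["stop_p"]
            )
            rows = []
            for k, rnd in enumerate(scan.rounds, start=1):
                for r in rnd:
                    rows.append(
                        {"round": k, "variant_id": r.variant_id, "beta": r.beta,
                         "se": r.se, "OR": r.or_ if np.isfinite(r.beta) else np.nan,
                         "p": r.p, "selected": r.variant_id in scan.selected_ids[:k],
                         "note": r.note}
                    )
            pd.DataFrame(rows).to_csv(out / "condscan.tsv", sep="\t", index=False)
            results["condscan"] = scan

        if stages["hap"]:
            stage = "hap"
            core = [v for v in model.core_ids if v in gcommon.variant_ids]
            phase = haplotype.em_phase(gcommon.subset_variants(core).dosages)
            fit = haplotype.haplotype_regression(
                phase, y, covs, min_freq=cfg["hap"]["min_freq"]
            )
            haplotype_table(fit, core).to_csv(out / "haplotypes.tsv", sep="\t", index=False)
            results["hap"] = fit

        if stages["rare"]:
            stage = "rare"
            res = rare.gene_test(
                gm, y, cfg["rare"]["gene"], covariates=covs,
                B=cfg["rare"]["B"], seed=int(rng.integers(2**31)),
                n_genes_tested=len(model.genes),
            )
            pd.DataFrame(
                [
                    {"set": r.set_id, "method": r.method, "arm": r.arm,
                     "n_variants": len(r.variant_ids), "statistic": r.statistic,
                     "p_empirical": r.p_empirical, "p_analytic": r.p_analytic,
                     "B": r.n_perm, "note": r.note}
                    for r in res
                ]
            ).to_csv(out / "rare_gene.tsv", sep="\t", index=False)
            results["rare"] = res

        if stages["phewas"]:
            stage = "phewas"
            emr_model = synthetic.EmrModel.default(cfg["phewas"]["n_phenotypes"])
            emr = synthetic.simulate_emr(emr_model, gm, subjects, seed=int(rng.integers(2**31)))
            cmap = phewas.CodeMap(emr_model.code_map())
            statuses = phewas.define_cases(
                emr["events"], cmap, subject_ids=gm.subject_ids
            )
            kept = phewas.prevalence_filter({"cohort1": statuses},
                                            min_prev=cfg["phewas"]["min_prev"])
            dos = gm.column(model.core_ids[0])
            rows = phewas.phewas_scan(
                {"cohort1": dos}, {"cohort1": statuses[kept]}, {"cohort1": covs},
                alpha=cfg["phewas"]["alpha"],
            )
            pd.DataFrame(
                [
                    {"phenotype": r.phenotype,
                     "OR": r.meta.or_ if r.meta else np.nan,
                     "p": r.meta.p if r.meta else np.nan,
                     "untestable": ",".join(r.untestable)}
                    for r in rows
                ]
            ).to_csv(out / "phewas.tsv", sep="\t", index=False)
            results["phewas"] = rows

        if stages["power"]:
            stage = "power"
            grid = power.power_grid(
                cfg["power"]["maf"], cfg["power"]["n_total"], cfg["power"]["alpha"]
            )
            grid.to_csv(out / "power_grid.tsv", sep="\t")
            results["power"] = grid
    except Exception as exc:
        raise RuntimeError(f"pipeline halted in stage {stage!r}: {exc}") from exc
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.vcf")):
        manifest.add_output(f)
    manifest.write(out / "manifest.json")
    results["manifest"] = manifest
    return results
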