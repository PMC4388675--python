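"""Synthetic case-control and EMR cohort generation.

The generator reproduces the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any external data:

* a disease locus carrying three protective missense variants whose minor
  alleles sit on three distinct haplotype backgrounds (default MAFs
  0.034 / 0.008 / 0.08 with per-allele odds ratios 0.66 / 0.53 / 0.86), plus
  a common benign tag variant in imperfect LD with the causal haplotypes
  and a configurable number of null common variants in linkage
  equilibrium;
* disease status drawn from a logistic model in haplotype-borne allele
  dosages, with case/control ascertainment by rejection sampling to exact
  counts — so the planted odds ratios are the direct estimands of the
  downstream logistic fits;
* a rare missense background (singletons included) with an optional
  enrichment mode that concentrates damaging carriers in one arm within a
  stated CDS interval;
* platform masks (chip designs miss rare variants; sequencing sees all);
* an EMR with configurable phenotype prevalences, ICD-style coded events,
  LDL and white-cell quantitative traits, and planted genotype-phenotype
  effects (empty by default: a global null).

Everything is driven by a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, VariantRecord

__all__ = [
    "GeneModel",
    "LocusModel",
    "LocusConfig",
    "EmrModel",
    "Enrichment",
    "build_locus_model",
    "simulate_case_control",
    "simulate_rare_background",
    "simulate_emr",
    "apply_platform_mask",
    "make_infection_codesets",
    "MAF_PRESETS",
]

# the two printed MAF sets for the three protective variants: the
# fine-mapping results quote 3.4% / 0.8% / 8%, the power calculations
# 3.4% / 0.7% / 8.7%; both are exposed rather than reconciled
MAF_PRESETS = {
    "results": (0.034, 0.008, 0.080),
    "power": (0.034, 0.007, 0.087),
}
OR_DEFAULTS = (0.66, 0.53, 0.86)
CORE_IDS = ("P1104A", "A928V", "I684S")
TAG_ID = "V362F"


@dataclass
class GeneModel:
    """One gene: concatenated-CDS length and named domain intervals
    (1-based, closed, in CDS coordinates)."""

    name: str
    cds_length: int
    start: int  # genomic bp of the CDS start on the linear locus coordinate
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)

    def genomic_pos(self, cds_pos: int) -> int:
        return self.start + cds_pos - 1

    def domain_of(self, cds_pos: int) -> str | None:
        for name, (lo, hi) in self.domains.items():
            if lo <= cds_pos <= hi:
                return name
        return None


def _default_genes() -> dict[str, GeneModel]:
    """An 11-gene locus on a linear coordinate, one kinase-domain gene."""
    genes: dict[str, GeneModel] = {}
    genes["TYK2"] = GeneModel(
        name="TYK2",
        cds_length=3564,
        start=10_460_000,
        domains={
            "FERM": (76, 1293),
            "SH2": (1348, 1587),
            "protein_kinase_1": (1765, 2625),
            "protein_kinase_2": (2689, 3528),
        },
    )
    others = ["ICAM1", "ICAM3", "ICAM4", "ICAM5", "CDC37",
              "PDE4A", "KEAP1", "S1PR5", "ANKLE1", "MRPL4"]
    pos = 10_480_000
    for i, name in enumerate(others):
        length = 900 + 120 * i
        genes[name] = GeneModel(name=name, cds_length=length, start=pos)
        pos += length + 15_000
    return genes


@dataclass
class LocusConfig:
    """Simulation settings for :func:`build_locus_model`."""

    preset: str = "results"
    causal_mafs: tuple | None = None
    causal_ors: tuple = OR_DEFAULTS
    tag_maf: float | None = 0.23
    tag_ld: float = 1.0          # fraction of causal-carrier haplotypes also carrying the tag
    n_null_common: int = 4
    null_mafs: tuple | None = None
    distinct_background: bool = True
    baseline_logit: float = float(np.log(0.2 / 0.8))


@dataclass
class LocusModel:
    """Haplotype pool, variant metadata and causal effects for one locus."""

    haplotype_pool: list[tuple[tuple[int, ...], float]]
    variant_meta: list[VariantRecord]
    causal_effects: dict[str, float]
    baseline_logit: float
    genes: dict[str, GeneModel] = field(default_factory=_default_genes)
    core_ids: tuple = CORE_IDS

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variant_meta]

    def implied_maf(self, variant_id: str) -> float:
        j = self.variant_ids.index(variant_id)
        return float(sum(f for h, f in self.haplotype_pool if h[j] == 1))

    def validate(self) -> None:
        total = sum(f for _, f in self.haplotype_pool)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype frequencies sum to {total!r}, not 1")
        for _, f in self.haplotype_pool:
            if f < -1e-15:
                raise ValueError("negative haplotype frequency")


def build_locus_model(config: LocusConfig | None = None, **overrides) -> LocusModel:
    """Construct the locus haplotype pool from requested MAFs and ORs.

    In distinct-background mode each causal variant's minor allele is
    placed on its own haplotype, so the implied per-variant MAF equals the
    carrier-haplotype frequency sum exactly and the variants are
    statistically independent signals.  The tag variant's minor allele is
    placed on a fraction ``tag_ld`` of every causal-carrier haplotype plus
    a tag-only haplotype absorbing the remaining tag frequency — the
    controllable "imperfect LD" pattern.  Null common variants enter in
    linkage equilibrium.
    """
    cfg = config or LocusConfig()
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise TypeError(f"unknown locus config field {k!r}")
        setattr(cfg, k, v)
    mafs = tuple(cfg.causal_mafs if cfg.causal_mafs is not None else MAF_PRESETS[cfg.preset])
    ors = tuple(cfg.causal_ors)[: len(mafs)]
    if len(ors) != len(mafs):
        raise ValueError("need one OR per causal MAF")
    for m in mafs:
        if not (0.0 < m <= 0.5):
            raise ValueError(f"causal MAF {m} outside (0, 0.5]")
    if cfg.distinct_background and sum(mafs) > 1.0:
        raise ValueError(
            f"infeasible: distinct-background mode requires causal MAFs to sum below 1 "
            f"(got {sum(mafs)})"
        )
    genes = _default_genes()
    main = genes["TYK2"]
    causal_cds = (3310, 2782, 2050)
    ids = list(CORE_IDS[: len(mafs)])
    meta = []
    for i, vid in enumerate(ids):
        cds = causal_cds[i] if i < len(causal_cds) else 100 + 37 * i
        meta.append(
            VariantRecord(
                variant_id=vid, chrom="19", pos=main.genomic_pos(cds), ref="C", alt="T",
                gene="TYK2", cds_pos=cds, consequence="missense",
                polyphen="probably", sift="probably", domain=main.domain_of(cds),
            )
        )
    # base pool: reference + one haplotype per causal variant
    k_causal = len(mafs)
    pool: list[list] = []
    ref = [0] * k_causal
    pool.append([tuple(ref), 1.0 - sum(mafs)])
    for i, m in enumerate(mafs):
        h = list(ref)
        h[i] = 1
        pool.append([tuple(h), m])
    if pool[0][1] < -1e-15:
        raise ValueError("infeasible: causal MAFs leave no reference haplotype mass")
    # tag variant in imperfect LD
    if cfg.tag_maf is not None:
        if not (0.0 <= cfg.tag_ld <= 1.0):
            raise ValueError("tag_ld is a haplotype fraction in [0, 1]")
        tag_on_causal = cfg.tag_ld * sum(mafs)
        tag_only = cfg.tag_maf - tag_on_causal
        if tag_only < -1e-12:
            raise ValueError(
                "infeasible: tag MAF smaller than the causal-haplotype mass it must tag "
                f"(tag_maf={cfg.tag_maf}, tagged causal mass={tag_on_causal:.4f})"
            )
        tag_only = max(tag_only, 0.0)
        new_pool = []
        for h, f in pool:
            if any(h):  # causal-carrier haplotype: split by tag_ld
                if cfg.tag_ld > 0:
                    new_pool.append([h + (1,), f * cfg.tag_ld])
                if cfg.tag_ld < 1:
                    new_pool.append([h + (0,), f * (1 - cfg.tag_ld)])
            else:
                if tag_only > 0:
                    new_pool.append([h + (1,), tag_only])
                new_pool.append([h + (0,), f - tag_only])
        if any(f < -1e-12 for _, f in new_pool):
            raise ValueError("infeasible: tag frequency exceeds the reference haplotype mass")
        pool = new_pool
        cds = 1084
        meta.append(
            VariantRecord(
                variant_id=TAG_ID, chrom="19", pos=main.genomic_pos(cds), ref="G", alt="T",
                gene="TYK2", cds_pos=cds, consequence="missense",
                polyphen="benign", sift="benign", domain=main.domain_of(cds),
            )
        )
    # null common variants in linkage equilibrium
    if cfg.n_null_common:
        nulls = tuple(
            cfg.null_mafs
            if cfg.null_mafs is not None
            else tuple(np.round(np.linspace(0.10, 0.40, cfg.n_null_common), 3))
        )
        if len(nulls) != cfg.n_null_common:
            raise ValueError("null_mafs length must match n_null_common")
        base = 10_440_000
        for i, q in enumerate(nulls):
            pool = [
                [h + (a,), f * (q if a else 1 - q)]
                for h, f in pool
                for a in (0, 1)
            ]
            meta.append(
                VariantRecord(
                    variant_id=f"nc{i + 1}", chrom="19", pos=base + 2_500 * i,
                    ref="A", alt="G", gene=None, cds_pos=None, consequence="intergenic",
                )
            )
    model = LocusModel(
        haplotype_pool=[(tuple(h), float(f)) for h, f in pool if f > 0],
        variant_meta=meta,
        causal_effects={vid: float(np.log(o)) for vid, o in zip(ids, ors)},
        baseline_logit=cfg.baseline_logit,
        genes=genes,
        core_ids=tuple(ids),
    )
    model.validate()
    for vid, m in zip(ids, mafs):
        assert abs(model.implied_maf(vid) - m) < 1e-12
    return model


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_case_control(
    model: LocusModel,
    n_case: int,
    n_control: int,
    seed: int,
    n_pcs: int = 2,
    missing_rate: float = 0.0,
    max_batches: int = 200,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw subjects to exact case/control counts by rejection sampling.

    Each subject receives two haplotypes from the pool and a Bernoulli
    disease status from the logistic model; draws continue in batches until
    both quotas are filled (a capped batch count guards against
    pathological configurations).  Covariates (age, sex, PCs) are simulated
    independent of status.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("need positive case and control counts")
    rng = np.random.default_rng(seed)
    haps = np.array([h for h, _ in model.haplotype_pool], dtype=float)
    freqs = np.array([f for _, f in model.haplotype_pool])
    freqs = freqs / freqs.sum()
    beta = np.zeros(haps.shape[1])
    for vid, b in model.causal_effects.items():
        beta[model.variant_ids.index(vid)] = b
    hap_eta = haps @ beta
    eta_max = model.baseline_logit + 2.0 * hap_eta.max()
    if _sigmoid(eta_max) >= 0.999:
        raise ValueError(
            f"pathological baseline_logit: a diplotype reaches disease probability "
            f"{_sigmoid(eta_max):.4f} >= 0.999"
        )
    need_case, need_control = n_case, n_control
    prev = _sigmoid(model.baseline_logit + 2.0 * float(hap_eta @ freqs))
    batch = max(int(1.5 * max(n_case / max(prev, 1e-3), n_control / max(1 - prev, 1e-3))), 1000)
    got_case, got_control = [], []
    for _ in range(max_batches):
        h1 = rng.choice(len(freqs), size=batch, p=freqs)
        h2 = rng.choice(len(freqs), size=batch, p=freqs)
        eta = model.baseline_logit + hap_eta[h1] + hap_eta[h2]
        y = rng.random(batch) < _sigmoid(eta)
        pairs = np.column_stack([h1, h2])
        if need_case > 0:
            take = pairs[y][:need_case]
            got_case.append(take)
            need_case -= take.shape[0]
        if need_control > 0:
            take = pairs[~y][:need_control]
            got_control.append(take)
            need_control -= take.shape[0]
        if need_case <= 0 and need_control <= 0:
            break
    else:
        raise RuntimeError(
            f"rejection sampling exhausted {max_batches} batches "
            f"(still need {need_case} cases, {need_control} controls)"
        )
    pairs = np.vstack(got_case + got_control)
    status = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    dosages = haps[pairs[:, 0]] + haps[pairs[:, 1]]
    n = n_case + n_control
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = dosages.astype(float)
        dosages[mask] = np.nan
    ids = [f"S{i:06d}" for i in range(n)]
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "status": status,
            "age": np.round(np.clip(rng.normal(58.0, 12.0, n), 18, 90), 1),
            "sex": rng.integers(0, 2, n),
            **{f"PC{k + 1}": rng.normal(0.0, 1.0, n) for k in range(n_pcs)},
            "platform": "sequencing",
        }
    )
    gm = GenotypeMatrix(dosages.astype(float), ids, [v for v in model.variant_meta])
    return gm, subjects


@dataclass
class Enrichment:
    """Placement rule concentrating damaging rare carriers in one arm."""

    gene: str = "TYK2"
    interval: tuple[int, int] | None = None   # CDS interval; None = kinase-1 domain
    group: str = "damaging"
    arm: str = "control"                      # arm receiving the excess carriers
    weight: float = 6.0                       # carrier-sampling odds toward the arm


def simulate_rare_background(
    genotypes: GenotypeMatrix,
    model: LocusModel,
    seed: int,
    n_variants: int = 7,
    singleton_fraction: float = 5.0 / 7.0,
    enrichment: Enrichment | None = None,
    subjects: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Append rare (MAF < 0.5%) missense/nonsense variants to a cohort.

    ``singleton_fraction`` of the variants are singletons (minor-allele
    count 1); the rest draw allele counts uniformly up to the 0.5% MAF
    ceiling.  With ``enrichment``, every appended variant lands in the
    stated CDS interval with damaging predictor labels and carriers are
    drawn with odds ``weight`` toward the stated arm (defaults reproduce a
    damaging-in-controls kinase-domain cluster of 7 variants with 5
    singletons).  ``n_variants=0`` returns the matrix unchanged.
    """
    if n_variants == 0:
        return genotypes
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    max_mac = max(int(np.floor(2 * n * 0.005)), 1)
    n_singletons = int(round(n_variants * singleton_fraction))
    if enrichment is not None:
        gene = model.genes.get(enrichment.gene)
        if gene is None:
            raise ValueError(f"enrichment gene {enrichment.gene!r} not in the locus model")
        interval = enrichment.interval or gene.domains.get("protein_kinase_1")
        if interval is None:
            raise ValueError("no enrichment interval given and the gene has no kinase-1 domain")
        lo, hi = interval
        if not (1 <= lo <= hi <= gene.cds_length):
            raise ValueError(
                f"enrichment interval {interval} falls outside the CDS of {gene.name} "
                f"(length {gene.cds_length})"
            )
        if subjects is None:
            raise ValueError("enrichment needs the subject table for arm placement")
        arm_is = (subjects["status"].to_numpy() == (1 if enrichment.arm == "case" else 0))
        weights = np.where(arm_is, enrichment.weight, 1.0)
        weights = weights / weights.sum()
    gene_names = list(model.genes)
    cols = np.zeros((n, n_variants))
    meta = []
    for j in range(n_variants):
        mac = 1 if j < n_singletons else int(rng.integers(2, max_mac + 1))
        if enrichment is not None:
            carriers = rng.choice(n, size=mac, replace=False, p=weights)
            gname = enrichment.gene
            cds = int(rng.integers(lo, hi + 1))
            pp, sf = "probably", "probably"
            cons = "missense"
        else:
            carriers = rng.choice(n, size=mac, replace=False)
            gname = gene_names[int(rng.integers(0, len(gene_names)))]
            cds = int(rng.integers(1, model.genes[gname].cds_length + 1))
            pp = ("benign", "possibly", "probably")[int(rng.integers(0, 3))]
            sf = ("benign", "possibly", "probably")[int(rng.integers(0, 3))]
            cons = "nonsense" if rng.random() < 0.1 else "missense"
        cols[carriers, j] = 1.0
        g = model.genes[gname]
        meta.append(
            VariantRecord(
                variant_id=f"rare_{gname}_{j + 1}", chrom="19", pos=g.genomic_pos(cds),
                ref="G", alt="A", gene=gname, cds_pos=cds, consequence=cons,
                polyphen=pp, sift=sf, domain=g.domain_of(cds),
            )
        )
    extra = GenotypeMatrix(cols, genotypes.subject_ids, meta)
    return genotypes.append_variants(extra)


DEFAULT_PLATFORM_MASKS = {
    "sequencing": {"design_maf": 0.0},
    "immunochip": {"design_maf": 0.005},
    "exomechip": {"design_maf": 0.005},
}


def apply_platform_mask(
    genotypes: GenotypeMatrix,
    platform: str,
    masks: dict | None = None,
    core_ids: tuple = CORE_IDS + (TAG_ID,),
    allow_empty: bool = False,
) -> GenotypeMatrix:
    """Restrict the variant columns to one genotyping platform's design.

    Chip designs exclude variants below their design MAF; the core
    fine-mapping variants are retained on every platform.  An unknown
    platform label raises; a mask leaving no variants raises unless
    ``allow_empty`` is set.
    """
    masks = masks or DEFAULT_PLATFORM_MASKS
    if platform not in masks:
        raise KeyError(f"unknown platform {platform!r}; configured: {sorted(masks)}")
    design_maf = masks[platform].get("design_maf", 0.0)
    maf = genotypes.maf()
    keep = [
        j
        for j, v in enumerate(genotypes.variants)
        if v.variant_id in core_ids or maf[j] >= design_maf
    ]
    explicit = masks[platform].get("variant_ids")
    if explicit is not None:
        keep = [j for j in keep if genotypes.variants[j].variant_id in explicit]
    if not keep and not allow_empty:
        raise ValueError(f"platform mask {platform!r} removes every variant")
    return genotypes.subset_variants(keep)


# ---------------------------------------------------------------------------
# EMR simulation
# ---------------------------------------------------------------------------

INFECTION_SITES = {
    "pneumonia": (["480.1", "481.0", "482.0", "486.0"], ["481.0"]),
    "sepsis": (["038.0", "038.9", "790.7"], ["038.9"]),
    "cellulitis": (["681.0", "682.0", "682.9"], ["681.0"]),
    "uti": (["590.1", "595.0", "599.0"], ["590.1"]),
    "osteomyelitis": (["730.0", "730.2"], ["730.0"]),
}


@dataclass
class EmrModel:
    """Event-generation law for a synthetic EMR cohort."""

    phenotype_prevalences: dict[str, float]
    codes: dict[str, list[str]]
    labels: dict[str, str] = field(default_factory=dict)
    inclusion_range: tuple[int, int] = (1, 779)
    event_geom_p: float = 0.40       # P(affected emits exactly 1 event)
    false_event_rate: float = 0.01   # unaffected single-event rate
    years: tuple[int, int] = (2000, 2014)
    ldl_mean: float = 130.0
    ldl_sd: float = 30.0
    ldl_year_drift: float = -1.2     # mg/dL per calendar year
    statin_prob: float = 0.25
    wbc_mean: float = 7.0
    wbc_between_sd: float = 1.6
    wbc_within_sd: float = 1.0
    wbc_extra_counts: float = 2.0    # measurements per subject = 1 + Poisson(this)
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        for g, p in self.phenotype_prevalences.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {g!r} is {p}; must lie in (0, 1)")

    @classmethod
    def default(cls, n_phenotypes: int = 60, include_infections: bool = True) -> "EmrModel":
        """Deterministic default phenome: prevalences geometrically spaced
        from 15% down to 1.5%, two ICD-style codes per phenotype, plus the
        infection site groups and a handful of out-of-range codes."""
        prev = np.geomspace(0.15, 0.015, n_phenotypes)
        prevalences, codes, labels = {}, {}, {}
        for i in range(n_phenotypes):
            g = f"P{i + 1:03d}"
            base = (i * 13) % 770 + 1
            prevalences[g] = float(prev[i])
            codes[g] = [f"{base:03d}.0", f"{base:03d}.1"]
            labels[g] = f"phenotype {i + 1}"
        if include_infections:
            inf_prev = {"pneumonia": 0.04, "sepsis": 0.02, "cellulitis": 0.03,
                        "uti": 0.05, "osteomyelitis": 0.01}
            for site, (comp, _) in INFECTION_SITES.items():
                g = f"INF_{site}"
                prevalences[g] = inf_prev[site]
                codes[g] = comp
                labels[g] = site
        # out-of-range group (ignored by the standard scan's inclusion filter)
        prevalences["XR01"] = 0.05
        codes["XR01"] = ["805.0", "805.1"]
        labels["XR01"] = "injury (out of range)"
        return cls(phenotype_prevalences=prevalences, codes=codes, labels=labels)

    def code_map(self) -> pd.DataFrame:
        rows = []
        for g, cs in self.codes.items():
            for c in cs:
                rows.append({"code": c, "phenotype": g, "label": self.labels.get(g, g)})
        return pd.DataFrame(rows)


def simulate_emr(
    model: EmrModel,
    genotypes: GenotypeMatrix,
    subjects: pd.DataFrame,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Generate coded events, LDL and WBC tables for a genotyped cohort.

    Affected subjects emit 1 + Geometric(event_geom_p) events of their
    phenotype's codes (so a fraction emits exactly one and is excluded by
    the two-event case rule); unaffected subjects emit a single
    false-positive event at ``false_event_rate``.  Planted effects tilt
    the per-subject affection logit (binary phenotypes) or enter as a
    per-allele slope (LDL / WBC).  The default model plants nothing: a
    global null.
    """
    if genotypes.n_subjects != len(subjects):
        raise ValueError("genotype matrix and subject table sizes differ")
    rng = np.random.default_rng(seed)
    n = genotypes.n_subjects
    ids = np.asarray(genotypes.subject_ids)
    y0, y1 = model.years
    dosage_of = {}
    for (vid, target), eff in model.planted_effects.items():
        if vid not in dosage_of:
            d = genotypes.column(vid).copy()
            d[np.isnan(d)] = np.nanmean(d)
            dosage_of[vid] = d
    ev_subj, ev_code, ev_year = [], [], []
    for g, prev in model.phenotype_prevalences.items():
        eta = np.full(n, np.log(prev / (1 - prev)))
        for (vid, target), eff in model.planted_effects.items():
            if target == g:
                eta = eta + eff * dosage_of[vid]
        affected = rng.random(n) < _sigmoid(eta)
        counts = np.zeros(n, dtype=int)
        counts[affected] = 1 + rng.geometric(model.event_geom_p, int(affected.sum())) - 1
        false_pos = (~affected) & (rng.random(n) < model.false_event_rate)
        counts[false_pos] = 1
        csum = counts.sum()
        if csum == 0:
            continue
        subj = np.repeat(ids, counts)
        codes = rng.choice(model.codes[g], size=csum)
        years = rng.integers(y0, y1 + 1, size=csum)
        ev_subj.append(subj)
        ev_code.append(codes)
        ev_year.append(years)
    events = pd.DataFrame(
        {
            "subject_id": np.concatenate(ev_subj) if ev_subj else [],
            "code": np.concatenate(ev_code) if ev_code else [],
            "year": np.concatenate(ev_year) if ev_year else [],
        }
    )
    # LDL: one first-measurement record per subject, optional statin date
    ldl_year = rng.integers(y0, y1 + 1, size=n)
    ldl = (
        model.ldl_mean
        + model.ldl_year_drift * (ldl_year - y0)
        + rng.normal(0.0, model.ldl_sd, n)
    )
    for (vid, target), eff in model.planted_effects.items():
        if target == "LDL":
            ldl = ldl + eff * dosage_of[vid]
    has_statin = rng.random(n) < model.statin_prob
    statin_year = np.where(
        has_statin, ldl_year + rng.integers(-5, 6, size=n), np.nan
    )
    ldl_table = pd.DataFrame(
        {
            "subject_id": ids,
            "ldl": np.round(ldl, 1),
            "year": ldl_year,
            "age_at_measure": subjects["age"].to_numpy(),
            "statin_year": statin_year,
        }
    )
    # WBC: a short series per subject around a subject-level mean
    counts = 1 + rng.poisson(model.wbc_extra_counts, n)
    base = model.wbc_mean + rng.normal(0.0, model.wbc_between_sd, n)
    for (vid, target), eff in model.planted_effects.items():
        if target == "WBC":
            base = base + eff * dosage_of[vid]
    subj = np.repeat(ids, counts)
    vals = np.repeat(base, counts) + rng.normal(0.0, model.wbc_within_sd, counts.sum())
    wbc_table = pd.DataFrame({"subject_id": subj, "wbc": np.round(vals, 2)})
    return {"events": events, "ldl": ldl_table, "wbc": wbc_table}


def make_infection_codesets() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The bundled synthetic comprehensive/restricted infection code sets
    (site -> ICD-style codes), standing in for the published expert lists."""
    comp_rows, restr_rows = [], []
    for site, (comp, restr) in INFECTION_SITES.items():
        comp_rows += [{"site": site, "code": c} for c in comp]
        restr_rows += [{"site": site, "code": c} for c in restr]
    return pd.DataFrame(comp_rows), pd.DataFrame(restr_rows)
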