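"""Variant- and sample-level quality control.

Implements the exact conditional Hardy-Weinberg test (summing the
probabilities of all heterozygote-count configurations no more likely than
the observed one, given the allele counts), the call-rate cascade
(variants first, then samples), and a method-of-moments IBD-sharing
(pi-hat) estimator from observed identity-by-state given allele
frequencies.

HWE is evaluated in controls only: computing it in cases would discard
true associations, and controls-only is the standard convention for
case-control chip QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = ["hwe_exact", "call_rate_filter", "pi_hat", "relatedness_prune", "QcReport"]

HWE_P_DEFAULT = 5.7e-7       # chip QC exclusion threshold
CALL_RATE_DEFAULT = 0.99     # variant and sample call-rate floor
PIHAT_DEFAULT = 0.125        # relatedness flag threshold


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability is <= that of
    the observed configuration.  Monomorphic sites return 1.0 by
    convention (there is nothing to test).  Mid-p is not applied.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # minor allele count
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the minor allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalised log-probabilities  P(het | allele counts) via log-gammas
    from scipy.special import gammaln

    rare_hom = (n_rare - het_values) // 2
    common_hom = n - het_values - rare_hom
    logp = (
        het_values * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(het_values + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[het_values == n_het][0]
    # numerically tolerant comparison, as configurations can tie exactly
    p = float(prob[prob <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


@dataclass
class QcReport:
    """Outcome of the QC cascade with per-record reason codes."""

    variant_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    flagged_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    genotypes: GenotypeMatrix | None = None

    @property
    def kept_variants(self) -> list[str]:
        t = self.variant_table
        return list(t.loc[t["kept"], "variant_id"])

    @property
    def kept_samples(self) -> list[str]:
        t = self.sample_table
        return list(t.loc[t["kept"], "subject_id"])


def call_rate_filter(
    genotypes: GenotypeMatrix,
    variant_min: float = CALL_RATE_DEFAULT,
    sample_min: float = CALL_RATE_DEFAULT,
    hwe_p: float | None = HWE_P_DEFAULT,
    controls: np.ndarray | None = None,
) -> QcReport:
    """Variant filters (call rate, then HWE) followed by the sample filter.

    Variants are dropped first (call rate < ``variant_min``, then HWE
    departure at p < ``hwe_p`` computed in the ``controls`` stratum when
    given, otherwise in all samples); sample call rates are then recomputed
    on the surviving variants.  Each dropped record carries exactly one
    primary reason code (the first failing check).
    """
    if not (0 <= variant_min <= 1 and 0 <= sample_min <= 1):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    d = genotypes.dosages
    vc = genotypes.variant_call_rate()
    reasons = np.array([""] * genotypes.n_variants, dtype=object)
    reasons[vc < variant_min] = "call_rate"
    if hwe_p is not None:
        stratum = d if controls is None else d[np.asarray(controls, bool)]
        hwe_pvals = np.ones(genotypes.n_variants)
        for j in range(genotypes.n_variants):
            if reasons[j]:
                continue
            col = stratum[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
            hwe_pvals[j] = hwe_exact(*counts)
        reasons[(reasons == "") & (hwe_pvals < hwe_p)] = "hwe"
    else:
        hwe_pvals = np.full(genotypes.n_variants, np.nan)
    vkeep = reasons == ""
    variant_table = pd.DataFrame(
        {
            "variant_id": genotypes.variant_ids,
            "call_rate": vc,
            "hwe_p": hwe_pvals,
            "kept": vkeep,
            "reason": reasons,
        }
    )
    kept_idx = np.where(vkeep)[0]
    g2 = genotypes.subset_variants(kept_idx) if len(kept_idx) < genotypes.n_variants else genotypes
    sc = g2.sample_call_rate() if g2.n_variants else np.ones(g2.n_subjects)
    skeep = sc >= sample_min
    sample_table = pd.DataFrame(
        {
            "subject_id": genotypes.subject_ids,
            "call_rate": sc,
            "kept": skeep,
            "reason": np.where(skeep, "", "call_rate"),
        }
    )
    if not skeep.any():
        raise ValueError("sample call-rate filter removed every subject")
    g3 = g2.subset_subjects(np.where(skeep)[0]) if not skeep.all() else g2
    return QcReport(variant_table=variant_table, sample_table=sample_table, genotypes=g3)


def pi_hat(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    allele_freqs: np.ndarray,
    min_overlap: int = 1000,
) -> float:
    """Method-of-moments IBD-sharing estimate for one sample pair.

    Uses the observed identity-by-state distribution across variants and
    the expected IBS probabilities given allele frequencies under 0/1/2
    alleles shared identical-by-descent; returns P(IBD=1)/2 + P(IBD=2),
    clipped to [0, 1].  Requires ``min_overlap`` jointly-called variants.
    """
    gi = np.asarray(genotypes_i, float)
    gj = np.asarray(genotypes_j, float)
    p = np.asarray(allele_freqs, float)
    ok = ~np.isnan(gi) & ~np.isnan(gj) & (p > 0) & (p < 1)
    m = int(ok.sum())
    if m < min_overlap:
        raise ValueError(
            f"only {m} overlapping non-missing informative variants; {min_overlap} required"
        )
    gi, gj, p = gi[ok], gj[ok], p[ok]
    q = 1.0 - p
    ibs = 2.0 - np.abs(gi - gj)
    ibs[(gi == 1) & (gj == 1)] = 2.0  # het/het shares both alleles
    # hom-ref vs hom-alt shares none; het vs hom shares one; identical shares two
    ibs[((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))] = 0.0
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    n2 = float((ibs == 2).sum())
    # expected IBS-class probabilities given IBD state (idealised, no
    # small-sample correction)
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(p**3 + q**3 + p**2 * q + p * q**2))
    p0 = n0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (n1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (n2 - p0 * e2_ibd0 - p1 * e2_ibd1) / m
    p0, p1, p2 = max(p0, 0.0), max(p1, 0.0), max(p2, 0.0)
    s = p0 + p1 + p2
    if s > 0:
        p0, p1, p2 = p0 / s, p1 / s, p2 / s
    return float(np.clip(0.5 * p1 + p2, 0.0, 1.0))


def relatedness_prune(
    genotypes: GenotypeMatrix,
    threshold: float = PIHAT_DEFAULT,
    maf_min: float = 0.05,
    min_overlap: int = 1000,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Flag related pairs (pi-hat > threshold) and pick a member to drop.

    The member with the lower call rate is dropped; ties break on the
    lexicographically larger subject id.  ``pairs=None`` scans all pairs
    (quadratic; meant for the locus-scale cohorts this package simulates).
    """
    common = np.where(genotypes.maf() >= maf_min)[0]
    sub = genotypes.subset_variants(common)
    freqs = sub.alt_freq()
    cr = genotypes.sample_call_rate()
    ids = genotypes.subject_ids
    if pairs is None:
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    rows = []
    for i, j in pairs:
        ph = pi_hat(sub.dosages[i], sub.dosages[j], freqs, min_overlap=min_overlap)
        if ph > threshold:
            if cr[i] < cr[j] or (cr[i] == cr[j] and ids[i] > ids[j]):
                drop = ids[i]
            else:
                drop = ids[j]
            rows.append({"id_i": ids[i], "id_j": ids[j], "pi_hat": ph, "drop": drop})
    return pd.DataFrame(rows, columns=["id_i", "id_j", "pi_hat", "drop"])
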