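"""Synthetic cohort generator: locus construction, sampling, EMR, masks."""

import numpy as np
import pytest

import finehap as fh
from finehap.synthetic import (
    Enrichment,
    EmrModel,
    MAF_PRESETS,
    apply_platform_mask,
    build_locus_model,
    simulate_case_control,
    simulate_emr,
    simulate_rare_background,
)


def test_default_model_implied_mafs_match_request_exactly():
    m = build_locus_model()
    for vid, maf in zip(m.core_ids, MAF_PRESETS["results"]):
        assert m.implied_maf(vid) == pytest.approx(maf, abs=1e-12)
    assert m.implied_maf("V362F") == pytest.approx(0.23, abs=1e-12)
    total = sum(f for _, f in m.haplotype_pool)
    assert total == pytest.approx(1.0, abs=1e-12)


def test_power_preset_mafs():
    m = build_locus_model(preset="power")
    assert [round(m.implied_maf(v), 4) for v in m.core_ids] == [0.034, 0.007, 0.087]


def test_distinct_background_minor_allele_on_single_haplotype():
    m = build_locus_model(n_null_common=0, tag_maf=None)
    for i, vid in enumerate(m.core_ids):
        carriers = [h for h, f in m.haplotype_pool if h[i] == 1]
        assert len(carriers) == 1


def test_single_variant_maf_half_symmetric():
    m = build_locus_model(causal_mafs=(0.5,), causal_ors=(0.8,),
                          tag_maf=None, n_null_common=0)
    assert sorted(f for _, f in m.haplotype_pool) == [0.5, 0.5]


def test_infeasible_configurations_error():
    with pytest.raises(ValueError, match="sum below 1"):
        build_locus_model(causal_mafs=(0.5, 0.4, 0.3))
    with pytest.raises(ValueError, match="outside"):
        build_locus_model(causal_mafs=(0.0,))
    with pytest.raises(ValueError, match="tag"):
        build_locus_model(tag_maf=0.05)  # smaller than the tagged causal mass
    with pytest.raises(TypeError, match="unknown"):
        build_locus_model(not_a_field=1)


def test_simulation_is_seed_deterministic():
    m = build_locus_model()
    g1, s1 = simulate_case_control(m, 300, 600, seed=77)
    g2, s2 = simulate_case_control(m, 300, 600, seed=77)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    assert s1.equals(s2)
    g3, _ = simulate_case_control(m, 300, 600, seed=78)
    assert not np.array_equal(g1.dosages, g3.dosages)


def test_simulation_exact_counts_and_status_layout():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 123, 456, seed=1)
    assert (subj["status"] == 1).sum() == 123
    assert (subj["status"] == 0).sum() == 456
    assert gm.n_subjects == 579


def test_pathological_baseline_rejected():
    m = build_locus_model()
    m.baseline_logit = 30.0
    with pytest.raises(ValueError, match="0.999"):
        simulate_case_control(m, 10, 10, seed=0)


def test_realized_maf_converges_to_model_maf():
    """|realized - model| < 3 sqrt(pq/2N) in >= 95% of seeds."""
    m = build_locus_model()
    n = 2000
    ok = total = 0
    for seed in range(30):
        gm, _ = simulate_case_control(m, n // 2, n // 2, seed=seed)
        f = gm.alt_freq()
        for vid in ("V362F", "nc1", "nc2", "nc3", "nc4"):  # null columns only
            j = gm.index_of(vid)
            p = m.implied_maf(vid)
            total += 1
            ok += abs(f[j] - p) < 3 * np.sqrt(p * (1 - p) / (2 * n))
    assert ok / total >= 0.95


def test_null_model_case_control_freqs_indistinguishable():
    """With all effects removed, per-variant case/control MAF differences
    are not significant at p < 0.001 in >= 99% of 100 replicates."""
    m = build_locus_model(causal_ors=(1.0, 1.0, 1.0))
    hits = trials = 0
    for seed in range(100):
        gm, subj = simulate_case_control(m, 400, 400, seed=seed)
        y = subj["status"].to_numpy(float)
        for vid in m.core_ids:
            r = fh.fit_logistic(y, gm.column(vid))
            trials += 1
            hits += r.p >= 0.001
    assert hits / trials >= 0.99


def test_rare_background_singletons_and_identity():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 200, 200, seed=2)
    assert simulate_rare_background(gm, m, seed=3, n_variants=0) is gm
    g2 = simulate_rare_background(gm, m, seed=3, n_variants=6, singleton_fraction=1.0)
    assert g2.n_variants == gm.n_variants + 6
    new = g2.dosages[:, gm.n_variants:]
    np.testing.assert_array_equal(new.sum(axis=0), np.ones(6))  # MAC = 1 each
    for v in g2.variants[gm.n_variants:]:
        assert v.consequence in ("missense", "nonsense")
        assert v.polyphen in ("benign", "possibly", "probably")


def test_rare_background_maf_ceiling():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 600, 600, seed=4)
    g2 = simulate_rare_background(gm, m, seed=5, n_variants=10, singleton_fraction=0.2)
    maf = g2.maf()[gm.n_variants:]
    assert (maf < 0.005 + 1e-12).all()


def test_enrichment_shifts_carriers_to_stated_arm():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 1118, 1118, seed=6)
    g2 = simulate_rare_background(
        gm, m, seed=7, n_variants=7, singleton_fraction=5 / 7,
        enrichment=Enrichment(arm="control"), subjects=subj,
    )
    new = g2.dosages[:, gm.n_variants:]
    y = subj["status"].to_numpy()
    assert new[y == 0].sum() > new[y == 1].sum()
    for v in g2.variants[gm.n_variants:]:
        assert v.domain == "protein_kinase_1"
        assert (v.polyphen, v.sift) == ("probably", "probably")


def test_enrichment_interval_validation():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 50, 50, seed=8)
    with pytest.raises(ValueError, match="outside the CDS"):
        simulate_rare_background(
            gm, m, seed=9, n_variants=2,
            enrichment=Enrichment(interval=(1, 10_000)), subjects=subj,
        )
    with pytest.raises(ValueError, match="not in the locus model"):
        simulate_rare_background(
            gm, m, seed=9, n_variants=2,
            enrichment=Enrichment(gene="NOPE"), subjects=subj,
        )


def test_platform_masks():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 500, 500, seed=10)
    g2 = simulate_rare_background(gm, m, seed=11, n_variants=5, singleton_fraction=1.0)
    seq = apply_platform_mask(g2, "sequencing")
    assert seq.variant_ids == g2.variant_ids  # identity mask
    chip = apply_platform_mask(g2, "exomechip")
    assert not any(v.startswith("rare_") for v in chip.variant_ids)  # singletons gone
    assert set(m.core_ids) <= set(chip.variant_ids)  # core always retained
    with pytest.raises(KeyError, match="unknown platform"):
        apply_platform_mask(g2, "nanopore")
    empty_mask = {"void": {"design_maf": 0.0, "variant_ids": []}}
    with pytest.raises(ValueError, match="every variant"):
        apply_platform_mask(g2, "void", masks=empty_mask, core_ids=())
    out = apply_platform_mask(g2, "void", masks=empty_mask, core_ids=(), allow_empty=True)
    assert out.n_variants == 0


def test_emr_reproducible_and_structured():
    m = build_locus_model()
    gm, subj = simulate_case_control(m, 400, 800, seed=12)
    em = EmrModel.default(10)
    e1 = simulate_emr(em, gm, subj, seed=13)
    e2 = simulate_emr(em, gm, subj, seed=13)
    for key in ("events", "ldl", "wbc"):
        assert e1[key].equals(e2[key])
    assert set(e1["events"].columns) == {"subject_id", "code", "year"}
    assert len(e1["ldl"]) == gm.n_subjects  # one first-measurement row each
    assert e1["wbc"].groupby("subject_id").size().min() >= 1


def test_emr_prevalence_validation():
    with pytest.raises(ValueError, match="prevalence"):
        EmrModel(phenotype_prevalences={"P": 1.5}, codes={"P": ["001.0"]})
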