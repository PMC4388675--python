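"""Rare-variant masks, collapsing statistics, SKAT/SKAT-O, permutations."""

import numpy as np
import pytest
from scipy.stats import chi2, norm

import finehap as fh
from finehap.containers import GenotypeMatrix, VariantRecord
from finehap.rare import (
    VariantMask,
    burden_stat,
    classify_damaging,
    domain_test,
    gene_test,
    perm_engine,
    skat_stat,
    skato_stat,
    vt_stat,
    window_scan,
    wt_stat,
    _std_score,
    _wt_weights,
)
from finehap.synthetic import Enrichment, build_locus_model, simulate_case_control, \
    simulate_rare_background


# --- damaging classification ------------------------------------------------

@pytest.mark.parametrize(
    "pp,sf,expected",
    [
        ("benign", "benign", "benign"),
        ("benign", "possibly", "benign"),
        ("benign", "probably", "benign"),
        ("probably", "benign", "benign"),
        ("possibly", "possibly", "potentially_damaging"),
        ("possibly", "probably", "potentially_damaging"),
        ("probably", "possibly", "potentially_damaging"),
        ("probably", "probably", "potentially_damaging"),
    ],
)
def test_classify_damaging_four_rule_table(pp, sf, expected):
    assert classify_damaging(pp, sf) == expected


def test_classify_damaging_rejects_unknown_label():
    with pytest.raises(ValueError, match="deleterious"):
        classify_damaging("benign", "deleterious")


# --- masks ------------------------------------------------------------------

def _annotated_matrix(rng, n=200, m=12):
    d = rng.binomial(1, 0.003, size=(n, m)).astype(float)
    cons = ["missense"] * (m - 2) + ["synonymous", "nonsense"]
    meta = [
        VariantRecord(
            variant_id=f"v{j}", gene="TYK2", cds_pos=50 * (j + 1),
            consequence=cons[j],
            polyphen=("benign", "probably")[j % 2], sift="probably",
        )
        for j in range(m)
    ]
    return GenotypeMatrix(d, [f"S{i}" for i in range(n)], meta)


def test_mask_idempotent_and_monotone(rng):
    gm = _annotated_matrix(rng)
    m1 = VariantMask(maf_max=0.005)
    ids = m1.apply(gm)
    assert m1.apply(gm.subset_variants(ids)) == ids  # idempotent
    wider = VariantMask(maf_max=0.05).apply(gm)
    assert set(ids) <= set(wider)  # raising the ceiling never removes variants


def test_mask_damaging_and_consequence_rules(rng):
    gm = _annotated_matrix(rng)
    ids = VariantMask(maf_max=0.05, damaging_only=True).apply(gm)
    for vid in ids:
        v = gm.variants[gm.index_of(vid)]
        assert classify_damaging(v.polyphen, v.sift) == "potentially_damaging"
    assert "v10" not in VariantMask(maf_max=0.05).apply(gm)  # synonymous excluded


# --- collapsing statistics ---------------------------------------------------

def test_burden_single_variant_is_trend_statistic(rng):
    n = 200
    g = rng.binomial(1, 0.05, n).astype(float)
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    z = burden_stat(g[:, None], y, arm="case")
    # Armitage trend z computed from first principles
    ybar = y.mean()
    cc = g - g.mean()
    z_oracle = (y - ybar) @ cc / np.sqrt(ybar * (1 - ybar) * (cc @ cc))
    assert z == pytest.approx(z_oracle, abs=1e-12)


def test_vt_single_threshold_equals_burden(rng):
    n = 150
    G = rng.binomial(1, 0.02, size=(n, 4)).astype(float)
    # force one shared MAF by construction: same carrier count per column
    G = np.zeros((n, 4))
    for j in range(4):
        G[rng.choice(n, 3, replace=False), j] = 1.0
    y = np.r_[np.ones(75), np.zeros(75)]
    assert vt_stat(G, y, arm="case") == pytest.approx(burden_stat(G, y, arm="case"), abs=1e-12)


def test_hand_fixture_six_subjects():
    """Spreadsheet-style manual computation on an enumerated 6x3 fixture."""
    G = np.array(
        [
            [1, 0, 0],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 0],
            [0, 0, 1],
            [0, 0, 0],
        ],
        dtype=float,
    )
    y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
    # burden: counts c = (1,1,2,0,1,0); ybar=.5; sum (y-.5)c = .5*(1+1+2) - .5*(1) = 1.5
    # var = .25 * sum (c - 5/6)^2 = .25 * (1/36*2 + 49/36 + 25/36*2 + 1/36*... )
    c = G.sum(axis=1)
    manual = (y - 0.5) @ (c - c.mean()) / np.sqrt(0.25 * ((c - c.mean()) ** 2).sum())
    assert burden_stat(G, y, "case") == pytest.approx(manual, abs=1e-12)
    # frequency-weighted: control-based +1 pseudo-count frequencies
    m_ctrl = G[3:].sum(axis=0)  # (0, 0, 1)
    q = (m_ctrl + 1) / (2 * 3 + 2)
    w = 1 / np.sqrt(6 * q * (1 - q))
    cw = G @ w
    manual_wt = (y - 0.5) @ (cw - cw.mean()) / np.sqrt(0.25 * ((cw - cw.mean()) ** 2).sum())
    assert wt_stat(G, y, "case") == pytest.approx(manual_wt, abs=1e-12)
    assert wt_stat(G, y, "control") == pytest.approx(-manual_wt, abs=1e-12)


def test_statistics_invariant_under_subject_reordering(rng):
    n = 120
    G = rng.binomial(1, 0.03, size=(n, 5)).astype(float)
    y = rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)])
    perm = rng.permutation(n)
    for stat in (burden_stat, wt_stat, vt_stat):
        assert stat(G, y, "case") == pytest.approx(stat(G[perm], y[perm], "case"), abs=1e-12)
    q1, p1 = skat_stat(G, y)
    q2, p2 = skat_stat(G[perm], y[perm])
    assert q1 == pytest.approx(q2, abs=1e-9) and p1 == pytest.approx(p2, abs=1e-9)


# --- SKAT / SKAT-O -----------------------------------------------------------

def test_skat_single_variant_equals_score_test(rng):
    n = 400
    g = rng.binomial(2, 0.1, n).astype(float)
    y = rng.permutation(np.r_[np.ones(150), np.zeros(250)])
    _, p = skat_stat(g[:, None], y)
    ybar = y.mean()
    U = g @ (y - ybar)
    V = ybar * (1 - ybar) * ((g - g.mean()) ** 2).sum()
    p_oracle = chi2.sf(U**2 / V, 1)
    assert p == pytest.approx(p_oracle, rel=1e-6)


def test_skato_endpoints_and_single_variant(rng):
    n = 300
    G = rng.binomial(1, 0.04, size=(n, 6)).astype(float)
    y = rng.permutation(np.r_[np.ones(120), np.zeros(180)])
    T, p_comb, p_rho = skato_stat(G, y)
    # rho=0 endpoint is the plain SKAT p
    _, p_skat = skat_stat(G, y)
    assert p_rho[0.0] == pytest.approx(p_skat, rel=1e-9)
    # rho=1 endpoint is the squared weighted burden referred to chi2_1
    assert 0 < p_rho[1.0] <= 1
    assert T == min(p_rho.values())
    assert T <= p_comb <= min(1.0, T * len(p_rho) + 1e-12)
    # single variant: burden and SKAT coincide, combined p collapses to T
    g1 = G[:, :1]
    T1, p1, _ = skato_stat(g1, y)
    _, ps1 = skat_stat(g1, y)
    assert p1 == pytest.approx(ps1, rel=1e-9)


def test_skat_degenerate_kernel_raises(rng):
    G = np.zeros((50, 2))
    G[0, 0] = 1
    y = np.r_[np.ones(25), np.zeros(25)]
    with pytest.raises(ValueError, match="degenerate"):
        skat_stat(G, y, weights=np.zeros(2))


# --- permutation engine -------------------------------------------------------

def test_perm_constant_statistic_p_one():
    y = np.r_[np.ones(3), np.zeros(3)]
    _, p, B = perm_engine(lambda yy: 1.0, y, B=99, seed=0)
    assert p == 1.0


def test_perm_exhaustive_matches_enumeration_oracle():
    from itertools import combinations

    y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
    c = np.array([2.0, 0.0, 1.0, 1.0, 0.0, 0.0])
    stat = lambda yy: float(yy @ c)
    obs, p, B = perm_engine(stat, y, exhaustive=True)
    # direct enumeration, independent of the engine
    vals = []
    for cases in combinations(range(6), 3):
        yy = np.zeros(6)
        yy[list(cases)] = 1
        vals.append(yy @ c)
    r = sum(v >= obs - 1e-12 for v in vals)
    assert B == 20
    assert p == pytest.approx((r + 1) / (B + 1), abs=1e-15)


def test_perm_p_bounded_below_and_seed_reproducible(rng):
    n = 40
    y = rng.permutation(np.r_[np.ones(20), np.zeros(20)])
    c = np.zeros(n)
    c[np.where(y == 1)[0][:5]] = 1.0  # extreme statistic
    stat = lambda yy: float(yy @ c)
    _, p1, B = perm_engine(stat, y, B=200, seed=5)
    _, p2, _ = perm_engine(stat, y, B=200, seed=5)
    assert p1 == p2
    assert p1 >= 1.0 / (B + 1)


# --- set-level drivers --------------------------------------------------------

@pytest.fixture(scope="module")
def enriched_cohort():
    model = build_locus_model()
    gm, subjects = simulate_case_control(model, 1118, 1118, seed=42)
    gm = simulate_rare_background(
        gm, model, seed=43, n_variants=7, singleton_fraction=5 / 7,
        enrichment=Enrichment(), subjects=subjects,
    )
    gm = simulate_rare_background(gm, model, seed=44, n_variants=15,
                                  singleton_fraction=0.4)
    return model, gm, subjects


def test_gene_test_structure_and_bonferroni(enriched_cohort):
    model, gm, subjects = enriched_cohort
    y = subjects["status"].to_numpy(float)
    res = gene_test(gm, y, "TYK2", B=200, seed=1, n_genes_tested=11)
    methods = {(r.method, r.arm) for r in res}
    assert ("burden", "case") in methods and ("burden", "control") in methods
    assert ("skato", "two_sided") in methods
    for r in res:
        if r.p_empirical is not None:
            assert 1 / (r.n_perm + 1) <= r.p_empirical <= 1
        assert "0.00454" in r.note or "bonferroni" in r.note


def test_gene_test_unknown_gene_raises(enriched_cohort):
    model, gm, subjects = enriched_cohort
    with pytest.raises(KeyError, match="absent"):
        gene_test(gm, subjects["status"].to_numpy(float), "NOSUCH", B=10)


def test_empty_masked_set_reported_not_tested(enriched_cohort):
    model, gm, subjects = enriched_cohort
    y = subjects["status"].to_numpy(float)
    res = gene_test(gm, y, "TYK2", mask=VariantMask(maf_max=1e-12), B=50)
    assert all(r.note.startswith("no qualifying variants") for r in res)
    assert all(r.p_empirical is None for r in res)


def test_control_enrichment_favours_control_arm(enriched_cohort):
    """Planted control-side damaging excess: control-arm one-sided tests
    give smaller empirical p than case-arm."""
    model, gm, subjects = enriched_cohort
    y = subjects["status"].to_numpy(float)
    dom = model.genes["TYK2"].domains["protein_kinase_1"]
    res = domain_test(gm, y, "TYK2", dom, mask=VariantMask(damaging_only=True),
                      B=500, seed=9)
    by = {(r.method, r.arm): r.p_empirical for r in res}
    for method in ("burden", "wt", "vt"):
        assert by[(method, "control")] < by[(method, "case")]


def test_window_membership_geometry(rng):
    """A variant at CDS position x joins exactly the windows centred on
    [x-250, x+250], i.e. width+1 positions (inside the gene)."""
    n = 400
    d = np.zeros((n, 1))
    d[:3, 0] = 1.0  # MAF 3/800 < 0.5%: passes the rare mask
    gm = GenotypeMatrix(
        d, [f"S{i}" for i in range(n)],
        [VariantRecord(variant_id="v0", gene="G1", cds_pos=500, consequence="missense")],
    )
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    track = window_scan(gm, y, "G1", cds_length=1000, window_bp=500, B=20, seed=0)
    covered = track.loc[track["n_variants"] > 0, "cds_pos"]
    assert covered.min() == 250 and covered.max() == 750
    assert len(covered) == 501
    assert (track.loc[track["n_variants"] == 0, "note"] == "empty").all()


def test_window_scan_rejects_odd_width(enriched_cohort):
    model, gm, subjects = enriched_cohort
    with pytest.raises(ValueError, match="even"):
        window_scan(gm, subjects["status"].to_numpy(float), "TYK2",
                    cds_length=100, window_bp=501)


def test_power_ordering_burden_vs_skat(rng):
    """Same-direction effects favour the one-sided burden; opposite-direction
    effects favour the variance-component test (200 replicates each)."""
    n, m = 400, 8
    reps = 200

    def rates(signs):
        rej_burden = rej_skat = 0
        for _ in range(reps):
            G = rng.binomial(1, 0.02, size=(n, m)).astype(float)
            eta = -0.2 + G @ (signs * 1.1)
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() in (0, n):
                continue
            z = burden_stat(G, y, arm="case")
            rej_burden += norm.sf(z) < 0.05
            _, p = skat_stat(G, y)
            rej_skat += p < 0.05
        return rej_burden / reps, rej_skat / reps

    b_same, s_same = rates(np.ones(m))
    b_mixed, s_mixed = rates(np.r_[np.ones(m // 2), -np.ones(m // 2)])
    assert b_same > s_same
    assert s_mixed > b_mixed
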