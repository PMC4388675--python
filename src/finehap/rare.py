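"""Rare-variant masks and collapsing tests with permutation nulls.

Four set-level tests are provided at gene, domain, and sliding-window
granularity:

* ``burden`` — standardized score of the per-subject minor-allele count
  (one-sided; reduces to the Armitage trend statistic for a single variant);
* ``wt`` — the frequency-weighted variant of the burden, with
  1/sqrt(n * q_j (1 - q_j)) weights from the control-based allele-frequency
  estimate under the +1 pseudo-count convention;
* ``vt`` — variable threshold: the maximum standardized burden statistic
  over all distinct observed MAF thresholds;
* ``skat`` / ``skato`` — the variance-component score test (weighted
  quadratic form of the null-model score residuals) with an analytic
  p-value for the chi-square mixture by a Lugannani-Rice saddlepoint
  approximation (moment matching as fallback near the mixture mean,
  where the saddlepoint degenerates and moment matching is accurate),
  and the optimal burden/variance-component mixture over the canonical
  8-point rho grid.

One-sided tests are run per "arm" (accumulation in cases or in controls);
empirical p-values come from case-control label permutation as
(r + 1) / (B + 1), so they are never zero and are bounded below by
1/(B+1).  Covariates stay attached to subjects: only the response is
permuted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, ncx2
from scipy.integrate import quad

from .assoc import logistic_irls
from .containers import GenotypeMatrix, RareSetResult

__all__ = [
    "classify_damaging",
    "VariantMask",
    "burden_stat",
    "wt_stat",
    "vt_stat",
    "skat_stat",
    "skato_stat",
    "perm_engine",
    "gene_test",
    "domain_test",
    "window_scan",
    "SkatNull",
]

MAF_CEILING_DEFAULT = 0.005
B_GENE_DEFAULT = 10_000     # gene/domain-test permutations
B_WINDOW_DEFAULT = 1_000    # sliding-window permutations (override to 10,000 available)
RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

_PREDICTOR_VOCAB = {"benign", "possibly", "probably"}


def classify_damaging(polyphen_label: str, sift_label: str) -> str:
    """Two-predictor damaging classification.

    The four-rule grouping: benign under both predictors, or benign under
    one and possibly/probably damaging under the other, counts as benign;
    possibly damaging under both (or possibly under one and probably under
    the other), or probably damaging under both, counts as potentially
    damaging.  Net effect: any 'benign' call wins.
    """
    for lab in (polyphen_label, sift_label):
        if lab not in _PREDICTOR_VOCAB:
            raise ValueError(
                f"unknown predictor label {lab!r}; expected one of {sorted(_PREDICTOR_VOCAB)}"
            )
    if "benign" in (polyphen_label, sift_label):
        return "benign"
    return "potentially_damaging"


@dataclass(frozen=True)
class VariantMask:
    """Rare-variant qualifying-set definition (idempotent by construction)."""

    maf_max: float = MAF_CEILING_DEFAULT
    consequences: frozenset = frozenset({"missense", "nonsense"})
    damaging_only: bool = False
    exclude: frozenset = frozenset()

    def apply(self, genotypes: GenotypeMatrix) -> list[str]:
        """Variant ids passing the mask; MAF from the combined sample."""
        maf = genotypes.maf()
        keep = []
        for j, v in enumerate(genotypes.variants):
            if v.variant_id in self.exclude:
                continue
            if v.consequence not in self.consequences:
                continue
            if maf[j] >= self.maf_max or maf[j] == 0:
                continue
            if self.damaging_only:
                if v.polyphen is None or v.sift is None:
                    continue
                if classify_damaging(v.polyphen, v.sift) != "potentially_damaging":
                    continue
            keep.append(v.variant_id)
        return keep


# ---------------------------------------------------------------------------
# one-sided collapsing statistics
# ---------------------------------------------------------------------------

def _clean(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    return np.nan_to_num(G, nan=0.0)  # missing rare calls count as reference


def _std_score(y: np.ndarray, c: np.ndarray) -> float:
    """Standardized (trend-type) score of a collapsed count vector."""
    ybar = y.mean()
    cc = c - c.mean()
    denom = ybar * (1.0 - ybar) * float(cc @ cc)
    if denom <= 0:
        return 0.0
    return float((y - ybar) @ cc / np.sqrt(denom))


def burden_stat(G: np.ndarray, y: np.ndarray, arm: str = "case") -> float:
    """Unweighted burden: standardized score of the per-subject allele count."""
    c = _clean(G).sum(axis=1)
    z = _std_score(np.asarray(y, float), c)
    return z if arm == "case" else -z


def _wt_weights(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Frequency weights from the control-based +1 pseudo-count estimate."""
    ctrl = np.asarray(y, float) == 0
    n_ctrl = int(ctrl.sum())
    m = G[ctrl].sum(axis=0)
    q = (m + 1.0) / (2.0 * n_ctrl + 2.0)
    n = G.shape[0]
    return 1.0 / np.sqrt(n * q * (1.0 - q))


def wt_stat(G: np.ndarray, y: np.ndarray, arm: str = "case") -> float:
    """Frequency-weighted burden (rarer variants up-weighted)."""
    G = _clean(G)
    y = np.asarray(y, float)
    w = _wt_weights(G, y)
    c = G @ w
    z = _std_score(y, c)
    return z if arm == "case" else -z


def vt_stat(G: np.ndarray, y: np.ndarray, arm: str = "case") -> float:
    """Variable-threshold: max standardized burden over observed MAF cut-offs."""
    G = _clean(G)
    y = np.asarray(y, float)
    f = G.mean(axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    best = -np.inf
    for t in np.unique(maf):
        c = G[:, maf <= t].sum(axis=1)
        z = _std_score(y, c)
        z = z if arm == "case" else -z
        best = max(best, z)
    return float(best)


# ---------------------------------------------------------------------------
# SKAT / SKAT-O
# ---------------------------------------------------------------------------

def beta_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(1, 25)-density variant weights (canonical SKAT default)."""
    from scipy.stats import beta as beta_dist

    return beta_dist.pdf(np.clip(maf, 1e-12, 1 - 1e-12), a, b)


class SkatNull:
    """Covariate-adjusted logistic null model fitted once per variant set."""

    def __init__(self, y: np.ndarray, covariates: np.ndarray | None = None):
        y = np.asarray(y, dtype=float)
        n = y.size
        if covariates is not None:
            C = np.asarray(covariates, float)
            if C.ndim == 1:
                C = C[:, None]
            X = np.column_stack([np.ones(n), C])
        else:
            X = np.ones((n, 1))
        beta, _, _, *_ = logistic_irls(y, X)
        eta = X @ beta
        self.mu = 1.0 / (1.0 + np.exp(-eta))
        self.v = self.mu * (1.0 - self.mu)
        self.X = X
        self.y = y
        self.resid = y - self.mu

    def projected_gram(self, Z: np.ndarray) -> np.ndarray:
        """Z' P0 Z with P0 = V - V X (X'VX)^-1 X'V (m x m)."""
        VX = self.X * self.v[:, None]
        XtVX = self.X.T @ VX
        ZtVZ = (Z * self.v[:, None]).T @ Z
        ZtVX = Z.T @ VX
        return ZtVZ - ZtVX @ np.linalg.solve(XtVX, ZtVX.T)


def _liu_params(lam: np.ndarray):
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        l = a**2 - 2.0 * d
    else:
        l = 1.0 / s2
        a = np.sqrt(l)
        d = 0.0
    return c1, np.sqrt(2.0 * c2), l, d, a


def liu_sf(q: float, lam: np.ndarray, mu_adj: float | None = None, sd_adj: float | None = None) -> float:
    """P(sum lam_k chi2_1 >= q) by four-moment (Liu-type) matching.

    ``mu_adj``/``sd_adj`` optionally recentre the statistic (used by the
    SKAT-O integration, where the mixture variance carries an extra
    cross-term).
    """
    lam = np.asarray(lam, float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    muQ, sigQ, l, d, a = _liu_params(lam)
    mu0 = muQ if mu_adj is None else mu_adj
    sig0 = sigQ if sd_adj is None else sd_adj
    t = (q - mu0) / sig0
    q_norm = t * np.sqrt(2.0 * l + 4.0 * d) + l + d
    if q_norm <= 0:
        return 1.0
    if d > 0:
        return float(ncx2.sf(q_norm, l, d))
    return float(chi2.sf(q_norm, l))


def saddlepoint_sf(q: float, lam: np.ndarray) -> float | None:
    """Lugannani-Rice saddlepoint survival for sum lam_k chi2_1.

    Accurate in both tails for skewed eigenvalue spectra, where pure
    moment matching degrades.  Returns None very close to the mean (the
    saddlepoint degenerates there; the caller falls back to moment
    matching, which is accurate in the body).
    """
    lam = np.asarray(lam, float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    mean = lam.sum()
    if abs(q - mean) < 1e-8 * mean:
        return None
    lmax = lam.max()

    def kprime(s):
        return float(np.sum(lam / (1.0 - 2.0 * s * lam)))

    # solve K'(s) = q on (-inf, 1/(2 lmax))
    from scipy.optimize import brentq

    hi = 1.0 / (2.0 * lmax) - 1e-12
    lo = -1e4 / mean
    while kprime(lo) > q:
        lo *= 8.0
        if lo < -1e12:
            return 1.0
    f = lambda s: kprime(s) - q
    if f(hi) < 0:  # q beyond numerical range of the upper branch
        return 0.0
    try:
        s_hat = brentq(f, lo, hi, xtol=1e-14, maxiter=200)
    except ValueError:
        return None
    if abs(s_hat) < 1e-10:
        return None
    K = -0.5 * float(np.sum(np.log1p(-2.0 * s_hat * lam)))
    K2 = 2.0 * float(np.sum(lam**2 / (1.0 - 2.0 * s_hat * lam) ** 2))
    w = np.sign(s_hat) * np.sqrt(max(2.0 * (s_hat * q - K), 0.0))
    v = s_hat * np.sqrt(K2)
    if w == 0.0 or v == 0.0:
        return None
    from scipy.stats import norm as _norm

    return float(np.clip(_norm.sf(w + np.log(v / w) / w), 0.0, 1.0))


def mixture_sf(q: float, lam: np.ndarray) -> float:
    """Survival of the chi-square mixture: saddlepoint with a moment-matched
    fallback in the immediate neighbourhood of the mean.  Equal eigenvalues
    collapse to an exact scaled chi-square."""
    lam = np.asarray(lam, float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12):
        return float(chi2.sf(q / lam[0], df=lam.size))
    p = saddlepoint_sf(q, lam)
    if p is None:
        p = liu_sf(q, lam)
    return p


def _mixture_isf(p: float, lam: np.ndarray) -> float:
    """Upper-tail quantile of the mixture (inverse of mixture_sf)."""
    lam = np.asarray(lam, float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 0.0
    from scipy.optimize import brentq

    start = _liu_isf(p, lam)
    lo, hi = max(start, 1e-12), max(start, 1e-12)
    while mixture_sf(hi, lam) > p:
        hi *= 2.0
        if hi > 1e12 * lam.sum():
            return hi
    while mixture_sf(lo, lam) < p and lo > 1e-300:
        lo /= 2.0
    try:
        return float(brentq(lambda q: mixture_sf(q, lam) - p, lo, hi, xtol=1e-10, maxiter=200))
    except ValueError:
        return start


def _liu_isf(p: float, lam: np.ndarray) -> float:
    """Inverse of liu_sf in q (upper-tail quantile of the mixture)."""
    lam = np.asarray(lam, float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 0.0
    muQ, sigQ, l, d, a = _liu_params(lam)
    if d > 0:
        q_norm = ncx2.isf(p, l, d)
    else:
        q_norm = chi2.isf(p, l)
    return float((q_norm - l - d) / np.sqrt(2.0 * l + 4.0 * d) * sigQ + muQ)


def skat_stat(
    G: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    null: SkatNull | None = None,
):
    """SKAT statistic Q and its analytic p-value.

    Q = sum_j w_j^2 (g_j' (y - mu))^2 with Beta(1,25) weights by default;
    the null distribution is the usual mixture of chi-squares with weights
    from the eigenvalues of W^1/2 G' P0 G W^1/2, approximated by moment
    matching.
    """
    G = _clean(G)
    if null is None:
        null = SkatNull(y, covariates)
    if weights is None:
        f = G.mean(axis=0) / 2.0
        weights = beta_weights(np.minimum(f, 1 - f))
    w = np.asarray(weights, float)
    if np.all(w == 0):
        raise ValueError("degenerate kernel: all variant weights are zero")
    Z = G * w[None, :]
    s = Z.T @ null.resid
    Q = float(s @ s)
    A = null.projected_gram(Z)
    lam = np.linalg.eigvalsh(A)
    p = mixture_sf(Q, lam)
    return Q, min(max(p, np.finfo(float).tiny), 1.0)


def _skato_prep(G: np.ndarray, null: SkatNull, weights: np.ndarray | None):
    G = _clean(G)
    if weights is None:
        f = G.mean(axis=0) / 2.0
        weights = beta_weights(np.minimum(f, 1 - f))
    w = np.asarray(weights, float)
    if np.all(w == 0):
        raise ValueError("degenerate kernel: all variant weights are zero")
    Z = G * w[None, :]
    return Z


def _rho_lambdas(A: np.ndarray, rho: float) -> np.ndarray:
    """Eigenvalues of the rho-mixture kernel L' A L, R_rho = L L'."""
    m = A.shape[0]
    R = (1.0 - rho) * np.eye(m) + rho * np.ones((m, m))
    # symmetric square root of R
    ev, U = np.linalg.eigh(R)
    L = U @ np.diag(np.sqrt(np.maximum(ev, 0.0))) @ U.T
    return np.linalg.eigvalsh(L @ A @ L)


def skato_stat(
    G: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    null: SkatNull | None = None,
    rho_grid: tuple = RHO_GRID,
):
    """SKAT-O: optimal mixture of burden and SKAT over the rho grid.

    Returns ``(min_p, p_combined, per_rho_p)``.  For each rho,
    Q_rho = (1 - rho) Q_skat + rho Q_burden is referred to its own
    chi-square-mixture null; the combined p-value accounts for the
    minimisation over the grid by the standard one-dimensional integration
    over the shared burden component.
    """
    if null is None:
        null = SkatNull(y, covariates)
    Z = _skato_prep(G, null, weights)
    m = Z.shape[1]
    s = Z.T @ null.resid
    Q_skat = float(s @ s)
    Q_burden = float(s.sum() ** 2)
    A = null.projected_gram(Z)
    p_rho = {}
    q_rho = {}
    for rho in rho_grid:
        q = (1.0 - rho) * Q_skat + rho * Q_burden
        lam = _rho_lambdas(A, rho)
        p_rho[rho] = mixture_sf(q, lam)
        q_rho[rho] = q
    T = min(p_rho.values())
    if m == 1:
        return T, min(max(T, np.finfo(float).tiny), 1.0), p_rho
    # decomposition into the shared burden direction and its orthogonal part
    one = np.ones(m)
    zbar_sq = float(one @ A @ one) / m**2          # ||P0^1/2 Z 1/m||^2
    if zbar_sq <= 1e-14:
        return T, min(max(T * len(rho_grid), np.finfo(float).tiny), 1.0), p_rho
    c = A @ one / m                                 # Z' P0 (Z 1/m)
    cof1 = c / zbar_sq
    A_orth = A - np.outer(c, c) / zbar_sq
    lam = np.linalg.eigvalsh(A_orth)
    lam = lam[lam > 1e-12]
    mu_k = float(lam.sum())
    var_k = 2.0 * float((lam**2).sum())
    var_cross = 4.0 * zbar_sq * float(cof1 @ A_orth @ cof1)
    sd_k = np.sqrt(var_k + var_cross)
    sd_lam = np.sqrt(var_k) if var_k > 0 else 1.0
    tau = {
        rho: m**2 * rho * zbar_sq + (1.0 - rho) * zbar_sq * float(cof1 @ cof1)
        for rho in rho_grid
    }
    qmin = {rho: _mixture_isf(max(T, 1e-300), _rho_lambdas(A, rho)) for rho in rho_grid}

    def integrand(x: float) -> float:
        vals = []
        for rho in rho_grid:
            if rho > 0.999:
                continue
            vals.append((qmin[rho] - tau[rho] * x) / (1.0 - rho))
        v = min(vals)
        if lam.size == 0:
            surv = 0.0 if v > 0 else 1.0
        else:
            # variance-adjusted standardisation: the kappa component carries
            # a burden/orthogonal cross-term in its variance
            tstd = (v - mu_k) / sd_k
            surv = mixture_sf(tstd * sd_lam + mu_k, lam)
        return (1.0 - surv) * chi2.pdf(x, 1)

    import warnings as _warnings

    with _warnings.catch_warnings():
        # roundoff reports from quad are harmless here: the integrand is
        # smooth and bounded in [0, 1] and the p-value is clipped below
        from scipy.integrate import IntegrationWarning

        _warnings.simplefilter("ignore", IntegrationWarning)
        integral, _ = quad(integrand, 0.0, chi2.isf(1e-12, 1), limit=200)
    p_comb = 1.0 - integral
    # the minimum over the grid bounds the combined p on both sides
    p_comb = min(max(p_comb, T), T * len(rho_grid), 1.0)
    return T, float(max(p_comb, np.finfo(float).tiny)), p_rho


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def perm_engine(
    stat_fn,
    response: np.ndarray,
    B: int = B_GENE_DEFAULT,
    seed: int = 0,
    exhaustive: bool = False,
    stat_fn_matrix=None,
) -> tuple[float, float, int]:
    """Empirical p-value by case-control label permutation.

    ``stat_fn(y) -> float`` evaluates the statistic for a label vector;
    larger values are more extreme (orient one-sided statistics before
    calling).  Covariates, being attached to subjects, are untouched.
    Returns ``(observed, p, B)`` with p = (r + 1)/(B + 1),
    r = #{permuted >= observed}.  ``exhaustive=True`` enumerates every
    distinct assignment of the case labels instead of sampling.
    ``stat_fn_matrix(Y) -> (B,)`` may be supplied to evaluate a whole
    (B x n) block of permuted label vectors at once.
    """
    y = np.asarray(response, dtype=float)
    obs = float(stat_fn(y))
    n = y.size
    k = int(y.sum())
    if exhaustive:
        perms = []
        for cases in combinations(range(n), k):
            yp = np.zeros(n)
            yp[list(cases)] = 1.0
            perms.append(yp)
        Y = np.array(perms)
        B = Y.shape[0]
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((B, n)), axis=1)
        Y = y[order]
    if stat_fn_matrix is not None:
        stats = np.asarray(stat_fn_matrix(Y), dtype=float)
    else:
        stats = np.array([stat_fn(Y[b]) for b in range(Y.shape[0])])
    r = int(np.sum(stats >= obs - 1e-12))
    p = (r + 1.0) / (B + 1.0)
    return obs, p, B


def _vt_matrix_fn(G: np.ndarray, arm: str):
    """Vectorized VT evaluator: thresholds depend only on MAFs, which are
    invariant under label permutation, so the per-threshold count vectors
    are precomputed once."""
    f = G.mean(axis=0) / 2.0
    maf = np.minimum(f, 1 - f)
    C = np.column_stack([G[:, maf <= t].sum(axis=1) for t in np.unique(maf)])
    Cc = C - C.mean(axis=0)
    css = (Cc**2).sum(axis=0)

    def fn(Y: np.ndarray) -> np.ndarray:
        ybar = Y.mean(axis=1)
        denom = ybar[:, None] * (1 - ybar[:, None]) * css[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (Y - ybar[:, None]) @ Cc / np.sqrt(denom)
        Z = np.nan_to_num(Z, nan=0.0)
        if arm == "control":
            Z = -Z
        return Z.max(axis=1)

    return fn


def _wt_perm_matrix_fn(G: np.ndarray, arm: str):
    """Vectorized WT evaluator recomputing the control-based frequency
    weights inside every permutation: the weights are a function of the
    labels, so keeping the observed-label weights would misalign the
    observed statistic with its permutation null (anticonservative)."""
    n, m = G.shape
    GtG = G.T @ G
    colsum = G.sum(axis=0)

    def fn(Y: np.ndarray) -> np.ndarray:
        n_ctrl = (1.0 - Y).sum(axis=1)  # constant across label permutations
        m_ctrl = (1.0 - Y) @ G          # (B, m) control minor-allele counts
        q = (m_ctrl + 1.0) / (2.0 * n_ctrl[:, None] + 2.0)
        W = 1.0 / np.sqrt(n * q * (1.0 - q))
        ybar = Y.mean(axis=1)
        U = (Y - ybar[:, None]) @ G     # (B, m) centred scores per variant
        s = (U * W).sum(axis=1)
        cbar = (W * colsum[None, :]).sum(axis=1) / n
        css = np.einsum("bi,ij,bj->b", W, GtG, W) - n * cbar**2
        denom = ybar * (1 - ybar) * css
        with np.errstate(invalid="ignore", divide="ignore"):
            z = s / np.sqrt(denom)
        z = np.nan_to_num(z, nan=0.0)
        return z if arm == "case" else -z

    return fn


def _collapse_matrix_fn(c: np.ndarray, arm: str):
    """Vectorized standardized-score evaluator for one collapsed count vector."""
    cc = c - c.mean()
    css = float(cc @ cc)

    def fn(Y: np.ndarray) -> np.ndarray:
        ybar = Y.mean(axis=1)
        denom = ybar * (1 - ybar) * css
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (Y - ybar[:, None]) @ cc / np.sqrt(denom)
        z = np.nan_to_num(z, nan=0.0)
        return z if arm == "case" else -z

    return fn


# ---------------------------------------------------------------------------
# set-level drivers
# ---------------------------------------------------------------------------

_ONE_SIDED = ("burden", "wt", "vt")
_STAT_FNS = {"burden": burden_stat, "wt": wt_stat, "vt": vt_stat}


def _run_set(
    set_id: str,
    G: np.ndarray,
    variant_ids: list[str],
    y: np.ndarray,
    covariates: np.ndarray | None,
    methods: tuple,
    B: int,
    seed: int,
) -> list[RareSetResult]:
    out = []
    if len(variant_ids) == 0:
        for method in methods:
            arms = ("case", "control") if method in _ONE_SIDED else ("two_sided",)
            for arm in arms:
                out.append(
                    RareSetResult(
                        set_id=set_id, variant_ids=[], method=method, arm=arm,
                        statistic=float("nan"), note="no qualifying variants",
                    )
                )
        return out
    Gc = _clean(G)
    y = np.asarray(y, float)
    rng = np.random.default_rng(seed)
    for method in methods:
        if method in _ONE_SIDED:
            for arm in ("case", "control"):
                if method == "vt":
                    fn = lambda yy, a=arm: vt_stat(Gc, yy, arm=a)
                    mat_fn = _vt_matrix_fn(Gc, arm)
                elif method == "wt":
                    # weights are label-dependent: recompute inside permutations
                    fn = lambda yy, a=arm: wt_stat(Gc, yy, arm=a)
                    mat_fn = _wt_perm_matrix_fn(Gc, arm)
                else:
                    c = Gc.sum(axis=1)
                    fn = lambda yy, cc=c, a=arm: (
                        _std_score(yy, cc) if a == "case" else -_std_score(yy, cc)
                    )
                    mat_fn = _collapse_matrix_fn(c, arm)
                obs, p, b = perm_engine(
                    fn, y, B=B, seed=int(rng.integers(2**31)), stat_fn_matrix=mat_fn
                )
                out.append(
                    RareSetResult(
                        set_id=set_id, variant_ids=list(variant_ids), method=method,
                        arm=arm, statistic=obs, p_empirical=p, n_perm=b,
                    )
                )
        elif method in ("skat", "skato"):
            null = SkatNull(y, covariates)
            if method == "skat":
                Q, p_an = skat_stat(Gc, y, covariates, null=null)
                fn = lambda yy: skat_stat(Gc, yy, covariates)[0]
                obs, p_emp, b = (Q, None, None)
                if B:
                    obs, p_emp, b = perm_engine(fn, y, B=B, seed=int(rng.integers(2**31)))
                out.append(
                    RareSetResult(
                        set_id=set_id, variant_ids=list(variant_ids), method="skat",
                        arm="two_sided", statistic=Q, p_empirical=p_emp, n_perm=b,
                        p_analytic=p_an,
                    )
                )
            else:
                T, p_an, _ = skato_stat(Gc, y, covariates, null=null)
                p_emp = None
                b = None
                if B:
                    p_emp, b = _skato_perm(Gc, y, covariates, B, int(rng.integers(2**31)))
                out.append(
                    RareSetResult(
                        set_id=set_id, variant_ids=list(variant_ids), method="skato",
                        arm="two_sided", statistic=T, p_empirical=p_emp, n_perm=b,
                        p_analytic=p_an,
                    )
                )
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def _skato_perm(G, y, covariates, B, seed):
    """Permutation p for the SKAT-O min-p statistic.

    Each permutation's Q_rho values are converted to within-permutation
    ranks per rho; the min over rho of those per-rho empirical p-values is
    the permuted statistic (smaller more extreme).
    """
    null = SkatNull(y, covariates)
    Z = _skato_prep(G, null, None)
    rng = np.random.default_rng(seed)
    n = y.size
    order = np.argsort(rng.random((B, n)), axis=1)
    Y = np.asarray(y, float)[order]
    mu = null.mu

    def q_components(Ymat):
        R = Ymat - mu[None, :]
        U = R @ Z                      # (B, m) score vectors
        qs = (U**2).sum(axis=1)
        qb = U.sum(axis=1) ** 2
        return qs, qb

    qs_p, qb_p = q_components(Y)
    r0 = (np.asarray(y, float) - mu) @ Z
    qs_o, qb_o = float(r0 @ r0), float(r0.sum() ** 2)
    minp_perm = np.full(B, np.inf)
    minp_obs = np.inf
    for rho in RHO_GRID:
        q_perm = (1 - rho) * qs_p + rho * qb_p
        q_obs = (1 - rho) * qs_o + rho * qb_o
        # empirical upper-tail p of each value within the permuted null
        sorted_q = np.sort(q_perm)
        ge = B - np.searchsorted(sorted_q, q_perm - 1e-12, side="left")
        p_perm = (ge + 1.0) / (B + 1.0)
        ge_obs = B - int(np.searchsorted(sorted_q, q_obs - 1e-12, side="left"))
        p_obs = (ge_obs + 1.0) / (B + 1.0)
        minp_perm = np.minimum(minp_perm, p_perm)
        minp_obs = min(minp_obs, p_obs)
    r = int(np.sum(minp_perm <= minp_obs + 1e-15))
    return (r + 1.0) / (B + 1.0), B


def gene_test(
    genotypes: GenotypeMatrix,
    response: np.ndarray,
    gene: str,
    mask: VariantMask | None = None,
    methods: tuple = ("burden", "wt", "vt", "skato"),
    covariates: np.ndarray | None = None,
    B: int = B_GENE_DEFAULT,
    seed: int = 0,
    n_genes_tested: int | None = None,
) -> list[RareSetResult]:
    """All configured collapsing tests for one gene's masked variant set.

    The Bonferroni-corrected significance threshold 0.05 / n_genes_tested
    is recorded on each result's note when the gene count is supplied.
    """
    mask = mask or VariantMask()
    genes = {v.gene for v in genotypes.variants if v.gene is not None}
    if gene not in genes:
        raise KeyError(f"gene {gene!r} absent from the annotation (have {sorted(genes)})")
    ids = [v for v in mask.apply(genotypes)
           if genotypes.variants[genotypes.index_of(v)].gene == gene]
    G = genotypes.subset_variants(ids).dosages if ids else np.zeros((genotypes.n_subjects, 0))
    res = _run_set(gene, G, ids, response, covariates, methods, B, seed)
    if n_genes_tested:
        thr = 0.05 / n_genes_tested
        for r in res:
            r.note = (r.note + f"; bonferroni_threshold={thr:g}").lstrip("; ")
    return res


def domain_test(
    genotypes: GenotypeMatrix,
    response: np.ndarray,
    gene: str,
    domain: str | tuple[int, int],
    mask: VariantMask | None = None,
    methods: tuple = ("burden", "wt", "vt"),
    covariates: np.ndarray | None = None,
    B: int = B_GENE_DEFAULT,
    seed: int = 0,
) -> list[RareSetResult]:
    """Collapsing tests restricted to one protein domain of a gene.

    ``domain`` is either a domain label from the annotation or a 1-based
    closed interval on the gene's concatenated CDS.
    """
    mask = mask or VariantMask()
    genes = {v.gene for v in genotypes.variants if v.gene is not None}
    if gene not in genes:
        raise KeyError(f"gene {gene!r} absent from the annotation")
    ids = []
    for vid in mask.apply(genotypes):
        v = genotypes.variants[genotypes.index_of(vid)]
        if v.gene != gene:
            continue
        if isinstance(domain, str):
            if v.domain == domain:
                ids.append(vid)
        else:
            lo, hi = domain
            if v.cds_pos is not None and lo <= v.cds_pos <= hi:
                ids.append(vid)
    set_id = f"{gene}:{domain}"
    G = genotypes.subset_variants(ids).dosages if ids else np.zeros((genotypes.n_subjects, 0))
    return _run_set(set_id, G, ids, response, covariates, methods, B, seed)


def window_scan(
    genotypes: GenotypeMatrix,
    response: np.ndarray,
    gene: str,
    cds_length: int,
    window_bp: int = 500,
    mask: VariantMask | None = None,
    method: str = "skato",
    covariates: np.ndarray | None = None,
    B: int = B_WINDOW_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Sliding-window collapsing test along a gene's coding sequence.

    For each 1-based CDS position the masked variants within
    +/- window_bp/2 (inclusive) form the tested set; identical variant
    subsets are tested once and shared across the positions they cover.
    Positions whose window holds no qualifying variant are recorded as
    empty, not tested.  Returns a position-indexed track.
    """
    if window_bp % 2 != 0:
        raise ValueError("window width must be even")
    mask = mask or VariantMask()
    half = window_bp // 2
    ids = [v for v in mask.apply(genotypes)
           if genotypes.variants[genotypes.index_of(v)].gene == gene]
    pos = {v: genotypes.variants[genotypes.index_of(v)].cds_pos for v in ids}
    ids = [v for v in ids if pos[v] is not None]
    rows = []
    cache: dict[frozenset, tuple[float, float | None]] = {}
    rng = np.random.default_rng(seed)
    seeds: dict[frozenset, int] = {}
    for x in range(1, cds_length + 1):
        members = frozenset(v for v in ids if abs(pos[v] - x) <= half)
        if not members:
            rows.append({"cds_pos": x, "n_variants": 0, "statistic": np.nan,
                         "p_empirical": np.nan, "note": "empty"})
            continue
        if members not in cache:
            sub = sorted(members)
            G = genotypes.subset_variants(sub).dosages
            sd = int(rng.integers(2**31))
            seeds[members] = sd
            res = _run_set(f"{gene}@{x}", G, sub, response, covariates, (method,), B, sd)
            r = res[0]
            cache[members] = (r.statistic, r.p_empirical)
        stat, p = cache[members]
        rows.append({"cds_pos": x, "n_variants": len(members), "statistic": stat,
                     "p_empirical": p, "note": ""})
    return pd.DataFrame(rows)
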