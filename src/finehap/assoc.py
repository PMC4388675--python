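"""Covariate-adjusted logistic association, stepwise conditional scan,
and inverse-variance fixed-effect meta-analysis.

The logistic fit is a direct iteratively-reweighted least-squares (IRLS)
Newton solver: at case-control cohort scale the conditional scan refits
every remaining candidate each round, so the fit is written as a handful of
dense linear-algebra calls with no per-observation Python overhead.
Missing dosages are mean-imputed within the fitted stratum, which keeps
subjects aligned with their covariate rows (standard chip practice).

Separation (a fitted probability pinned at 0 or 1 with a diverging
coefficient) is flagged rather than silently reported: the Wald p is
unreliable there, so the likelihood-ratio p is substituted and the result
carries ``flagged=True``.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2, norm

from .containers import AssocResult, ConditionalScanResult, GenotypeMatrix

__all__ = ["fit_logistic", "conditional_scan", "meta_fixed", "logistic_irls"]

_MAX_ITER = 100
_GTOL = 1e-8


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the gradient-norm trace."""

    def __init__(self, trace):
        self.trace = list(trace)
        super().__init__(
            f"logistic IRLS did not converge in {len(self.trace)} iterations; "
            f"final gradient norm {self.trace[-1]:.3e}"
        )


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def logistic_irls(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = _MAX_ITER,
    gtol: float = _GTOL,
    ridge: float = 0.0,
):
    """Newton/IRLS maximum-likelihood logistic fit.

    Returns ``(beta, cov, loglik, converged, separated, trace)``.  ``cov``
    is the inverse observed information.  ``separated`` is True when some
    fitted probability is within 1e-10 of 0/1 while its linear predictor
    exceeds 15 in magnitude — the classic diverging-coefficient signature.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    # sensible intercept start when the first column is constant 1
    if np.all(X[:, 0] == 1.0):
        ybar = min(max(y.mean(), 1e-9), 1 - 1e-9)
        beta[0] = np.log(ybar / (1 - ybar))
    trace = []
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        g = X.T @ (y - mu)
        gnorm = float(np.linalg.norm(g, ord=np.inf))
        trace.append(gnorm)
        if gnorm < gtol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        if ridge:
            H = H + ridge * np.eye(k)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # dampen absurd steps (separation paths)
        smax = np.max(np.abs(step))
        if smax > 10.0:
            step = step * (10.0 / smax)
        beta = beta + step
    eta = X @ beta
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    ll = float(np.sum(y * eta - np.log1p(np.exp(-np.abs(eta))) - np.maximum(eta, 0.0)))
    pinned = (mu < 1e-8) | (mu > 1 - 1e-8)
    separated = bool(np.any(pinned & (np.abs(eta) > 15.0)))
    if not converged and not separated:
        raise ConvergenceError(trace)
    return beta, cov, ll, converged, separated, trace


def _null_loglik(y: np.ndarray, C: np.ndarray) -> float:
    b, _, ll, *_ = logistic_irls(y, C)
    return ll


def _design(dosage, covariates, n):
    """Build [1 | dosage | covariates], mean-imputing missing dosages."""
    d = np.asarray(dosage, dtype=float).copy()
    miss = np.isnan(d)
    if miss.all():
        raise ValueError("dosage entirely missing")
    if miss.any():
        d[miss] = d[~miss].mean()
    cols = [np.ones(n), d]
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        sd = C.std(axis=0)
        if np.any(sd == 0):
            bad = int(np.where(sd == 0)[0][0])
            raise ValueError(f"covariate column {bad} is constant")
        cols.append(C)
    X = np.column_stack(cols)
    return X, d, C


def fit_logistic(
    response: np.ndarray,
    dosage: np.ndarray,
    covariates: np.ndarray | None = None,
    variant_id: str = "",
    lrt: bool = False,
) -> AssocResult:
    """Additive-model logistic association of one dosage column.

    ``response`` is 0/1 disease status; ``covariates`` (optional) enter
    unpenalised alongside an intercept.  Returns Wald statistics; when the
    fit separates, ``p`` is the likelihood-ratio p and the result is
    flagged.  ``lrt=True`` additionally reports the LRT p for clean fits.
    """
    y = np.asarray(response, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    n = y.size
    X, d, C = _design(dosage, covariates, n)
    if np.nansum(d) == 0:
        raise ValueError("dosage has no carriers")
    beta, cov, ll, converged, separated, trace = logistic_irls(y, X)
    b = float(beta[1])
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se > 0 and not separated:
        z = b / se
        p = float(2.0 * norm.sf(abs(z)))
    else:
        p = float("nan")
    p_lrt = None
    if lrt or separated:
        Xnull = np.column_stack([np.ones(n)] + ([C] if C is not None else []))
        ll0 = _null_loglik(y, Xnull)
        stat = max(0.0, 2.0 * (ll - ll0))
        p_lrt = float(chi2.sf(stat, df=1))
    if separated:
        p = p_lrt
    p = min(max(float(p), np.finfo(float).tiny), 1.0)
    case = y == 1
    with np.errstate(invalid="ignore"):
        fc = float(np.nanmean(np.asarray(dosage, float)[case]) / 2.0)
        fk = float(np.nanmean(np.asarray(dosage, float)[~case]) / 2.0)
    return AssocResult(
        variant_id=variant_id,
        beta=b,
        se=se,
        p=p,
        n_case=int(case.sum()),
        n_control=int((~case).sum()),
        freq_case=fc,
        freq_control=fk,
        p_lrt=p_lrt,
        flagged=separated,
        note="separation" if separated else "",
    )


def conditional_scan(
    genotypes: GenotypeMatrix,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
    stop_p: float = 0.01,
) -> ConditionalScanResult:
    """Stepwise conditional (forward-selection) association scan.

    Round k fits every remaining variant with the k-1 previously selected
    variants appended to the covariates; the minimum-p candidate is selected
    while its p < ``stop_p``.  Ties break on smaller genomic position, then
    lexicographic variant id.  Candidates collinear with the selected set
    are skipped with a note, never a crash.  No MAF floor is applied.
    """
    if genotypes.n_variants == 0:
        raise ValueError("no variants to scan")
    y = np.asarray(response, dtype=float)
    out = ConditionalScanResult(stop_p=stop_p)
    remaining = list(range(genotypes.n_variants))
    selected_cols: list[np.ndarray] = []
    while remaining:
        extra = np.column_stack(selected_cols) if selected_cols else None
        if covariates is not None and extra is not None:
            cond = np.column_stack([np.asarray(covariates, float), extra])
        elif covariates is not None:
            cond = np.asarray(covariates, float)
        else:
            cond = extra
        # design matrix of the conditioning set, for collinearity screening
        base = np.ones((y.size, 1)) if cond is None else np.column_stack([np.ones(y.size), cond])
        round_results: list[AssocResult] = []
        for j in remaining:
            v = genotypes.variants[j]
            d = genotypes.dosages[:, j]
            dv = d.copy()
            miss = np.isnan(dv)
            if miss.any() and not miss.all():
                dv[miss] = dv[~miss].mean()
            resid_ss = np.nan
            if not miss.all():
                coef, _, _, _ = np.linalg.lstsq(base, dv, rcond=None)
                resid = dv - base @ coef
                tot = float(((dv - dv.mean()) ** 2).sum())
                resid_ss = float((resid**2).sum()) / tot if tot > 0 else 0.0
            if not np.isfinite(resid_ss) or resid_ss < 1e-10:
                r = AssocResult(
                    variant_id=v.variant_id, beta=float("nan"), se=float("nan"),
                    p=float("nan"), n_case=int(y.sum()), n_control=int((1 - y).sum()),
                    note="skipped: collinear with selected set",
                )
                round_results.append(r)
                continue
            try:
                r = fit_logistic(y, d, cond, variant_id=v.variant_id)
            except (ValueError, ConvergenceError) as exc:
                r = AssocResult(
                    variant_id=v.variant_id, beta=float("nan"), se=float("nan"),
                    p=float("nan"), n_case=int(y.sum()), n_control=int((1 - y).sum()),
                    note=f"skipped: {exc}",
                )
            round_results.append(r)
        out.rounds.append(round_results)
        testable = [r for r in round_results if np.isfinite(r.p)]
        if not testable:
            out.stop_best_p = float("nan")
            break
        pos = {v.variant_id: v.pos for v in genotypes.variants}
        best = min(testable, key=lambda r: (r.p, pos[r.variant_id], r.variant_id))
        if best.p < stop_p:
            out.selected.append(best)
            j = genotypes.index_of(best.variant_id)
            d = genotypes.dosages[:, j].copy()
            miss = np.isnan(d)
            if miss.any():
                d[miss] = d[~miss].mean()
            selected_cols.append(d)
            remaining.remove(j)
        else:
            out.stop_best_p = best.p
            break
    return out


def meta_fixed(results: list[AssocResult], variant_id: str | None = None) -> AssocResult:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    beta_meta = sum(beta_i / se_i^2) / sum(1 / se_i^2);
    se_meta = sqrt(1 / sum(1 / se_i^2)); two-sided Wald p.
    Effect alleles must agree across studies when recorded.
    """
    if not results:
        raise ValueError("meta_fixed needs at least one study")
    alleles = {r.effect_allele for r in results if r.effect_allele is not None}
    if len(alleles) > 1:
        raise ValueError(
            f"effect alleles differ across studies ({sorted(alleles)}); harmonise before meta-analysis"
        )
    w = np.array([1.0 / r.se**2 for r in results])
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite study weight (se of 0 or inf)")
    b = np.array([r.beta for r in results])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    z = beta / se
    p = float(min(max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
    return AssocResult(
        variant_id=variant_id or results[0].variant_id,
        beta=beta,
        se=se,
        p=p,
        n_case=int(sum(r.n_case for r in results)),
        n_control=int(sum(r.n_control for r in results)),
        effect_allele=next(iter(alleles)) if alleles else None,
        note=f"meta of {len(results)} studies",
    )
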