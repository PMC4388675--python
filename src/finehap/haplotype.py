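"""EM haplotype phasing over small variant sets and haplotype-dosage
regression with an omnibus likelihood-ratio test.

Phasing enumerates all 2^k haplotypes over the k <= 10 modeled variants and
runs a deterministic EM over the diplotype completions of each observed
genotype vector (grouped by unique pattern, so cost scales with the number
of distinct genotype patterns, not subjects).  The regression is
haplotype-trend regression: each subject contributes their posterior-mean
haplotype counts, which propagates phase uncertainty instead of committing
to a best-guess phase.  Per-haplotype odds ratios are reported against the
most frequent modeled haplotype, and the omnibus test is the LRT of all
non-reference haplotype effects jointly (df = #haplotypes - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.stats import chi2, norm

from .assoc import logistic_irls
from .containers import AssocResult, HaplotypeFit

__all__ = ["em_phase", "haplotype_regression", "PhaseResult"]

MAX_VARIANTS = 10
POOL_FLOOR_DEFAULT = 1e-3


@dataclass
class PhaseResult:
    """EM phasing output over the full 2^k haplotype space."""

    haplotypes: list[tuple[int, ...]]   # all 2^k allele vectors
    frequencies: np.ndarray             # matching EM frequency estimates
    dosages: np.ndarray                 # subjects x 2^k posterior-mean counts
    loglik: float
    n_iter: int

    def modeled(self, floor: float = POOL_FLOOR_DEFAULT):
        """Haplotypes at or above the pooling floor, by descending frequency."""
        keep = np.where(self.frequencies >= floor)[0]
        order = keep[np.argsort(-self.frequencies[keep], kind="stable")]
        return [self.haplotypes[i] for i in order], self.frequencies[order]


def _compatible_pairs(g: np.ndarray, k: int):
    """Ordered (h1, h2) index pairs consistent with one genotype vector.

    Missing sites are unconstrained.  The ordered sum of f[h1]*f[h2] over
    these pairs equals the genotype probability under random mating.
    """
    typed = ~np.isnan(g)
    h1s, h2s = [], []
    for h1 in range(2 ** k):
        bits1 = [(h1 >> s) & 1 for s in range(k)]
        opts = []
        ok = True
        for s in range(k):
            if typed[s]:
                a2 = int(g[s]) - bits1[s]
                if a2 not in (0, 1):
                    ok = False
                    break
                opts.append((a2,))
            else:
                opts.append((0, 1))
        if not ok:
            continue
        for combo in product(*opts):
            h2 = sum(b << s for s, b in enumerate(combo))
            h1s.append(h1)
            h2s.append(h2)
    return np.array(h1s, dtype=int), np.array(h2s, dtype=int)


def em_phase(
    genotypes: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> PhaseResult:
    """Estimate haplotype frequencies and posterior diplotype dosages by EM.

    ``genotypes`` is a subjects x k dosage slice (k <= 10; NaN = missing).
    Initialisation is the linkage-equilibrium product of allele
    frequencies, making the fit deterministic.  The log-likelihood is
    asserted non-decreasing every iteration and the EM stops when its
    improvement falls below ``tol``.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, k = G.shape
    if k > MAX_VARIANTS:
        raise ValueError(
            f"{k} variants exceeds the {MAX_VARIANTS}-variant enumeration limit; prune the set first"
        )
    fully_typed = ~np.isnan(G).any(axis=1)
    if not fully_typed.any():
        raise ValueError("no fully-typed subject; cannot anchor phasing")
    H = 2 ** k
    haps = [tuple((h >> s) & 1 for s in range(k)) for h in range(H)]
    # unique genotype patterns
    keys = [tuple(-1 if np.isnan(x) else int(x) for x in row) for row in G]
    uniq: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        uniq.setdefault(key, []).append(i)
    patterns = []
    for key, idx in uniq.items():
        g = np.array([np.nan if v == -1 else float(v) for v in key])
        h1s, h2s = _compatible_pairs(g, k)
        if h1s.size == 0:
            raise ValueError(f"genotype pattern {key} admits no diplotype")
        patterns.append((np.array(idx, dtype=int), h1s, h2s))
    # linkage-equilibrium start
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(G, axis=0) / 2.0
    p_alt = np.clip(np.nan_to_num(p_alt, nan=0.5), 1e-6, 1 - 1e-6)
    f = np.ones(H)
    for s in range(k):
        bit = (np.arange(H) >> s) & 1
        f *= np.where(bit == 1, p_alt[s], 1 - p_alt[s])
    f /= f.sum()
    ll_prev = -np.inf
    n_iter = 0
    dosages = np.zeros((n, H))
    for n_iter in range(1, max_iter + 1):
        counts = np.zeros(H)
        ll = 0.0
        dosages[:] = 0.0
        for idx, h1s, h2s in patterns:
            w = f[h1s] * f[h2s]
            tot = w.sum()
            if tot <= 0:
                # all compatible haplotypes drove to zero frequency: restart
                # those entries at a tiny mass so the pattern stays explained
                w = np.ones_like(w)
                tot = float(w.size)
            post = w / tot
            ll += idx.size * np.log(max(tot, 1e-300))
            contrib = np.bincount(h1s, weights=post, minlength=H) + np.bincount(
                h2s, weights=post, minlength=H
            )
            counts += idx.size * contrib
            dosages[idx] = contrib
        assert ll >= ll_prev - 1e-9, "EM log-likelihood decreased"
        if ll - ll_prev < tol:
            ll_prev = ll
            break
        ll_prev = ll
        f = counts / (2.0 * n)
    freqs = f / f.sum()
    return PhaseResult(
        haplotypes=haps, frequencies=freqs, dosages=dosages, loglik=float(ll_prev), n_iter=n_iter
    )


def _reference_haplotype(haps: list[tuple[int, ...]], freqs: np.ndarray) -> int:
    """Most frequent haplotype; frequency ties break on the
    lexicographically smallest allele vector."""
    best = 0
    for i in range(1, len(haps)):
        if freqs[i] > freqs[best] + 1e-15 or (
            abs(freqs[i] - freqs[best]) <= 1e-15 and haps[i] < haps[best]
        ):
            best = i
    return best


def haplotype_regression(
    phase: PhaseResult,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
    min_freq: float = POOL_FLOOR_DEFAULT,
    variant_ids: list[str] | None = None,
) -> HaplotypeFit:
    """Logistic haplotype-trend regression with an omnibus LRT.

    Haplotypes below ``min_freq`` are dropped from the model and the
    remaining posterior dosages renormalised so each subject still
    contributes two haplotype copies.  One dosage column enters per
    non-reference modeled haplotype (the reference column is omitted by
    construction, which absorbs the sum-to-two constraint); the omnibus
    statistic is twice the log-likelihood gain over the covariate-only
    model, on #haplotypes - 1 degrees of freedom.
    """
    y = np.asarray(response, dtype=float)
    keep = np.where(phase.frequencies >= min_freq)[0]
    if keep.size < 2:
        raise ValueError("fewer than 2 haplotypes above the pooling floor")
    order = keep[np.argsort(-phase.frequencies[keep], kind="stable")]
    haps = [phase.haplotypes[i] for i in order]
    freqs = phase.frequencies[order].copy()
    freqs /= freqs.sum()  # modeled haplotypes renormalise to a proper simplex
    D = phase.dosages[:, order].copy()
    # renormalise so dropped haplotypes' mass is redistributed
    rowsum = D.sum(axis=1)
    ok = rowsum > 1e-12
    D[ok] *= 2.0 / rowsum[ok, None]
    ref_local = _reference_haplotype(haps, freqs)
    nonref = [i for i in range(len(haps)) if i != ref_local]
    n = y.size
    cols = [np.ones(n)] + [D[:, i] for i in nonref]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
        Xnull = np.column_stack([np.ones(n), C])
    else:
        Xnull = np.ones((n, 1))
    X = np.column_stack(cols)
    beta, cov, ll, *_ = logistic_irls(X=X, y=y)
    _, _, ll0, *_ = logistic_irls(X=Xnull, y=y)
    stat = max(0.0, 2.0 * (ll - ll0))
    df = len(haps) - 1
    p_omnibus = float(chi2.sf(stat, df=df))
    n_case = int(y.sum())
    n_control = int(n - n_case)
    results: dict[tuple[int, ...], AssocResult] = {}
    label = lambda h: "".join(map(str, h))
    for slot, i in enumerate(nonref, start=1):
        b = float(beta[slot])
        se = float(np.sqrt(max(cov[slot, slot], 0.0)))
        z = b / se if se > 0 else np.nan
        p = float(min(max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny), 1.0)) if se > 0 else 1.0
        results[haps[i]] = AssocResult(
            variant_id=f"hap_{label(haps[i])}", beta=b, se=se, p=p,
            n_case=n_case, n_control=n_control,
        )
    results[haps[ref_local]] = AssocResult(
        variant_id=f"hap_{label(haps[ref_local])}", beta=0.0, se=0.0, p=1.0,
        n_case=n_case, n_control=n_control, note="reference",
    )
    return HaplotypeFit(
        haplotypes=haps,
        frequencies=freqs,
        reference=haps[ref_local],
        dosages=D,
        results=results,
        lrt_stat=float(stat),
        df=df,
        p_omnibus=p_omnibus,
        loglik=float(ll),
    )
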