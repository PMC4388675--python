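"""Analytic case-control power, detectable-effect inversion, and
liability-scale variance explained.

The power model is the allele-count two-proportion normal approximation
(equivalent to a 1-df allelic trend test): the control risk-allele
frequency is q0, cases carry q1 = q0*OR / (1 - q0 + q0*OR), and the test
compares the two allele proportions over 2*n_case and 2*n_control allele
counts, with the null standard error pooled and two-sided alpha.  It is
validated elsewhere in the package against the empirical rejection rate of
the pipeline's own logistic test.

Variance explained uses the liability-threshold model: a variant with
allelic odds ratio OR at frequency p maps to a liability-scale effect
beta_liab = ln(OR) * K(1-K) / phi(Phi^-1(1-K)) at disease prevalence K,
and explains 2 p (1-p) beta_liab^2 of the unit liability variance.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .containers import PowerSpec

__all__ = [
    "cc_power",
    "min_detectable_or",
    "required_cases",
    "variance_explained_liability",
    "power_grid",
    "K_RA_DEFAULT",
]

K_RA_DEFAULT = 0.005        # preset lifetime prevalence used for the liability scale
POWER_TARGET_DEFAULT = 0.80
GENOME_WIDE_ALPHA = 5e-8


def _resolve_n(spec: PowerSpec, n_total: int | None):
    if spec.n_case is not None and spec.n_control is not None:
        return int(spec.n_case), int(spec.n_control)
    if spec.phen_freq is None or n_total is None:
        raise ValueError("need either explicit n_case/n_control or phen_freq with n_total")
    n_case = int(round(spec.phen_freq * n_total))
    return n_case, int(n_total) - n_case


def cc_power(spec: PowerSpec, n_total: int | None = None) -> float:
    """Analytic power of the two-sided allele-count test.

    ``spec.raf`` is the control risk-allele frequency (either minor or
    major side: protective alleles can be entered as RAF > 0.5, e.g.
    0.966 for the major allele of a protective MAF-0.034 variant).
    """
    if not (0.0 < spec.raf < 1.0):
        raise ValueError("risk-allele frequency must lie in (0, 1)")
    if spec.or_ <= 0:
        raise ValueError("odds ratio must be positive")
    n_case, n_control = _resolve_n(spec, n_total)
    if n_case < 1 or n_control < 1:
        raise ValueError(
            f"phenotype frequency leaves {n_case} cases / {n_control} controls; both must be >= 1"
        )
    q0 = spec.raf
    q1 = q0 * spec.or_ / (1.0 - q0 + q0 * spec.or_)
    m1, m2 = 2.0 * n_case, 2.0 * n_control
    delta = abs(q1 - q0)
    pbar = (m1 * q1 + m2 * q0) / (m1 + m2)
    se0 = np.sqrt(pbar * (1.0 - pbar) * (1.0 / m1 + 1.0 / m2))
    se1 = np.sqrt(q1 * (1.0 - q1) / m1 + q0 * (1.0 - q0) / m2)
    z = norm.isf(spec.alpha / 2.0)
    power = norm.cdf((delta - z * se0) / se1) + norm.cdf((-delta - z * se0) / se1)
    spec.power = float(np.clip(power, 0.0, 1.0))
    return spec.power


def min_detectable_or(
    maf: float,
    phen_freq: float,
    n_total: int,
    alpha: float = 1e-4,
    power_target: float = POWER_TARGET_DEFAULT,
    or_grid: np.ndarray | None = None,
) -> float | None:
    """Smallest grid OR reaching the power target; None if the grid runs out."""
    if or_grid is None:
        or_grid = np.round(np.arange(1.1, 3.0 + 1e-9, 0.1), 10)
    or_grid = np.asarray(or_grid, float)
    if or_grid.size == 0:
        raise ValueError("empty OR grid")
    if np.any(np.diff(or_grid) <= 0):
        raise ValueError("OR grid must be strictly ascending")
    for o in or_grid:
        spec = PowerSpec(raf=maf, or_=float(o), alpha=alpha, phen_freq=phen_freq)
        if cc_power(spec, n_total) >= power_target:
            return float(o)
    return None


def required_cases(
    maf: float,
    or_: float,
    alpha: float = GENOME_WIDE_ALPHA,
    power_target: float = POWER_TARGET_DEFAULT,
    control_ratio: float = 1.0,
) -> int:
    """Minimal case count (controls = ratio * cases) reaching the target power.

    Inverts :func:`cc_power` by bisection on the integer case count; the
    returned n satisfies power(n) >= target and power(n - 1) < target.
    """
    if or_ == 1.0:
        raise ValueError("OR = 1 carries no signal; required sample size is unbounded")

    def power_at(n_case: int) -> float:
        spec = PowerSpec(
            raf=maf, or_=or_, alpha=alpha,
            n_case=n_case, n_control=max(int(round(control_ratio * n_case)), 1),
        )
        return cc_power(spec)

    lo, hi = 1, 2
    while power_at(hi) < power_target:
        hi *= 2
        if hi > 10**9:
            raise RuntimeError("required case count exceeds 1e9; check the inputs")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= power_target:
            hi = mid
        else:
            lo = mid
    return hi


def variance_explained_liability(
    variants: list[tuple[float, float]],
    K: float = K_RA_DEFAULT,
) -> float:
    """Total percent of liability variance explained by (MAF, OR) pairs.

    Each variant contributes 2 p (1-p) beta_liab^2 with
    beta_liab = ln(OR) K(1-K)/phi(Phi^-1(1-K)); contributions sum under
    the assumed independence of the variants (distinct haplotype
    backgrounds).  Returned on the percent scale (0.25 means 0.25%).
    """
    if not (0.0 < K < 0.5):
        raise ValueError("prevalence K must lie in (0, 0.5)")
    thresh = norm.isf(K)
    factor = K * (1.0 - K) / norm.pdf(thresh)
    total = 0.0
    for p, or_ in variants:
        beta = np.log(or_) * factor
        total += 2.0 * p * (1.0 - p) * beta**2
    return float(total * 100.0)


def power_grid(
    maf: float,
    n_total: int,
    alpha: float = 1e-4,
    phen_freqs: np.ndarray | None = None,
    ors: np.ndarray | None = None,
):
    """Phenotype-frequency x OR power grid for one risk-allele frequency."""
    import pandas as pd

    if phen_freqs is None:
        phen_freqs = np.array([0.01, 0.02, 0.05, 0.10, 0.20])
    if ors is None:
        ors = np.round(np.arange(1.1, 3.0 + 1e-9, 0.1), 10)
    rows = {}
    for pf in phen_freqs:
        rows[pf] = [
            cc_power(PowerSpec(raf=maf, or_=float(o), alpha=alpha, phen_freq=float(pf)), n_total)
            for o in ors
        ]
    return pd.DataFrame(rows, index=np.round(ors, 10)).T.rename_axis("phen_freq")
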