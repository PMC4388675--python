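"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as a dense subjects x variants dosage matrix counting
copies of the alternate allele (0/1/2), with ``numpy.nan`` marking missing
calls.  Variant metadata travels alongside as a list of
:class:`VariantRecord`.  Subject-level phenotypes and covariates live in a
plain :class:`pandas.DataFrame` keyed by ``subject_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "AssocResult",
    "ConditionalScanResult",
    "HaplotypeFit",
    "RareSetResult",
    "PhewasRow",
    "PowerSpec",
]


@dataclass
class VariantRecord:
    """Annotation for one biallelic variant.

    ``cds_pos`` is the 1-based position on the gene's concatenated coding
    sequence (strand-resolved, so positions follow the coding order);
    ``None`` for non-coding variants.  ``polyphen``/``sift`` carry the
    three-level function-predictor labels consumed (never computed) by the
    rare-variant masks.
    """

    variant_id: str
    chrom: str = "19"
    pos: int = 0
    ref: str = "A"
    alt: str = "G"
    gene: str | None = None
    cds_pos: int | None = None
    consequence: str | None = None  # missense / nonsense / synonymous / intergenic
    polyphen: str | None = None     # benign / possibly / probably
    sift: str | None = None         # benign / possibly / probably (mapped scale)
    domain: str | None = None


class GenotypeMatrix:
    """Subjects x variants alternate-allele dosage matrix with missingness."""

    def __init__(
        self,
        dosages: np.ndarray,
        subject_ids: Sequence[str],
        variants: Sequence[VariantRecord],
    ):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x variants)")
        if dosages.shape[0] != len(subject_ids):
            raise ValueError(
                f"{dosages.shape[0]} dosage rows but {len(subject_ids)} subject ids"
            )
        if dosages.shape[1] != len(variants):
            raise ValueError(
                f"{dosages.shape[1]} dosage columns but {len(variants)} variant records"
            )
        ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        self.dosages = dosages
        self.subject_ids = list(subject_ids)
        self.variants = list(variants)

    # -- basic introspection -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def index_of(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    # -- summaries -----------------------------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def variant_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=1)

    # -- manipulation --------------------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), list(self.subject_ids), [replace(v) for v in self.variants]
        )

    def subset_variants(self, keep: Sequence[int] | Sequence[str]) -> "GenotypeMatrix":
        if len(keep) and isinstance(keep[0], str):
            idx = [self.index_of(v) for v in keep]
        else:
            idx = list(keep)  # type: ignore[arg-type]
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.subject_ids,
            [self.variants[i] for i in idx],
        )

    def subset_subjects(self, keep: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.subject_ids[i] for i in idx],
            self.variants,
        )

    def append_variants(self, other: "GenotypeMatrix") -> "GenotypeMatrix":
        if other.subject_ids != self.subject_ids:
            raise ValueError("subject ids differ; cannot append variant columns")
        return GenotypeMatrix(
            np.hstack([self.dosages, other.dosages]),
            self.subject_ids,
            self.variants + other.variants,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GenotypeMatrix {self.n_subjects} subjects x {self.n_variants} variants>"


@dataclass
class AssocResult:
    """One covariate-adjusted association test result.

    ``beta`` is the log-odds per alternate allele, ``or_`` = exp(beta),
    ``p`` the two-sided Wald p-value (LRT substituted and ``flagged``
    set when the fit separated).
    """

    variant_id: str
    beta: float
    se: float
    p: float
    n_case: int
    n_control: int
    freq_case: float = float("nan")
    freq_control: float = float("nan")
    p_lrt: float | None = None
    flagged: bool = False
    note: str = ""
    effect_allele: str | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.isf((1.0 - level) / 2.0)
        return float(np.exp(self.beta - z * self.se)), float(np.exp(self.beta + z * self.se))


@dataclass
class ConditionalScanResult:
    """Trace of a stepwise conditional association scan.

    ``selected`` lists the chosen variant per round with its round-specific
    result; ``rounds`` holds the full per-candidate table for every round
    (including the stopping round); ``stop_best_p`` is the smallest p seen
    in the round that failed the threshold (NaN when candidates ran out).
    """

    selected: list[AssocResult] = field(default_factory=list)
    rounds: list[list[AssocResult]] = field(default_factory=list)
    stop_p: float = 0.01
    stop_best_p: float = float("nan")

    @property
    def selected_ids(self) -> list[str]:
        return [r.variant_id for r in self.selected]


@dataclass
class HaplotypeFit:
    """Haplotype frequencies, per-haplotype effects and the omnibus test."""

    haplotypes: list[tuple[int, ...]]
    frequencies: np.ndarray
    reference: tuple[int, ...]
    dosages: np.ndarray  # subjects x modeled haplotypes (expected counts)
    results: dict[tuple[int, ...], AssocResult]
    lrt_stat: float
    df: int
    p_omnibus: float
    loglik: float = float("nan")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class RareSetResult:
    """Result of one rare-variant collapsing test on one variant set."""

    set_id: str
    variant_ids: list[str]
    method: str
    arm: str  # "case", "control" or "two_sided"
    statistic: float
    p_empirical: float | None = None
    n_perm: int | None = None
    p_analytic: float | None = None
    note: str = ""

    @property
    def testable(self) -> bool:
        return self.note != "no qualifying variants" and self.note != "empty"


@dataclass
class PhewasRow:
    """One phenotype row of a phenome scan: per-cohort fits plus meta."""

    phenotype: str
    label: str = ""
    per_cohort: dict[str, AssocResult] = field(default_factory=dict)
    meta: AssocResult | None = None
    untestable: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool | None:
        return None if self.meta is None else bool(self.meta.p < 1e-4)

    def consistent(self) -> bool:
        """Directionally consistent suggestive signal across cohorts.

        True iff every contributing cohort's effect has the same sign and the
        meta p-value is below each cohort's own p-value.  Pure predicate on
        this row's fields.
        """
        if self.meta is None or len(self.per_cohort) < 2:
            return False
        signs = {np.sign(r.beta) for r in self.per_cohort.values()}
        if len(signs) != 1 or 0.0 in signs:
            return False
        return all(self.meta.p < r.p for r in self.per_cohort.values())


@dataclass
class PowerSpec:
    """Inputs and result of one analytic case-control power evaluation."""

    raf: float
    or_: float
    alpha: float
    phen_freq: float | None = None
    n_case: int | None = None
    n_control: int | None = None
    power: float | None = None
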