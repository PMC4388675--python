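"""Phenome-wide association on coded clinical events across EMR cohorts.

Cases for a phenotype are subjects with at least two mapped events of its
code group; subjects with no events of the group are controls; subjects
with exactly one event are excluded from that phenotype's regression by
default (configurable to treat-as-control).  Phenotypes must exceed a
case-prevalence floor in every cohort and fall inside the configured code
inclusion range.  Per-cohort logistic fits share the package's association
engine and are combined by inverse-variance fixed-effect meta-analysis;
the quantitative-trait pipelines (first-LDL with statin exclusion, mean
WBC with measurement-count adjustment) are ordinary linear models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import fit_logistic, meta_fixed
from .containers import AssocResult, PhewasRow

__all__ = [
    "CodeMap",
    "define_cases",
    "prevalence_filter",
    "phewas_scan",
    "infection_scan",
    "quant_ldl",
    "quant_wbc",
]

ALPHA_DEFAULT = 1e-4       # phenome-wide significance (0.05 / ~500 phenotypes)
MIN_EVENTS_DEFAULT = 2
MIN_PREV_DEFAULT = 0.01


@dataclass
class CodeMap:
    """Code -> phenotype-group mapping with an inclusion range on the
    integer part of the (dotted, ICD-style) code."""

    table: pd.DataFrame  # columns: code, phenotype, label
    inclusion_range: tuple[int, int] = (1, 779)

    def __post_init__(self):
        need = {"code", "phenotype"}
        if not need <= set(self.table.columns):
            raise ValueError(f"code map needs columns {sorted(need)}")
        if self.table.groupby("phenotype").size().min() < 1:
            raise ValueError("empty phenotype group in code map")

    def phenotypes_in_range(self) -> list[str]:
        lo, hi = self.inclusion_range
        t = self.table
        roots = t["code"].str.split(".").str[0].astype(int)
        return sorted(t.loc[(roots >= lo) & (roots <= hi), "phenotype"].unique())

    def label(self, phenotype: str) -> str:
        t = self.table
        if "label" in t.columns:
            hit = t.loc[t["phenotype"] == phenotype, "label"]
            if len(hit):
                return str(hit.iloc[0])
        return phenotype


def define_cases(
    events: pd.DataFrame,
    codemap: CodeMap,
    min_events: int = MIN_EVENTS_DEFAULT,
    subject_ids: list[str] | None = None,
    one_event: str = "exclude",
) -> pd.DataFrame:
    """Per-subject, per-phenotype case status from the event table.

    Returns a subjects x phenotypes frame of {1 case, 0 control, NaN
    excluded}.  ``one_event`` handles subjects with exactly one mapped
    event below ``min_events``: "exclude" (default) or "control".
    Unmapped codes inside the inclusion range trigger a warning with the
    exclusion count.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if one_event not in ("exclude", "control"):
        raise ValueError("one_event must be 'exclude' or 'control'")
    lo, hi = codemap.inclusion_range
    roots = events["code"].str.split(".").str[0].astype(int)
    in_range = (roots >= lo) & (roots <= hi)
    mapped = events["code"].isin(set(codemap.table["code"]))
    n_unmapped = int((in_range & ~mapped).sum())
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} events carry codes inside the inclusion range "
            "but absent from the code map; they are ignored",
            stacklevel=2,
        )
    ev = events.loc[mapped].merge(codemap.table[["code", "phenotype"]], on="code")
    counts = ev.groupby(["subject_id", "phenotype"]).size().unstack(fill_value=0)
    phenos = codemap.phenotypes_in_range()
    if subject_ids is None:
        subject_ids = sorted(counts.index)
    counts = counts.reindex(index=subject_ids, columns=phenos, fill_value=0)
    status = pd.DataFrame(0.0, index=subject_ids, columns=phenos)
    status[counts >= min_events] = 1.0
    between = (counts > 0) & (counts < min_events)
    if one_event == "exclude":
        status[between] = np.nan
    return status


def prevalence_filter(
    status_tables: dict[str, pd.DataFrame],
    min_prev: float = MIN_PREV_DEFAULT,
) -> list[str]:
    """Phenotypes whose case prevalence exceeds ``min_prev`` in every cohort."""
    if not status_tables:
        raise ValueError("need at least one cohort status table")
    kept = None
    for name, tab in status_tables.items():
        prev = (tab == 1.0).mean(axis=0)
        ok = set(prev.index[prev > min_prev])
        kept = ok if kept is None else kept & ok
    return sorted(kept)


def _cohort_fit(dosage, status_col, covariates, phenotype) -> AssocResult | None:
    y = status_col.to_numpy(dtype=float)
    keep = ~np.isnan(y)
    yk = y[keep]
    if yk.sum() == 0 or yk.sum() == keep.sum():
        return None
    d = np.asarray(dosage, dtype=float)[keep]
    with np.errstate(invalid="ignore"):
        if np.nansum(d) == 0:
            return None
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)[keep]
    try:
        return fit_logistic(yk, d, C, variant_id=phenotype)
    except Exception:
        return None


def phewas_scan(
    dosage_per_cohort: dict[str, np.ndarray],
    status_per_cohort: dict[str, pd.DataFrame],
    covariates_per_cohort: dict[str, np.ndarray | None] | None = None,
    phenotypes: list[str] | None = None,
    alpha: float = ALPHA_DEFAULT,
    labels=None,
) -> list[PhewasRow]:
    """Logistic phenome scan per cohort with fixed-effect meta-analysis.

    ``dosage_per_cohort`` maps cohort name to the variant dosage vector
    aligned with that cohort's status-table rows; cohorts may carry extra
    covariate adjustments (e.g. one cohort further adjusted for disease
    status used in its ascertainment).  Rows with a zero-carrier or
    single-class phenotype-cohort cell are flagged untestable for that
    cohort; the meta-analysis pools whichever cohorts remain.
    """
    covariates_per_cohort = covariates_per_cohort or {}
    if phenotypes is None:
        phenotypes = sorted(
            set.intersection(*(set(t.columns) for t in status_per_cohort.values()))
        )
    rows = []
    for ph in phenotypes:
        row = PhewasRow(phenotype=ph, label=labels(ph) if labels else ph)
        for cohort, statuses in status_per_cohort.items():
            res = _cohort_fit(
                dosage_per_cohort[cohort],
                statuses[ph],
                covariates_per_cohort.get(cohort),
                ph,
            )
            if res is None:
                row.untestable.append(cohort)
            else:
                row.per_cohort[cohort] = res
        if len(row.per_cohort) >= 2:
            row.meta = meta_fixed(list(row.per_cohort.values()), variant_id=ph)
        elif len(row.per_cohort) == 1:
            row.meta = next(iter(row.per_cohort.values()))
        rows.append(row)
    return rows


def infection_scan(
    dosage_per_cohort: dict[str, np.ndarray],
    events_per_cohort: dict[str, pd.DataFrame],
    codeset: pd.DataFrame,
    covariates_per_cohort: dict[str, np.ndarray | None] | None = None,
    subject_ids_per_cohort: dict[str, list[str]] | None = None,
    min_events: int = MIN_EVENTS_DEFAULT,
) -> list[PhewasRow]:
    """Infection scan by anatomical site using an external code set.

    ``codeset`` has columns (site, code) — the comprehensive or restricted
    list is supplied as an input table, not reconstructed.  Sites reduce to
    ordinary phenotype groups and reuse the scan machinery; a site with no
    codes or no qualifying subjects is reported untestable.
    """
    if codeset is None or not {"site", "code"} <= set(codeset.columns):
        raise ValueError("infection code set needs columns (site, code)")
    table = codeset.rename(columns={"site": "phenotype"})[["code", "phenotype"]]
    table["label"] = table["phenotype"]
    cmap = CodeMap(table=table, inclusion_range=(0, 999))
    statuses = {}
    for cohort, ev in events_per_cohort.items():
        ids = None if subject_ids_per_cohort is None else subject_ids_per_cohort[cohort]
        with warnings.catch_warnings():
            # a site code set is intentionally sparse; other codes are not "unmapped"
            warnings.simplefilter("ignore", UserWarning)
            statuses[cohort] = define_cases(ev, cmap, min_events=min_events, subject_ids=ids)
    sites = sorted(set(codeset["site"]))
    return phewas_scan(
        dosage_per_cohort, statuses, covariates_per_cohort, phenotypes=sites
    )


def _ols(y: np.ndarray, X: np.ndarray, name: str) -> AssocResult:
    import statsmodels.api as sm

    fit = sm.OLS(y, X).fit()
    return AssocResult(
        variant_id=name,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n_case=int(len(y)),
        n_control=0,
        note="linear model",
    )


def quant_ldl(
    records: pd.DataFrame,
    dosage: np.ndarray,
    subject_ids: list[str],
    covariates: pd.DataFrame | None = None,
    name: str = "LDL",
) -> AssocResult:
    """First-LDL linear model with prior-statin exclusion.

    The outcome is each subject's first (earliest-year) LDL measurement;
    subjects with a statin prescription dated strictly before that
    measurement are excluded.  The fit adjusts for age at measurement,
    measurement year and any supplied covariates; beta is mg/dL per
    alternate allele.
    """
    rec = records.sort_values(["subject_id", "year"]).groupby("subject_id").first()
    rec = rec.reindex(subject_ids).dropna(subset=["ldl"])
    statin = rec["statin_year"]
    keep = statin.isna() | (statin >= rec["year"])
    rec = rec.loc[keep]
    if rec.empty:
        raise ValueError("statin exclusion removed every subject")
    idx = [subject_ids.index(s) for s in rec.index]
    d = np.asarray(dosage, float)[idx]
    d = np.where(np.isnan(d), np.nanmean(d), d)
    cols = [np.ones(len(rec)), d, rec["age_at_measure"].to_numpy(), rec["year"].to_numpy()]
    if covariates is not None:
        cols.append(covariates.iloc[idx].to_numpy(dtype=float))
    X = np.column_stack(cols)
    return _ols(rec["ldl"].to_numpy(dtype=float), X, name)


def quant_wbc(
    series: pd.DataFrame,
    dosage: np.ndarray,
    subject_ids: list[str],
    covariates: pd.DataFrame | None = None,
    name: str = "WBC",
) -> AssocResult:
    """Mean-WBC linear model with the measurement count as covariate.

    The outcome is the per-subject mean of all measurements; the number of
    measurements enters as a covariate (dropped with a warning when
    constant, e.g. every subject measured exactly once).
    """
    agg = series.groupby("subject_id")["wbc"].agg(["mean", "count"])
    agg = agg.reindex(subject_ids).dropna()
    if agg.empty:
        raise ValueError("no WBC measurements")
    idx = [subject_ids.index(s) for s in agg.index]
    d = np.asarray(dosage, float)[idx]
    d = np.where(np.isnan(d), np.nanmean(d), d)
    cols = [np.ones(len(agg)), d]
    counts = agg["count"].to_numpy(dtype=float)
    if np.ptp(counts) == 0:
        warnings.warn("measurement count is constant; dropped from the model", stacklevel=2)
    else:
        cols.append(counts)
    if covariates is not None:
        cols.append(covariates.iloc[idx].to_numpy(dtype=float))
    X = np.column_stack(cols)
    return _ols(agg["mean"].to_numpy(dtype=float), X, name)
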