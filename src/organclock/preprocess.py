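"""Cohort QC and normalization for plasma proteomics on a log2 relative scale.

Quality control drops proteins missing in more than 20% of subjects,
then subjects missing more than 50% of the retained proteins (both
strict inequalities, so a protein missing in exactly 20% is kept).
Retained values are rescaled per protein to [0, 1] and centered on the
median of the scaled values; missing entries stay missing — the
downstream gradient-boosted regressors handle them natively.

Chronological age is a decimal: days between the assigned birth date
(first day of the birth month) and the visit date, divided by 365.25.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
import pandas as pd

__all__ = [
    "ProteomeCohort",
    "compute_decimal_age",
    "filter_missingness",
    "scale_values",
    "apply_scaling",
    "preprocess_cohort",
]

DAYS_PER_YEAR = 365.25


@dataclass
class ProteomeCohort:
    """Subject-by-protein plasma proteome plus demographics and outcomes.

    ``values`` holds log2-scale relative quantities (NaN = missing),
    indexed by unique subject ids; ``demographics`` is aligned on the
    same index and carries at least ``age`` (decimal years) and ``sex``;
    ``covariates`` names additional adjustment columns in
    ``demographics``; ``outcomes`` maps outcome name → table with either
    (``event``, ``time``) or (``label``) columns on the same index.
    """

    values: pd.DataFrame
    demographics: pd.DataFrame
    covariates: tuple[str, ...] = ()
    outcomes: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("subject ids must be unique")
        if not self.values.index.equals(self.demographics.index):
            self.demographics = self.demographics.loc[self.values.index]
        if "age" in self.demographics and (self.demographics["age"] <= 0).any():
            raise ValueError("ages must be positive")
        for c in self.covariates:
            if c not in self.demographics.columns:
                raise ValueError(f"covariate {c!r} missing from demographics")

    @property
    def age(self) -> pd.Series:
        return self.demographics["age"]

    def subset(self, subject_ids) -> "ProteomeCohort":
        return ProteomeCohort(
            values=self.values.loc[subject_ids],
            demographics=self.demographics.loc[subject_ids],
            covariates=self.covariates,
            outcomes={k: v.loc[v.index.intersection(subject_ids)] for k, v in self.outcomes.items()},
        )


def compute_decimal_age(
    birth_year: int, birth_month: int, visit_date: _dt.date | str
) -> float:
    """Decimal age in years at ``visit_date``.

    The birth date is assigned as the first day of the birth month; the
    age is the calendar-day count to the visit divided by 365.25.
    """
    if isinstance(visit_date, str):
        visit_date = _dt.date.fromisoformat(visit_date)
    birth = _dt.date(birth_year, birth_month, 1)
    if visit_date < birth:
        raise ValueError(f"visit {visit_date} precedes assigned birth date {birth}")
    return (visit_date - birth).days / DAYS_PER_YEAR


def filter_missingness(
    values: pd.DataFrame,
    protein_max: float = 0.20,
    subject_max: float = 0.50,
) -> tuple[pd.DataFrame, dict]:
    """Drop over-missing proteins, then over-missing subjects.

    Proteins with missing fraction strictly greater than ``protein_max``
    are removed first; subject missingness is then computed on the
    retained proteins and subjects strictly above ``subject_max`` are
    removed.  Returns the filtered matrix and a QC report.
    """
    prot_frac = values.isna().mean(axis=0)
    keep_prot = prot_frac <= protein_max
    v1 = values.loc[:, keep_prot]
    subj_frac = (
        v1.isna().mean(axis=1) if v1.shape[1] else pd.Series(1.0, index=values.index)
    )
    keep_subj = subj_frac <= subject_max
    out = v1.loc[keep_subj]
    report = {
        "n_proteins_in": int(values.shape[1]),
        "n_subjects_in": int(values.shape[0]),
        "dropped_proteins": {p: float(prot_frac[p]) for p in values.columns[~keep_prot]},
        "dropped_subjects": {s: float(subj_frac[s]) for s in values.index[~keep_subj]},
        "n_proteins_out": int(out.shape[1]),
        "n_subjects_out": int(out.shape[0]),
    }
    if out.size == 0:
        raise ValueError(f"missingness filter removed everything: {report}")
    return out, report


def scale_values(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-protein rescale to [0, 1] then center on the median.

    x' = (x − min) / (max − min); x'' = x' − median(x').  Missing
    entries stay missing.  Constant proteins have an undefined range and
    are dropped with a warning.  Returns the scaled matrix and the
    scaling parameters (``vmin``, ``vmax``, ``median`` of the scaled
    values) for projection onto external cohorts.
    """
    vmin = values.min(axis=0)
    vmax = values.max(axis=0)
    constant = (vmax - vmin) <= 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant protein(s): "
            f"{list(values.columns[constant])[:5]}"
        )
    keep = values.loc[:, ~constant]
    vmin, vmax = vmin[~constant], vmax[~constant]
    scaled01 = (keep - vmin) / (vmax - vmin)
    med = scaled01.median(axis=0)
    params = pd.DataFrame({"vmin": vmin, "vmax": vmax, "median": med})
    return scaled01 - med, params


def apply_scaling(values: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Apply stored scaling parameters to another cohort (frozen mode)."""
    missing = [p for p in params.index if p not in values.columns]
    if missing:
        raise ValueError(f"cohort lacks proteins required by scaling parameters: {missing}")
    sub = values[params.index]
    scaled01 = (sub - params["vmin"]) / (params["vmax"] - params["vmin"])
    return scaled01 - params["median"]


def preprocess_cohort(
    cohort: ProteomeCohort,
    protein_max: float = 0.20,
    subject_max: float = 0.50,
    scaling_params: pd.DataFrame | None = None,
) -> tuple[ProteomeCohort, dict, pd.DataFrame]:
    """Missingness filter followed by scaling; returns (cohort, QC report, params).

    With ``scaling_params`` given, applies the stored (frozen) training
    parameters instead of re-estimating within this cohort; the default
    re-estimates per cohort, matching separately normalized cohorts.
    """
    filtered, report = filter_missingness(cohort.values, protein_max, subject_max)
    if scaling_params is None:
        scaled, params = scale_values(filtered)
    else:
        scaled, params = apply_scaling(filtered, scaling_params), scaling_params
    out = ProteomeCohort(
        values=scaled,
        demographics=cohort.demographics.loc[scaled.index],
        covariates=cohort.covariates,
        outcomes={k: v.loc[v.index.intersection(scaled.index)] for k, v in cohort.outcomes.items()},
    )
    return out, report, params
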