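"""Aging phenotypes derived from proteomic ages.

*Age gap* is the residual of proteomic age regressed (OLS, with
intercept) on chronological age: positive values mean accelerated aging
relative to same-aged peers.  *Extreme ageotypes* flag organs whose gap
exceeds ±1.5 cohort standard deviations (aged vs youthful).  Subjects
are further grouped by how many organs are extreme (0, 1–2, 3–4, 5+)
and, for two standardized risk scores, into five combined bins at cut
points ±0.5 and ±1.5 s.d. (intervals closed on the left, so a value
exactly at a cut point falls in the upper bin).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compute_age_gap",
    "apply_age_gap",
    "classify_ageotypes",
    "count_extreme_organs",
    "burden_group",
    "combine_scores",
    "build_phenotype_table",
]

BURDEN_LEVELS = ("0", "1-2", "3-4", "5+")
AGEOTYPE_LEVELS = ("youthful", "normal", "aged")


def compute_age_gap(
    proteomic_age: pd.Series, chronological_age: pd.Series
) -> tuple[pd.Series, tuple[float, float]]:
    """OLS residual of proteomic age on chronological age.

    Returns (gaps, (slope, intercept)); the coefficients are kept so
    the same regression can be applied to externally projected cohorts.
    By the normal equations the gaps have mean zero and zero sample
    correlation with age.
    """
    if len(proteomic_age) < 3:
        raise ValueError("need at least 3 subjects")
    x = chronological_age.loc[proteomic_age.index].to_numpy(dtype=float)
    ypred = proteomic_age.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("chronological age is constant; gap regression undefined")
    slope, intercept = np.polyfit(x, ypred, 1)
    gaps = pd.Series(ypred - (slope * x + intercept), index=proteomic_age.index, name="age_gap")
    return gaps, (float(slope), float(intercept))


def apply_age_gap(
    proteomic_age: pd.Series, chronological_age: pd.Series, coef: tuple[float, float]
) -> pd.Series:
    """Gap for external subjects under a frozen (slope, intercept)."""
    slope, intercept = coef
    x = chronological_age.loc[proteomic_age.index].to_numpy(dtype=float)
    return pd.Series(
        proteomic_age.to_numpy(dtype=float) - (slope * x + intercept),
        index=proteomic_age.index,
        name="age_gap",
    )


def classify_ageotypes(
    age_gaps: pd.Series, threshold_sd: float = 1.5, sd: float | None = None
) -> tuple[pd.Series, float]:
    """Label each subject aged / normal / youthful by the gap z-score.

    ``sd`` defaults to the analysis-sample standard deviation of the
    gaps (and should be passed frozen when labelling projected
    cohorts).  Returns (labels, sd used).
    """
    if sd is None:
        sd = float(age_gaps.std(ddof=1))
    if not sd > 0:
        raise ValueError("age-gap standard deviation must be positive")
    z = age_gaps / sd
    labels = pd.Series("normal", index=age_gaps.index, name="ageotype")
    labels[z > threshold_sd] = "aged"
    labels[z < -threshold_sd] = "youthful"
    return labels, sd


def burden_group(counts: pd.Series) -> pd.Series:
    """Map extreme-organ counts to the groups 0, 1–2, 3–4, 5+."""
    def _grp(c: int) -> str:
        if c <= 0:
            return "0"
        if c <= 2:
            return "1-2"
        if c <= 4:
            return "3-4"
        return "5+"

    return counts.map(_grp).astype(pd.CategoricalDtype(BURDEN_LEVELS, ordered=True))


def count_extreme_organs(labels: pd.DataFrame) -> pd.DataFrame:
    """Per subject: counts of aged and youthful organs plus burden groups.

    ``labels`` is subjects × organs with ageotype strings.
    """
    aged = (labels == "aged").sum(axis=1)
    youthful = (labels == "youthful").sum(axis=1)
    return pd.DataFrame(
        {
            "extreme_aged_count": aged,
            "extreme_youthful_count": youthful,
            "aged_burden_group": burden_group(aged),
            "youthful_burden_group": burden_group(youthful),
        }
    )


def combine_scores(
    score_a_z: pd.Series, score_b_z: pd.Series, restandardize: bool = True
) -> tuple[pd.Series, pd.Series]:
    """Combined standardized score and its five-bin stratification.

    The combined score is the mean of the two z-scores, re-standardized
    by default (``restandardize=False`` keeps the raw mean).  Bins:
    −2 (< −1.5), −1 ([−1.5, −0.5)), 0 ([−0.5, 0.5)), +1 ([0.5, 1.5)),
    +2 (≥ 1.5); boundary values fall in the upper bin.
    """
    if not score_a_z.index.equals(score_b_z.index):
        raise ValueError("score subject sets differ")
    combined = (score_a_z + score_b_z) / 2.0
    if restandardize:
        combined = (combined - combined.mean()) / combined.std(ddof=1)
    z = combined.to_numpy(dtype=float)
    bins = np.select(
        [z < -1.5, z < -0.5, z < 0.5, z < 1.5], [-2, -1, 0, 1], default=2
    )
    return combined.rename("combined_z"), pd.Series(bins, index=combined.index, name="combined_bin")


def build_phenotype_table(
    proteomic_ages: pd.DataFrame,
    chronological_age: pd.Series,
    threshold_sd: float = 1.5,
    burden_organs: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject aging phenotypes for a set of clocks.

    ``proteomic_ages`` is subjects × clocks (one column per organ, an
    ``organismal`` column allowed).  For each clock the table carries
    proteomic age, age gap, gap z-score and ageotype; burden counts run
    over ``burden_organs`` (default: every column except ``organismal``).
    Returns (table, fitted parameters for external application).
    """
    table = pd.DataFrame(index=proteomic_ages.index)
    fitted: dict[str, dict] = {}
    label_cols = {}
    for organ in proteomic_ages.columns:
        gaps, coef = compute_age_gap(proteomic_ages[organ], chronological_age)
        labels, sd = classify_ageotypes(gaps, threshold_sd)
        table[f"{organ}__proteomic_age"] = proteomic_ages[organ]
        table[f"{organ}__age_gap"] = gaps
        table[f"{organ}__age_gap_z"] = gaps / sd
        table[f"{organ}__ageotype"] = labels
        label_cols[organ] = labels
        fitted[organ] = {"slope": coef[0], "intercept": coef[1], "gap_sd": sd}
    organs = burden_organs or [c for c in proteomic_ages.columns if c != "organismal"]
    counts = count_extreme_organs(pd.DataFrame({o: label_cols[o] for o in organs}))
    return pd.concat([table, counts], axis=1), fitted
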