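"""Downstream association statistics for organ age gaps.

Cox proportional-hazards and logistic models report effects per 1 s.d.
of the exposure, adjusted for declared covariates, with Benjamini–
Hochberg FDR control within declared test families.  Also provided:
relative-contribution profiles (|z| of significant terms scaled to sum
to 1), cognitive/distress transition definitions, multimorbidity
labels, age/sex-matched case–control sets, paired-bootstrap AUC model
comparison, Kaplan–Meier cumulative incidence, and lifestyle risk
categories.

Cox models use lifelines (Efron tie handling); logistic models use
statsmodels.  The BH step-up itself is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import ConvergenceError
from scipy import stats
from sklearn.linear_model import LogisticRegression

import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "fit_cox",
    "fit_logistic",
    "bh_fdr",
    "add_fdr",
    "results_table",
    "relative_contribution",
    "define_transitions",
    "define_multimorbidity",
    "match_controls",
    "compare_auc",
    "cumulative_incidence",
    "lifestyle_category",
    "check_proportional_hazards",
]


@dataclass
class AssociationResult:
    """One outcome × exposure association, effect per 1 s.d. of exposure."""

    outcome: str
    exposure: str
    effect: float  # HR or OR
    ci_low: float
    ci_high: float
    z: float
    p: float
    n_events: int
    kind: str = "cox"  # "cox" | "logistic"
    q: float | None = None
    flagged: bool = False
    note: str = ""


def _standardize(x: pd.Series) -> pd.Series:
    sd = float(x.std(ddof=1))
    if not sd > 0:
        raise ValueError(f"exposure {x.name!r} has zero variance")
    return x / sd


def fit_cox(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    time_col: str = "time",
    event_col: str = "event",
    min_events: int = 10,
) -> AssociationResult:
    """Cox PH fit; HR per 1 s.d. of the exposure, Wald CI and p.

    Ties use the Efron approximation (lifelines default).  Convergence
    failure or separation yields a flagged result (excluded from FDR
    families by :func:`add_fdr`).
    """
    cols = [time_col, event_col, exposure, *covariates]
    data = df[cols].dropna().copy()
    n_events = int(data[event_col].sum())
    if n_events < min_events:
        return AssociationResult(
            outcome, exposure, np.nan, np.nan, np.nan, np.nan, np.nan,
            n_events, flagged=True, note=f"<{min_events} events",
        )
    data[exposure] = _standardize(data[exposure])
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=time_col, event_col=event_col)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
        return AssociationResult(
            outcome, exposure, np.nan, np.nan, np.nan, np.nan, np.nan,
            n_events, flagged=True, note=f"fit failed: {err}",
        )
    row = cph.summary.loc[exposure]
    return AssociationResult(
        outcome=outcome,
        exposure=exposure,
        effect=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        z=float(row["z"]),
        p=float(row["p"]),
        n_events=n_events,
        kind="cox",
    )


def fit_logistic(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    label_col: str = "label",
) -> AssociationResult:
    """Maximum-likelihood logistic fit; OR per 1 s.d. with Wald CI."""
    cols = [label_col, exposure, *covariates]
    data = df[cols].dropna().copy()
    y = data[label_col].astype(int)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present")
    data[exposure] = _standardize(data[exposure])
    X = sm.add_constant(data[[exposure, *covariates]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise ValueError("no convergence")
        beta = float(fit.params[exposure])
        se = float(fit.bse[exposure])
        if not np.isfinite(se) or se > 50:
            raise ValueError("separation suspected (unbounded s.e.)")
    except Exception as err:
        return AssociationResult(
            outcome, exposure, np.nan, np.nan, np.nan, np.nan, np.nan,
            int(y.sum()), kind="logistic", flagged=True, note=str(err),
        )
    return AssociationResult(
        outcome=outcome,
        exposure=exposure,
        effect=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        z=beta / se,
        p=float(fit.pvalues[exposure]),
        n_events=int(y.sum()),
        kind="logistic",
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    q(i) = min_{j >= i} p(j)·m/j on the sorted p-values, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def add_fdr(results: list[AssociationResult]) -> list[AssociationResult]:
    """BH-adjust one declared family in place (flagged results excluded)."""
    ok = [r for r in results if not r.flagged]
    if ok:
        qs = bh_fdr([r.p for r in ok])
        for r, q in zip(ok, qs):
            r.q = float(q)
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses_asdict(r) for r in results])


def dataclasses_asdict(r: AssociationResult) -> dict:
    return {
        "outcome": r.outcome, "exposure": r.exposure, "kind": r.kind,
        "effect": r.effect, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "z": r.z, "p": r.p, "q": r.q, "n_events": r.n_events,
        "flagged": r.flagged, "note": r.note,
    }


def relative_contribution(
    results: list[AssociationResult], alpha: float = 0.05
) -> pd.Series:
    """|z| of q-significant terms, scaled to sum to 1 (empty if none)."""
    outcomes = {r.outcome for r in results}
    if len(outcomes) > 1:
        raise ValueError(f"results span multiple outcomes: {sorted(outcomes)}")
    sig = [r for r in results if not r.flagged and r.q is not None and r.q < alpha]
    if not sig:
        return pd.Series(dtype=float, name="weight")
    z = pd.Series({r.exposure: abs(r.z) for r in sig}, name="weight")
    return z / z.sum()


def define_transitions(
    cognitive_baseline: pd.Series,
    cognitive_followup: pd.Series,
    education: pd.Series,
    distress: pd.Series,
    baseline_normal: pd.Series | None = None,
    threshold_sd: float = 1.5,
    distress_cutoff: float = 6.0,
    min_reference: int = 2,
) -> pd.DataFrame:
    """Cognitive and distress transition labels.

    MCI is a global cognitive score at least ``threshold_sd`` standard
    deviations below the baseline mean of cognitively normal subjects
    (``baseline_normal`` mask, e.g. disease-free at baseline; default
    everyone), with the reference mean/s.d. computed within education
    strata.  Baseline and follow-up scores are both called against the
    same reference cut.  Distress is a PHQ-4-like score ≥ 6
    (inclusive).  Strata with fewer than ``min_reference`` reference
    subjects are skipped with a warning (labels NaN).
    """
    idx = cognitive_baseline.index
    if baseline_normal is None:
        baseline_normal = pd.Series(True, index=idx)
    out = pd.DataFrame(index=idx)
    mci_base = pd.Series(np.nan, index=idx)
    mci_follow = pd.Series(np.nan, index=idx)
    for stratum, members in education.groupby(education, observed=False).groups.items():
        ref = cognitive_baseline.loc[members][baseline_normal.loc[members]].dropna()
        if len(ref) < min_reference:
            warnings.warn(
                f"education stratum {stratum!r}: <{min_reference} reference subjects, skipped"
            )
            continue
        cut = ref.mean() - threshold_sd * ref.std(ddof=1)
        base = cognitive_baseline.loc[members].dropna()
        mci_base.loc[base.index] = (base <= cut).astype(float)
        fol = cognitive_followup.loc[members].dropna()
        mci_follow.loc[fol.index] = (fol <= cut).astype(float)
    out["mci_baseline"] = mci_base
    out["mci_followup"] = mci_follow
    out["distress_baseline"] = (distress >= distress_cutoff).astype(float).where(distress.notna())
    out["healthy_to_mci"] = ((out["mci_baseline"] == 0) & (out["mci_followup"] == 1)).where(
        out["mci_baseline"].notna() & out["mci_followup"].notna()
    )
    return out


def define_multimorbidity(
    incident: pd.DataFrame, category_map: Mapping[str, str]
) -> pd.DataFrame:
    """Multimorbidity: ≥2 incident diseases per category and overall.

    ``incident`` is subjects × diseases (0/1); every disease must be in
    ``category_map``.  The combined label counts diseases across all
    categories.
    """
    unmapped = [d for d in incident.columns if d not in category_map]
    if unmapped:
        raise ValueError(f"diseases without category: {unmapped}")
    out = pd.DataFrame(index=incident.index)
    for cat in sorted(set(category_map.values())):
        cols = [d for d in incident.columns if category_map[d] == cat]
        out[f"{cat}_multimorbid"] = (incident[cols].sum(axis=1) >= 2).astype(int)
    out["combined_multimorbid"] = (incident.sum(axis=1) >= 2).astype(int)
    return out


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 5,
    age_tolerance: float = 2.0,
    match_sex: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Up to ``ratio`` age (±tolerance) and sex matched controls per case.

    Sampling is without replacement across the whole matched set — a
    control serves at most one case.  Returns (matches with columns
    case_id/control_id, list of cases with no eligible control).
    """
    if pool.empty:
        raise ValueError("control pool is empty")
    rng = np.random.default_rng([int(seed), 31])
    available = pool.copy()
    rows, unmatched = [], []
    for case_id in cases.index:
        age = cases.at[case_id, "age"]
        ok = (available["age"] - age).abs() <= age_tolerance
        if match_sex:
            ok &= available["sex"] == cases.at[case_id, "sex"]
        eligible = available.index[ok]
        if len(eligible) == 0:
            unmatched.append(case_id)
            continue
        take = rng.choice(eligible, size=min(ratio, len(eligible)), replace=False)
        rows.extend((case_id, c) for c in sorted(take))
        available = available.drop(index=take)
    return pd.DataFrame(rows, columns=["case_id", "control_id"]), unmatched


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann–Whitney AUC (tie-aware, rank-based)."""
    ranks = stats.rankdata(score)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compare_auc(
    df: pd.DataFrame,
    label_col: str,
    model_specs: Mapping[str, Sequence[str]],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Logistic-model AUCs plus pairwise paired-bootstrap difference tests.

    Each spec lists predictor columns; models are fit once on the full
    sample and subjects' fitted scores are resampled jointly in each of
    ``n_boot`` bootstrap draws (draws missing a class are redrawn).
    The two-sided p is the percentile tail of the AUC-difference
    distribution around zero.
    """
    y = df[label_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    scores: dict[str, np.ndarray] = {}
    for name, cols in model_specs.items():
        X = df[list(cols)].to_numpy(dtype=float)
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(X, y)
        scores[name] = clf.predict_proba(X)[:, 1]
    aucs = {name: _auc(y, s) for name, s in scores.items()}

    rng = np.random.default_rng([int(seed), 37])
    names = list(model_specs)
    n = len(y)
    boot = {name: np.empty(n_boot) for name in names}
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if 0 < y[idx].sum() < n:
                break
            redraws += 1
        for name in names:
            boot[name][b] = _auc(y[idx], scores[name][idx])
    rows = []
    for i, a in enumerate(names):
        for bname in names[i + 1 :]:
            d = boot[a] - boot[bname]
            p = 2.0 * min(float((d <= 0).mean()), float((d >= 0).mean()))
            rows.append(
                {
                    "model_a": a, "model_b": bname,
                    "auc_a": aucs[a], "auc_b": aucs[bname],
                    "diff": aucs[a] - aucs[bname], "p": min(p, 1.0),
                    "n_boot": n_boot, "redraws": redraws,
                }
            )
    return aucs, pd.DataFrame(rows)


def cumulative_incidence(
    outcome: pd.DataFrame,
    groups: pd.Series,
    time_col: str = "time",
    event_col: str = "event",
) -> dict[str, pd.DataFrame]:
    """1 − Kaplan–Meier per group, with event counts at each step."""
    out: dict[str, pd.DataFrame] = {}
    for g, members in groups.groupby(groups, observed=False).groups.items():
        sub = outcome.loc[outcome.index.intersection(members)]
        if sub.empty:
            warnings.warn(f"group {g!r} is empty; skipped")
            continue
        km = KaplanMeierFitter()
        km.fit(sub[time_col], sub[event_col])
        tab = km.event_table
        curve = pd.DataFrame(
            {
                "time": km.survival_function_.index,
                "cum_incidence": 1.0 - km.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
        curve["n_events"] = tab["observed"].reindex(curve["time"]).fillna(0).astype(int).to_numpy()
        out[g] = curve.reset_index(drop=True)
    return out


def lifestyle_category(counts: pd.Series) -> pd.Series:
    """Unhealthy-factor counts → favorable (0–2) / intermediate (3–5) / unfavorable (6–9)."""
    c = counts.astype(int)
    if ((c < 0) | (c > 9)).any():
        raise ValueError("counts must lie in [0, 9]")
    cat = pd.cut(
        c, bins=[-0.5, 2.5, 5.5, 9.5],
        labels=["favorable", "intermediate", "unfavorable"],
    )
    return cat.astype(pd.CategoricalDtype(["favorable", "intermediate", "unfavorable"], ordered=True))


def check_proportional_hazards(
    df: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    time_col: str = "time",
    event_col: str = "event",
) -> float:
    """Scaled Schoenfeld-residual test p-value for the exposure term.

    Small p flags a time-varying effect (proportional-hazards
    violation).
    """
    from lifelines.statistics import proportional_hazard_test

    data = df[[time_col, event_col, exposure, *covariates]].dropna()
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col=time_col, event_col=event_col)
    res = proportional_hazard_test(cph, data, time_transform="rank")
    return float(res.summary.loc[exposure, "p"].min() if hasattr(res.summary.loc[exposure, "p"], "min") else res.summary.loc[exposure, "p"])
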