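"""Organ aging clocks: LightGBM regressors of chronological age on plasma proteins.

The training recipe, applied per organ (or to all proteins for the
organismal clock):

1. split subjects 7:3 into training and held-out test sets;
2. tune LightGBM hyperparameters by seeded random search, maximizing
   mean out-of-fold R² over k-fold cross-validation on the training set;
3. Boruta feature selection: each trial adds one permuted "shadow" copy
   per surviving protein, refits, and removes every real protein whose
   mean |SHAP| importance falls below the maximum shadow importance
   (the 100% threshold), until the survivor set is stable;
4. retune on the selected panel and fit the final model; performance
   (Pearson r, R²) is reported on the untouched test set;
5. proteomic age for *every* subject is the out-of-fold prediction from
   a fresh k-fold fit on the full sample, so nobody is predicted by a
   model that saw them.

SHAP importances come from LightGBM's native TreeSHAP
(``predict(pred_contrib=True)``).  Missing protein values are handled
natively by the trees (routed to the loss-minimizing split side).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SearchSpace",
    "ClockModel",
    "split_train_test",
    "tune_hyperparameters",
    "boruta_select",
    "fit_final",
    "predict_oof",
    "train_clock",
    "project",
    "shap_importance",
    "save_clock",
    "load_clock",
]

#: settings that make single-threaded LightGBM runs byte-reproducible
_LGB_FIXED = dict(
    deterministic=True,
    force_row_wise=True,
    n_jobs=1,
    verbosity=-1,
    min_split_gain=0.0,
)

SHADOW_PREFIX = "shadow__"


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges for the random search.

    ``n_trials`` defaults to the full-scale 200; :meth:`desk` returns
    the reduced desk-scale space (30 trials) for interactive runs and
    simulations.
    """

    learning_rate: tuple[float, float] = (0.02, 0.2)  # sampled log-uniform
    num_leaves: tuple[int, int] = (7, 63)
    min_child_samples: tuple[int, int] = (10, 80)
    feature_fraction: tuple[float, float] = (0.5, 1.0)
    bagging_fraction: tuple[float, float] = (0.5, 1.0)
    max_estimators: int = 400
    early_stopping_rounds: int = 25
    n_trials: int = 200
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    @classmethod
    def desk(cls, n_trials: int = 30, **kw) -> "SearchSpace":
        return cls(n_trials=n_trials, **kw)

    def sample(self, rng: np.random.Generator) -> dict:
        lr_lo, lr_hi = self.learning_rate
        return {
            "learning_rate": float(np.exp(rng.uniform(np.log(lr_lo), np.log(lr_hi)))),
            "num_leaves": int(rng.integers(self.num_leaves[0], self.num_leaves[1] + 1)),
            "min_child_samples": int(
                rng.integers(self.min_child_samples[0], self.min_child_samples[1] + 1)
            ),
            "feature_fraction": float(rng.uniform(*self.feature_fraction)),
            "bagging_fraction": float(rng.uniform(*self.bagging_fraction)),
            "bagging_freq": 1,
        }


def _make_regressor(params: dict, seed: int, n_estimators: int) -> lgb.LGBMRegressor:
    clean = {k: v for k, v in params.items() if k != "n_estimators"}
    return lgb.LGBMRegressor(
        n_estimators=n_estimators, random_state=int(seed) % (2**31 - 1), **_LGB_FIXED, **clean
    )


def split_train_test(
    ids: Sequence, train_fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Seed-deterministic disjoint, exhaustive 7:3-style partition of ids."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = list(ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 subjects to split")
    rng = np.random.default_rng([int(seed), 11])
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test


def _kfold(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def _cv_r2(
    X: pd.DataFrame, y: np.ndarray, params: dict, k: int, seed: int,
    max_estimators: int, early_stopping_rounds: int,
) -> tuple[float, int]:
    """Mean out-of-fold R² and mean early-stopped tree count over k folds."""
    rng = np.random.default_rng([int(seed), 13])
    folds = _kfold(len(X), k, rng)
    r2s, iters = [], []
    for i, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(len(X)), val_idx)
        model = _make_regressor(params, seed + i, max_estimators)
        model.fit(
            X.iloc[tr_idx], y[tr_idx],
            eval_set=[(X.iloc[val_idx], y[val_idx])],
            eval_metric="l2",
            callbacks=[lgb.early_stopping(early_stopping_rounds, verbose=False)],
        )
        pred = model.predict(X.iloc[val_idx])
        ss_res = float(np.sum((y[val_idx] - pred) ** 2))
        ss_tot = float(np.sum((y[val_idx] - y[val_idx].mean()) ** 2))
        r2s.append(1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"))
        iters.append(model.best_iteration_ or max_estimators)
    return float(np.mean(r2s)), int(round(float(np.mean(iters))))


def tune_hyperparameters(
    X: pd.DataFrame, y: Sequence[float], space: SearchSpace, seed: int = 0
) -> tuple[dict, pd.DataFrame]:
    """Seeded random search maximizing mean k-fold out-of-fold R².

    Returns the best configuration (with ``n_estimators`` fixed to the
    mean early-stopped tree count of its folds) and the full trial log.
    """
    if X.shape[1] == 0:
        raise ValueError("candidate protein set is empty")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng([int(seed), 17])
    records = []
    for t in range(space.n_trials):
        params = space.sample(rng)
        r2, n_est = _cv_r2(
            X, y, params, space.k_folds, seed,
            space.max_estimators, space.early_stopping_rounds,
        )
        records.append({"trial": t, "mean_r2": r2, "n_estimators": n_est, **params})
    log = pd.DataFrame(records)
    if log["mean_r2"].isna().all():
        raise RuntimeError("all tuning trials failed to fit")
    best = log.loc[log["mean_r2"].idxmax()]
    best_params = {
        k: best[k]
        for k in ("learning_rate", "num_leaves", "min_child_samples",
                  "feature_fraction", "bagging_fraction", "bagging_freq")
    }
    best_params = {k: (int(v) if k in ("num_leaves", "min_child_samples", "bagging_freq") else float(v))
                   for k, v in best_params.items()}
    best_params["n_estimators"] = int(best["n_estimators"])
    return best_params, log


def shap_importance(model: lgb.LGBMRegressor, X: pd.DataFrame) -> pd.Series:
    """Mean |TreeSHAP| attribution per feature (nonnegative)."""
    contrib = model.predict(X, pred_contrib=True)
    return pd.Series(np.abs(contrib[:, :-1]).mean(axis=0), index=X.columns)


def boruta_select(
    X: pd.DataFrame,
    y: Sequence[float],
    params: dict,
    max_trials: int = 200,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Boruta shadow-feature selection at the 100% threshold.

    Each trial permutes every surviving column independently to create
    shadow features, fits the regressor on real + shadow features,
    computes mean |SHAP| on the training data, and removes every real
    feature whose importance is below the maximum shadow importance.
    Stops when a trial removes nothing (or at ``max_trials``).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng([int(seed), 19])
    surviving = list(X.columns)
    records = []
    for trial in range(max_trials):
        Xr = X[surviving]
        shadows = pd.DataFrame(
            {SHADOW_PREFIX + c: rng.permutation(Xr[c].to_numpy()) for c in surviving},
            index=Xr.index,
        )
        Xfull = pd.concat([Xr, shadows], axis=1)
        model = _make_regressor(params, seed + trial, params.get("n_estimators", 100))
        model.fit(Xfull, y)
        imp = shap_importance(model, Xfull)
        max_shadow = float(imp[[c for c in Xfull.columns if c.startswith(SHADOW_PREFIX)]].max())
        removed = [c for c in surviving if imp[c] < max_shadow]
        surviving = [c for c in surviving if c not in removed]
        records.append(
            {
                "trial": trial,
                "n_surviving": len(surviving),
                "n_removed": len(removed),
                "max_shadow_importance": max_shadow,
                "removed": ",".join(removed),
            }
        )
        if not removed or not surviving:
            break
    if not surviving:
        warnings.warn("Boruta removed every feature; returning empty selection")
    return surviving, pd.DataFrame(records)


def fit_final(
    X: pd.DataFrame, y: Sequence[float], params: dict, seed: int = 0
) -> lgb.LGBMRegressor:
    """Fit the final regressor on the training set with tuned parameters."""
    if X.shape[1] == 0:
        raise ValueError("selected protein set is empty")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: age is constant")
    model = _make_regressor(params, seed, params.get("n_estimators", 100))
    model.fit(X, y)
    return model


def predict_oof(
    X: pd.DataFrame,
    y: Sequence[float],
    params: dict,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, list[lgb.LGBMRegressor]]:
    """Out-of-fold proteomic age for every subject.

    Subjects are partitioned into k folds; each subject's prediction
    comes from the one model whose training fold excluded them.
    Returns (predictions, fold assignment, fold models).
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng([int(seed), 23])
    folds = _kfold(len(X), k, rng)
    pred = np.full(len(X), np.nan)
    fold_of = np.full(len(X), -1)
    models = []
    for i, val_idx in enumerate(folds):
        tr_idx = np.setdiff1d(np.arange(len(X)), val_idx)
        model = fit_final(X.iloc[tr_idx], y[tr_idx], params, seed=seed + 100 + i)
        pred[val_idx] = model.predict(X.iloc[val_idx])
        fold_of[val_idx] = i
        models.append(model)
    assert (fold_of >= 0).all(), "every subject must be predicted exactly once"
    return (
        pd.Series(pred, index=X.index, name="proteomic_age"),
        pd.Series(fold_of, index=X.index, name="fold"),
        models,
    )


@dataclass
class ClockModel:
    """One organ's trained clock with its evaluation and bookkeeping."""

    organ: str
    candidate_proteins: list[str]
    selected_proteins: list[str]
    hyperparameters: dict
    fold_models: list = field(default_factory=list, repr=False)
    fold_assignment: pd.Series | None = field(default=None, repr=False)
    oof_age: pd.Series | None = field(default=None, repr=False)
    evaluation: dict = field(default_factory=dict)
    train_ids: list = field(default_factory=list, repr=False)
    test_ids: list = field(default_factory=list, repr=False)
    tuning_log: pd.DataFrame | None = field(default=None, repr=False)
    boruta_log: pd.DataFrame | None = field(default=None, repr=False)
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.selected_proteins) <= set(self.candidate_proteins):
            raise ValueError("selected proteins must be a subset of the candidates")


def train_clock(
    values: pd.DataFrame,
    age: pd.Series,
    organ: str,
    candidate_proteins: Sequence[str],
    space: SearchSpace,
    seed: int = 0,
    train_fraction: float = 0.7,
    boruta_max_trials: int = 200,
) -> ClockModel:
    """Full training recipe for one clock; see the module docstring."""
    candidates = [p for p in candidate_proteins if p in values.columns]
    if len(candidates) < 2:
        raise ValueError(f"organ {organ!r}: need >=2 measured candidate proteins")
    train_ids, test_ids = split_train_test(values.index, train_fraction, seed)
    Xtr, ytr = values.loc[train_ids, candidates], age.loc[train_ids].to_numpy()

    params0, tune_log = tune_hyperparameters(Xtr, ytr, space, seed=seed)
    selected, boruta_log = boruta_select(
        Xtr, ytr, params0, max_trials=boruta_max_trials, seed=seed
    )
    if not selected:
        warnings.warn(f"organ {organ!r}: empty Boruta selection, keeping all candidates")
        selected = list(candidates)
    params1, tune_log2 = tune_hyperparameters(Xtr[selected], ytr, space, seed=seed + 1)

    final = fit_final(Xtr[selected], ytr, params1, seed=seed)
    yte = age.loc[test_ids].to_numpy()
    pred_te = final.predict(values.loc[test_ids, selected])
    r, _ = stats.pearsonr(pred_te, yte)
    ss_res = float(np.sum((yte - pred_te) ** 2))
    ss_tot = float(np.sum((yte - yte.mean()) ** 2))
    cv_r2 = float(tune_log2["mean_r2"].max())

    oof, fold_of, models = predict_oof(
        values[selected], age.to_numpy(), params1, k=space.k_folds, seed=seed
    )
    # leakage guard: held-out evaluation subjects never entered the final fit
    assert not set(test_ids) & set(train_ids)
    return ClockModel(
        organ=organ,
        candidate_proteins=list(candidates),
        selected_proteins=list(selected),
        hyperparameters=params1,
        fold_models=models,
        fold_assignment=fold_of,
        oof_age=oof,
        evaluation={"test_r": float(r), "test_r2": 1.0 - ss_res / ss_tot, "cv_r2": cv_r2},
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        tuning_log=pd.concat([tune_log.assign(stage="pre"), tune_log2.assign(stage="post")]),
        boruta_log=boruta_log,
        seed=seed,
    )


def project(model: ClockModel, external_values: pd.DataFrame) -> pd.Series:
    """Proteomic age for an external cohort: mean over the fold ensemble."""
    missing = [p for p in model.selected_proteins if p not in external_values.columns]
    if missing:
        raise ValueError(f"external cohort lacks required proteins: {missing}")
    X = external_values[model.selected_proteins]
    preds = np.column_stack([m.predict(X) for m in model.fold_models])
    return pd.Series(preds.mean(axis=1), index=X.index, name="proteomic_age")


# ---------------------------------------------------------------------------
# model bundle (text-only) serialization


def save_clock(model: ClockModel, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "organ": model.organ,
        "candidate_proteins": model.candidate_proteins,
        "selected_proteins": model.selected_proteins,
        "hyperparameters": model.hyperparameters,
        "evaluation": model.evaluation,
        "train_ids": model.train_ids,
        "test_ids": model.test_ids,
        "seed": model.seed,
        "n_folds": len(model.fold_models),
    }
    (out / "clock.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for i, m in enumerate(model.fold_models):
        (out / f"fold{i}.txt").write_text(m.booster_.model_to_string())
    if model.oof_age is not None:
        pd.DataFrame(
            {"proteomic_age": model.oof_age, "fold": model.fold_assignment}
        ).to_csv(out / "oof.tsv", sep="\t", float_format="%.10g", index_label="subject_id")


class _BoosterRegressor:
    """Predict-only stand-in for a fitted LGBMRegressor, loaded from text."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict(self, X, **kw):
        return self.booster_.predict(X, **kw)


def load_clock(in_dir) -> ClockModel:
    src = Path(in_dir)
    meta = json.loads((src / "clock.json").read_text())
    models = [
        _BoosterRegressor(lgb.Booster(model_str=(src / f"fold{i}.txt").read_text()))
        for i in range(meta["n_folds"])
    ]
    oof = None
    fold_of = None
    oof_path = src / "oof.tsv"
    if oof_path.exists():
        df = pd.read_csv(oof_path, sep="\t", index_col="subject_id")
        oof, fold_of = df["proteomic_age"], df["fold"]
    return ClockModel(
        organ=meta["organ"],
        candidate_proteins=meta["candidate_proteins"],
        selected_proteins=meta["selected_proteins"],
        hyperparameters=meta["hyperparameters"],
        fold_models=models,
        fold_assignment=fold_of,
        oof_age=oof,
        evaluation=meta["evaluation"],
        train_ids=meta["train_ids"],
        test_ids=meta["test_ids"],
        seed=meta["seed"],
    )
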