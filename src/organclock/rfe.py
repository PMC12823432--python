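"""SHAP-guided recursive feature elimination for clock sparsification.

Starting from the full feature-selected panel, models are refit with
k-fold cross-validation at every panel size; the protein with the
lowest mean |SHAP| importance (averaged over folds, computed on each
fold's training data) is eliminated, down to a single protein.  A
minimal panel is then chosen as the smallest size whose mean
out-of-fold r² retains a stated fraction (default 85%) of the
full-panel r² — an explicit stand-in for choosing the knee of the r²
curve by eye.  Hyperparameters are held fixed along the path; re-tuning
at every size would square the cost for little ranking benefit.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .clock import _kfold, _make_regressor, shap_importance

__all__ = ["rfe_shap", "choose_panel", "panel_at_size", "elbow_size"]


def rfe_shap(
    X: pd.DataFrame,
    y,
    proteins: list[str],
    params: dict,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Elimination path from ``len(proteins)`` down to 1.

    Returns a DataFrame with one record per panel size: ``panel_size``,
    ``eliminated`` (the protein dropped after fitting at that size; at
    size 1 the remaining protein), and ``mean_r2`` (mean out-of-fold r²
    across the k folds).  Importance ties break to the lexicographically
    smallest protein id.  The starting panel is stored in
    ``result.attrs["initial_panel"]``.
    """
    if len(proteins) < 2:
        raise ValueError("RFE needs at least 2 proteins")
    y = np.asarray(y, dtype=float)
    panel = sorted(proteins)
    records = []
    try:
        while panel:
            rng = np.random.default_rng([int(seed), 29, len(panel)])
            folds = _kfold(len(X), k, rng)
            r2s = []
            imps = []
            for i, val_idx in enumerate(folds):
                tr_idx = np.setdiff1d(np.arange(len(X)), val_idx)
                model = _make_regressor(params, seed + i, params.get("n_estimators", 100))
                model.fit(X.iloc[tr_idx][panel], y[tr_idx])
                pred = model.predict(X.iloc[val_idx][panel])
                ss_res = float(np.sum((y[val_idx] - pred) ** 2))
                ss_tot = float(np.sum((y[val_idx] - y[val_idx].mean()) ** 2))
                r2s.append(1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"))
                imps.append(shap_importance(model, X.iloc[tr_idx][panel]))
            mean_imp = pd.concat(imps, axis=1).mean(axis=1)
            # ties break to the lexicographically smallest id (panel is sorted)
            victim = panel[int(np.argmin(mean_imp[panel].to_numpy()))] if len(panel) > 1 else panel[0]
            records.append(
                {"panel_size": len(panel), "eliminated": victim, "mean_r2": float(np.mean(r2s))}
            )
            if len(panel) == 1:
                break
            panel = [p for p in panel if p != victim]
    except Exception:
        if records:  # persist the partial path before aborting
            path = pd.DataFrame(records)
            path.attrs["initial_panel"] = sorted(proteins)
            path.attrs["partial"] = True
            raise RuntimeError(f"RFE fit failed; partial path of {len(records)} records") from None
        raise
    path = pd.DataFrame(records)
    path.attrs["initial_panel"] = sorted(proteins)
    return path


def panel_at_size(path: pd.DataFrame, size: int) -> list[str]:
    """Reconstruct the surviving panel at a given size from the elimination order.

    proteins(s) = initial panel minus every protein eliminated at sizes > s.
    """
    initial = path.attrs.get("initial_panel")
    if initial is None:
        raise ValueError("path lacks its initial panel (attrs['initial_panel'])")
    dropped = set(path.loc[path["panel_size"] > size, "eliminated"])
    return [p for p in initial if p not in dropped]


def choose_panel(path: pd.DataFrame, retention: float = 0.85) -> tuple[list[str], int]:
    """Smallest panel retaining ``retention`` of the full-panel mean r².

    Returns (panel proteins, panel size).
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must lie in (0, 1]")
    if path.empty:
        raise ValueError("empty RFE path")
    full_r2 = float(path.loc[path["panel_size"].idxmax(), "mean_r2"])
    ok = path[path["mean_r2"] >= retention * full_r2]
    size = int(ok["panel_size"].min()) if not ok.empty else int(path["panel_size"].max())
    return panel_at_size(path, size), size


def elbow_size(path: pd.DataFrame) -> int:
    """Kneedle-style elbow: size maximizing distance to the chord of the r² curve."""
    p = path.sort_values("panel_size")
    x = p["panel_size"].to_numpy(dtype=float)
    y = p["mean_r2"].to_numpy(dtype=float)
    if len(x) < 3:
        return int(x[-1])
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    denom = math.hypot(x1 - x0, y1 - y0) if (x1 != x0 or y1 != y0) else 1.0
    d = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / denom
    return int(x[int(np.argmax(d))])
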