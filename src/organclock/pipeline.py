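"""End-to-end pipeline driver: simulate → map → preprocess → train → refine → phenotype → associate.

Runs the whole method on a simulated cohort under one master seed and
writes every result as deterministic TSV/JSON (fixed float formatting),
so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from . import associations as assoc
from . import organ_mapping as om
from . import phenotypes as ph
from .clock import SearchSpace, train_clock
from .preprocess import preprocess_cohort
from .rfe import choose_panel, rfe_shap
from .synthetic import (
    SimulationConfig,
    simulate_cohort,
    write_cohort_tsv,
    write_expression_tsv,
    write_outcomes_tsv,
)

__all__ = ["run_pipeline"]

_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format=_FMT, **kw)


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    space: SearchSpace | None = None,
    fold_threshold: float = 4.0,
    retention: float = 0.85,
    boruta_max_trials: int = 200,
    train_organ_clocks: bool = True,
) -> dict:
    """Run every stage and write result tables under ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) with
    the paths of all written tables and headline metrics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    space = space or SearchSpace.desk()
    seed = config.seed

    # 1. simulate
    cohort, expr_a, expr_b, truth = simulate_cohort(config)
    write_expression_tsv(expr_a, out / "expression_discovery.tsv")
    write_expression_tsv(expr_b, out / "expression_confirmation.tsv")
    write_cohort_tsv(cohort, out / "cohort.tsv")
    if cohort.outcomes:
        write_outcomes_tsv(cohort.outcomes, out / "outcomes.tsv")
    (out / "truth.json").write_text(truth.to_json())

    # 2. organ mapping with confirmation
    ann = om.call_enriched(om.collapse_tissues_to_organs(expr_a), fold_threshold)
    confirmed = om.confirm_enrichment(ann, expr_b, fold_threshold)
    _write(confirmed, out / "annotations.tsv", index_label="protein_id")

    # 3. preprocess
    clean, qc, scaling = preprocess_cohort(cohort)
    (out / "qc_report.json").write_text(json.dumps(qc, indent=1, sort_keys=True))
    _write(scaling, out / "scaling_params.tsv", index_label="protein_id")

    # 4. clocks: organismal (all proteins) + per-organ (confirmed proteins)
    clocks = {}
    clocks["organismal"] = train_clock(
        clean.values, clean.age, "organismal", list(clean.values.columns),
        space, seed=seed, boruta_max_trials=boruta_max_trials,
    )
    if train_organ_clocks:
        for organ in config.organs:
            prots = [
                p for p in confirmed.index[confirmed["organ"] == organ]
                if p in clean.values.columns
            ]
            if len(prots) < 2:
                warnings.warn(f"organ {organ!r}: <2 confirmed measured proteins; no clock")
                continue
            clocks[organ] = train_clock(
                clean.values, clean.age, organ, prots,
                space, seed=seed, boruta_max_trials=boruta_max_trials,
            )
    eval_rows = [
        {"organ": name, "n_selected": len(c.selected_proteins), **c.evaluation}
        for name, c in clocks.items()
    ]
    _write(pd.DataFrame(eval_rows).set_index("organ"), out / "clock_evaluation.tsv")

    # 5. refine the organismal clock by RFE
    rfe_info = {}
    cm = clocks["organismal"]
    if len(cm.selected_proteins) >= 2:
        path = rfe_shap(
            clean.values.loc[cm.train_ids], clean.age.loc[cm.train_ids],
            cm.selected_proteins, cm.hyperparameters, k=space.k_folds, seed=seed,
        )
        _write(path, out / "rfe_path.tsv", index=False)
        panel, size = choose_panel(path, retention)
        rfe_info = {"panel": panel, "panel_size": size, "retention": retention}
        (out / "refined_panel.json").write_text(json.dumps(rfe_info, indent=1, sort_keys=True))

    # 6. phenotypes
    ages = pd.DataFrame({name: c.oof_age for name, c in clocks.items()})
    phen, fitted = ph.build_phenotype_table(ages, clean.age)
    _write(phen, out / "phenotypes.tsv", index_label="subject_id")
    (out / "gap_regressions.json").write_text(json.dumps(fitted, indent=1, sort_keys=True))

    # 7. associations: each clock's gap vs each outcome, BH within outcome
    results = []
    for oname, table in clean.outcomes.items():
        fam = []
        for name in clocks:
            df = table.join(phen[[f"{name}__age_gap"]], how="inner").join(
                clean.demographics[list(clean.covariates)], how="inner"
            )
            if {"event", "time"} <= set(table.columns):
                fam.append(
                    assoc.fit_cox(df, oname, f"{name}__age_gap", list(clean.covariates))
                )
            elif "label" in table.columns:
                fam.append(
                    assoc.fit_logistic(df, oname, f"{name}__age_gap", list(clean.covariates))
                )
        assoc.add_fdr(fam)
        results.extend(fam)
    if results:
        _write(assoc.results_table(results), out / "associations.tsv", index=False)

    manifest = {
        "seed": seed,
        "n_subjects": int(len(clean.values)),
        "n_proteins": int(clean.values.shape[1]),
        "n_confirmed_enriched": int(len(confirmed)),
        "clocks": {
            name: {"n_selected": len(c.selected_proteins), **c.evaluation}
            for name, c in clocks.items()
        },
        "rfe": {k: v for k, v in rfe_info.items() if k != "panel"},
        "files": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
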