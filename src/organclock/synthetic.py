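"""Synthetic cohort generator with known ground truth.

Emulates the data structure the clock pipeline assumes: a discovery and
a confirmation gene-by-tissue expression matrix with planted
organ-enriched genes; a cohort with ages uniform on the study range
(37–70 years by default), ten organ systems, organ-enriched plasma
proteins on a log2 relative scale, heterogeneous age trajectories
(linear plus an accelerating quadratic ramp after a configurable onset
age), a latent per-organ aging offset in years, MCAR missingness, and
survival / binary outcomes whose hazards depend on the standardized
latent offsets through an exponential proportional-hazards (or
logistic) model.

Every planted quantity — enrichment labels, informative-protein sets,
generating slopes and curvatures, subject×organ offsets, outcome
coefficients — is recorded in :class:`LatentTruth`, so downstream
recovery is testable without external data.

Each generation stage draws from its own random stream split from the
master seed, so stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .organ_mapping import TissueExpressionMatrix
from .preprocess import ProteomeCohort

__all__ = [
    "TEN_ORGANS",
    "OutcomeSpec",
    "SimulationConfig",
    "LatentTruth",
    "simulate_tissue_expression",
    "simulate_subjects",
    "simulate_proteome",
    "simulate_outcomes",
    "simulate_cohort",
    "default_outcome_specs",
]

#: the ten organ systems modeled by the clocks
TEN_ORGANS = (
    "brain",
    "heart",
    "lung",
    "immune",
    "artery",
    "intestine",
    "liver",
    "kidney",
    "muscle",
    "pancreas",
)

# sub-stream indices split from the master seed
_STAGES = {"expression": 1, "params": 2, "subjects": 3, "offsets": 4, "proteome": 5, "outcomes": 6}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGES[stage]])


@dataclass(frozen=True)
class OutcomeSpec:
    """Generating parameters for one outcome.

    ``log_hr`` is the true log hazard ratio (or log odds ratio for
    ``kind="binary"``) per 1 s.d. of each organ's latent offset; a
    scalar applies the same coefficient to every organ, a mapping sets
    per-organ coefficients (absent organs get 0).
    """

    name: str
    log_hr: float | Mapping[str, float] = 0.0
    baseline_hazard: float = 0.02  # events per year (survival)
    horizon: float = 13.0  # years of follow-up, administrative censoring
    kind: str = "survival"  # "survival" | "binary"
    intercept: float = -2.0  # baseline log-odds (binary)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)

    def coefficient(self, organ: str) -> float:
        if isinstance(self.log_hr, Mapping):
            return float(self.log_hr.get(organ, 0.0))
        return float(self.log_hr)


def default_outcome_specs() -> tuple[OutcomeSpec, ...]:
    """One mortality-like survival outcome and one binary transition."""
    return (
        OutcomeSpec("mortality", log_hr=0.2, baseline_hazard=0.02, horizon=13.0),
        OutcomeSpec("mci_transition", log_hr=0.3, kind="binary", intercept=-2.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_subjects: int = 2000
    age_min: float = 37.0
    age_max: float = 70.0
    organs: tuple[str, ...] = TEN_ORGANS
    n_proteins_per_organ: int = 20
    n_background_proteins: int = 0
    frac_age_informative: float = 0.10
    slope_range: tuple[float, float] = (0.03, 0.08)  # log2-units per year (magnitude)
    nonlinear_fraction: float = 0.25
    nonlinear_onset_age: float = 55.0
    offset_sd: float = 3.0  # years
    noise_sd: float = 0.3  # log2 units
    missing_rate: float = 0.05
    n_tissues_per_organ: int = 2
    enriched_fold: float = 8.0
    expr_noise_sigma: float = 0.2  # lognormal sigma on expression
    background_level: float = 1.0
    outcome_specs: tuple[OutcomeSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not self.age_min <= self.age_max:
            raise ValueError("need age_min <= age_max")
        if not self.organs or len(set(self.organs)) != len(self.organs):
            raise ValueError("organs must be nonempty and unique")
        for name in ("frac_age_informative", "nonlinear_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.offset_sd < 0 or self.noise_sd < 0 or self.expr_noise_sigma < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_tissues_per_organ < 1:
            raise ValueError("each organ needs at least one tissue subtype")
        if self.enriched_fold <= 1:
            raise ValueError("enriched_fold must exceed 1")
        for spec in self.outcome_specs:
            if spec.kind == "survival" and spec.baseline_hazard <= 0:
                raise ValueError(f"outcome {spec.name!r}: baseline hazard must be positive")


@dataclass
class LatentTruth:
    """Ground truth of one simulated cohort (no hidden state).

    ``organ_offsets`` is filled by :func:`simulate_proteome`;
    ``true_outcome_params`` by :func:`simulate_outcomes`.
    """

    enriched_protein_labels: dict[str, str]
    informative_proteins: dict[str, list[str]]  # organ -> proteins with nonzero slope
    slopes: dict[str, float]
    intercepts: dict[str, float]
    quadratic: dict[str, float]  # curvature past the onset age; 0 if linear
    nonlinear_onset_age: float
    organ_offsets: pd.DataFrame | None = None
    true_outcome_params: dict[str, OutcomeSpec] = field(default_factory=dict)

    @property
    def informative_protein_set(self) -> set[str]:
        return {p for ps in self.informative_proteins.values() for p in ps}

    def to_json(self) -> str:
        payload = {
            "enriched_protein_labels": self.enriched_protein_labels,
            "informative_proteins": self.informative_proteins,
            "slopes": self.slopes,
            "intercepts": self.intercepts,
            "quadratic": self.quadratic,
            "nonlinear_onset_age": self.nonlinear_onset_age,
            "organ_offsets": None
            if self.organ_offsets is None
            else {
                "index": list(self.organ_offsets.index),
                "columns": list(self.organ_offsets.columns),
                "values": self.organ_offsets.to_numpy().tolist(),
            },
            "true_outcome_params": {
                k: dataclasses.asdict(v) for k, v in self.true_outcome_params.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _protein_catalog(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    labels: dict[str, str] = {}
    proteins: list[str] = []
    for organ in config.organs:
        for i in range(config.n_proteins_per_organ):
            p = f"{organ}_p{i:03d}"
            proteins.append(p)
            labels[p] = organ
    proteins.extend(f"bg_p{i:03d}" for i in range(config.n_background_proteins))
    return proteins, labels


def _draw_truth(config: SimulationConfig) -> LatentTruth:
    rng = _rng(config.seed, "params")
    proteins, labels = _protein_catalog(config)
    informative: dict[str, list[str]] = {}
    slopes: dict[str, float] = {}
    quadratic: dict[str, float] = {}
    intercepts = {p: float(rng.normal(0.0, 1.0)) for p in proteins}
    for organ in config.organs:
        organ_prots = [p for p in proteins if labels.get(p) == organ]
        k = int(round(config.frac_age_informative * len(organ_prots)))
        chosen = sorted(rng.choice(organ_prots, size=k, replace=False).tolist()) if k else []
        informative[organ] = chosen
        if not chosen:
            continue
        lo, hi = config.slope_range
        mags = rng.uniform(lo, hi, size=len(chosen))
        signs = rng.choice([-1.0, 1.0], size=len(chosen))
        n_curved = int(round(config.nonlinear_fraction * len(chosen)))
        curved = set(rng.choice(len(chosen), size=n_curved, replace=False).tolist())
        for j, p in enumerate(chosen):
            slopes[p] = float(signs[j] * mags[j])
            # curvature scales with the linear slope so zero-slope proteins stay flat
            quadratic[p] = (
                float(slopes[p] * rng.uniform(0.01, 0.03)) if j in curved else 0.0
            )
    return LatentTruth(
        enriched_protein_labels=labels,
        informative_proteins=informative,
        slopes=slopes,
        intercepts=intercepts,
        quadratic=quadratic,
        nonlinear_onset_age=config.nonlinear_onset_age,
    )


def simulate_tissue_expression(
    config: SimulationConfig,
) -> tuple[TissueExpressionMatrix, TissueExpressionMatrix, LatentTruth]:
    """Discovery-like and confirmation-like gene-by-tissue matrices.

    Each planted enriched gene sits ``enriched_fold`` (default 8) above
    the background level in its organ's tissues in *both* matrices,
    modulated by independent multiplicative lognormal noise; background
    genes are near-uniform.  The two matrices share the plan and differ
    only in noise, emulating independent expression resources.
    """
    truth = _draw_truth(config)
    rng = _rng(config.seed, "expression")
    proteins, labels = _protein_catalog(config)
    tissues = [
        f"{organ}_t{j}" for organ in config.organs for j in range(config.n_tissues_per_organ)
    ]
    tissue_to_organ = {t: t.rsplit("_t", 1)[0] for t in tissues}

    base = np.full((len(proteins), len(tissues)), config.background_level)
    organ_of_tissue = np.array([tissue_to_organ[t] for t in tissues])
    for i, p in enumerate(proteins):
        organ = labels.get(p)
        if organ is not None:
            base[i, organ_of_tissue == organ] *= config.enriched_fold

    def one_matrix() -> TissueExpressionMatrix:
        noise = np.exp(config.expr_noise_sigma * rng.standard_normal(base.shape))
        return TissueExpressionMatrix(
            values=pd.DataFrame(base * noise, index=proteins, columns=tissues),
            tissue_to_organ=tissue_to_organ,
        )

    return one_matrix(), one_matrix(), truth


def simulate_subjects(config: SimulationConfig) -> pd.DataFrame:
    """Demographics: uniform ages, balanced sex, two continuous covariates."""
    rng = _rng(config.seed, "subjects")
    n = config.n_subjects
    ids = [f"S{i:06d}" for i in range(n)]
    demo = pd.DataFrame(
        {
            "age": rng.uniform(config.age_min, config.age_max, size=n),
            "sex": rng.integers(0, 2, size=n),
            "bmi": rng.normal(27.0, 4.0, size=n),
            "activity": rng.normal(0.0, 1.0, size=n),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    if config.age_min == config.age_max:
        demo["age"] = float(config.age_min)
    return demo


def simulate_proteome(
    demographics: pd.DataFrame, truth: LatentTruth, config: SimulationConfig
) -> ProteomeCohort:
    """Plasma proteome with latent per-organ aging offsets.

    An informative protein ``i`` of organ ``g`` takes
    ``intercept_i + slope_i·(age + offset_{s,g}) + quad_i·max(0, age +
    offset_{s,g} − onset)² + N(0, noise_sd)``; all other proteins are
    age-independent noise.  Offsets are drawn Normal(0, ``offset_sd``)
    per subject×organ and stored in ``truth.organ_offsets``.  Entries go
    missing completely at random at ``missing_rate``.
    """
    rng_off = _rng(config.seed, "offsets")
    rng = _rng(config.seed, "proteome")
    n = len(demographics)
    age = demographics["age"].to_numpy()

    offsets = pd.DataFrame(
        rng_off.normal(0.0, config.offset_sd, size=(n, len(config.organs))),
        index=demographics.index,
        columns=list(config.organs),
    )
    truth.organ_offsets = offsets

    proteins = list(truth.intercepts)
    X = np.empty((n, len(proteins)))
    for j, p in enumerate(proteins):
        x = np.full(n, truth.intercepts[p])
        if p in truth.slopes:
            organ = truth.enriched_protein_labels[p]
            eff_age = age + offsets[organ].to_numpy()
            x = x + truth.slopes[p] * eff_age
            q = truth.quadratic.get(p, 0.0)
            if q:
                x = x + q * np.maximum(0.0, eff_age - truth.nonlinear_onset_age) ** 2
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=n)
        X[:, j] = x
    if config.missing_rate > 0:
        mask = rng.random(size=X.shape) < config.missing_rate
        X[mask] = np.nan
    values = pd.DataFrame(X, index=demographics.index, columns=proteins)
    return ProteomeCohort(
        values=values, demographics=demographics, covariates=("bmi", "activity")
    )


def simulate_outcomes(
    demographics: pd.DataFrame, truth: LatentTruth, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Survival and binary outcomes driven by the standardized offsets.

    Survival: event times are exponential with hazard
    ``baseline_hazard · exp(Σ_g β_g · offset_g / offset_sd + covariate
    terms)``, administratively censored at the horizon.  Binary:
    Bernoulli with the analogous logistic linear predictor.  Covariate
    effects apply to z-scored covariates.
    """
    if not config.outcome_specs:
        raise ValueError("outcome_specs is empty")
    if truth.organ_offsets is None:
        raise ValueError("run simulate_proteome first (offsets not drawn)")
    rng = _rng(config.seed, "outcomes")
    offsets = truth.organ_offsets
    sd = config.offset_sd if config.offset_sd > 0 else 1.0
    out: dict[str, pd.DataFrame] = {}
    for spec in config.outcome_specs:
        lp = np.zeros(len(demographics))
        for organ in config.organs:
            beta = spec.coefficient(organ)
            if beta:
                lp += beta * offsets[organ].to_numpy() / sd
        for cov, beta in spec.covariate_effects.items():
            x = demographics[cov].to_numpy(dtype=float)
            z = (x - x.mean()) / (x.std() or 1.0)
            lp += beta * z
        if spec.kind == "survival":
            hazard = spec.baseline_hazard * np.exp(lp)
            t = rng.exponential(1.0 / hazard)
            event = (t <= spec.horizon).astype(int)
            out[spec.name] = pd.DataFrame(
                {"event": event, "time": np.minimum(t, spec.horizon)},
                index=demographics.index,
            )
        elif spec.kind == "binary":
            p = 1.0 / (1.0 + np.exp(-(spec.intercept + lp)))
            out[spec.name] = pd.DataFrame(
                {"label": (rng.random(len(p)) < p).astype(int)}, index=demographics.index
            )
        else:
            raise ValueError(f"unknown outcome kind {spec.kind!r}")
        truth.true_outcome_params[spec.name] = spec
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ProteomeCohort, TissueExpressionMatrix, TissueExpressionMatrix, LatentTruth]:
    """Run all generation stages; outcomes are attached to the cohort."""
    expr_a, expr_b, truth = simulate_tissue_expression(config)
    demo = simulate_subjects(config)
    cohort = simulate_proteome(demo, truth, config)
    if config.outcome_specs:
        cohort.outcomes = simulate_outcomes(demo, truth, config)
    return cohort, expr_a, expr_b, truth


# ---------------------------------------------------------------------------
# text serialization (TSV / JSON), deterministic float formatting

_FLOAT_FMT = "%.10g"


def write_expression_tsv(expr: TissueExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="gene_id")


def write_cohort_tsv(cohort: ProteomeCohort, path) -> None:
    wide = pd.concat([cohort.demographics, cohort.values], axis=1)
    wide.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="subject_id")


def write_outcomes_tsv(outcomes: Mapping[str, pd.DataFrame], path) -> None:
    rows = []
    for name in sorted(outcomes):
        df = outcomes[name].copy()
        df.insert(0, "outcome", name)
        rows.append(df)
    pd.concat(rows).to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="subject_id")
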