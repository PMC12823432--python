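"""Organ-enriched protein mapping from tissue-level expression.

A plasma protein is called *organ-enriched* when the expression of its
encoding gene in one organ is at least ``fold_threshold`` (default 4)
times higher than in every other organ.  Organ-level expression is the
maximum over that organ's tissue subtypes.  Calls made on a discovery
resource are confirmed by re-applying the same rule to an independent
expression resource; proteins whose call does not replicate are dropped.

Expression values are used as-is (no log transform): the enrichment test
is a ratio and therefore invariant to common rescaling of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TissueExpressionMatrix",
    "OrganPCProfile",
    "collapse_tissues_to_organs",
    "call_enriched",
    "confirm_enrichment",
    "organ_pc1",
]

#: tissues mapped to this pseudo-organ compete in the enrichment test but
#: can never receive an assignment
OTHER_ORGAN = "other"


@dataclass
class TissueExpressionMatrix:
    """Gene-by-tissue nonnegative expression (TPM-like) with a tissue→organ map.

    Parameters
    ----------
    values
        DataFrame, rows = gene ids (unique), columns = tissue ids.
    tissue_to_organ
        Maps every tissue column to one organ name or to ``"other"``.
    """

    values: pd.DataFrame
    tissue_to_organ: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.size == 0:
            raise ValueError("expression matrix is empty")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any():
            raise ValueError("expression values must be nonnegative and complete")
        missing = [t for t in self.values.columns if t not in self.tissue_to_organ]
        if missing:
            raise ValueError(f"tissues without organ mapping: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def tissue_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class OrganPCProfile:
    """First principal component of one organ's protein submatrix."""

    organ: str
    subject_scores: pd.Series
    loading_vector: pd.Series
    explained_variance_ratio: float = field(default=float("nan"))


def collapse_tissues_to_organs(expr: TissueExpressionMatrix) -> pd.DataFrame:
    """Collapse tissue columns to organ columns by the per-organ maximum.

    Each organ's expression for a gene is the maximum expression value
    among its tissue subtypes.  Organs with no mapped tissue are absent
    from the output.
    """
    groups: dict[str, list[str]] = {}
    for tissue in expr.values.columns:
        groups.setdefault(expr.tissue_to_organ[tissue], []).append(tissue)
    out = pd.DataFrame(
        {organ: expr.values[tissues].max(axis=1) for organ, tissues in groups.items()}
    )
    return out


def call_enriched(
    organ_expr: pd.DataFrame,
    fold_threshold: float = 4.0,
    exclude: tuple[str, ...] = (OTHER_ORGAN,),
) -> pd.DataFrame:
    """Apply the fourfold enrichment rule to an organ-collapsed matrix.

    A gene is assigned to organ ``g`` iff its expression there is at
    least ``fold_threshold`` times its expression in every other organ
    (boundary equality qualifies).  The rule can hold for at most one
    organ, so assignments are unique by construction.  A runner-up of
    exactly zero with positive top expression satisfies the rule with
    fold recorded as ``inf``.

    Returns a DataFrame indexed by gene with columns ``organ`` (name or
    None), ``fold`` (top / runner-up ratio) and ``confirmed`` (False
    until :func:`confirm_enrichment`).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    eligible = [c for c in organ_expr.columns if c not in exclude]
    if len([c for c in organ_expr.columns]) < 2 or not eligible:
        raise ValueError("need at least two organs, one of them assignable")

    arr = organ_expr.to_numpy(dtype=float)
    order = np.argsort(arr, axis=1)
    top_idx = order[:, -1]
    top = arr[np.arange(len(arr)), top_idx]
    runner = arr[np.arange(len(arr)), order[:, -2]] if arr.shape[1] > 1 else np.zeros(len(arr))

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(runner > 0, top / runner, np.where(top > 0, np.inf, 0.0))
    organs = organ_expr.columns.to_numpy()
    assigned = (top > 0) & (fold >= fold_threshold)
    assigned &= np.isin(organs[top_idx], eligible)

    organ_col = np.where(assigned, organs[top_idx], None)
    out = pd.DataFrame(
        {"organ": organ_col, "fold": fold, "confirmed": False},
        index=organ_expr.index,
    )
    # the rule cannot hold for two organs at once; assert the invariant anyway
    assert out["organ"].notna().sum() == int(assigned.sum())
    return out


def assigned_only(annotations: pd.DataFrame) -> pd.DataFrame:
    """Rows of an annotation table that received an organ."""
    return annotations[annotations["organ"].notna()]


def confirm_enrichment(
    annotations: pd.DataFrame,
    second_expr: TissueExpressionMatrix,
    fold_threshold: float = 4.0,
    lenient: bool = False,
) -> pd.DataFrame:
    """Keep a protein only if the second resource assigns the same organ.

    The enrichment rule is re-applied, organ-collapsed, to
    ``second_expr``.  Proteins whose organ call replicates are kept with
    ``confirmed=True``.  Proteins absent from the second matrix are
    dropped in strict mode (default) or kept unconfirmed when
    ``lenient=True``.
    """
    primary = assigned_only(annotations)
    second = call_enriched(
        collapse_tissues_to_organs(second_expr), fold_threshold=fold_threshold
    )
    keep_rows = []
    for gene, row in primary.iterrows():
        if gene not in second.index:
            if lenient:
                keep_rows.append((gene, row["organ"], row["fold"], False))
            continue
        if second.at[gene, "organ"] == row["organ"]:
            keep_rows.append((gene, row["organ"], row["fold"], True))
    return pd.DataFrame(
        keep_rows, columns=["protein_id", "organ", "fold", "confirmed"]
    ).set_index("protein_id")


def organ_pc1(
    values: pd.DataFrame,
    annotations: pd.DataFrame,
    min_proteins: int = 2,
) -> tuple[dict[str, OrganPCProfile], pd.DataFrame]:
    """Per-organ PC1 summary of the organ-enriched protein submatrix.

    For each organ the annotated proteins measured in ``values`` are
    mean-imputed (summary only — clocks see the raw missing values),
    column-standardized, and decomposed; subjects' PC1 scores and the
    loading vector are returned, the latter oriented so its largest-
    magnitude entry is positive.  Also returns the organ×organ Pearson
    correlation matrix of subject scores.
    """
    profiles: dict[str, OrganPCProfile] = {}
    for organ, rows in assigned_only(annotations).groupby("organ"):
        proteins = [p for p in rows.index if p in values.columns]
        if len(proteins) < min_proteins:
            warnings.warn(f"organ {organ!r} has <{min_proteins} measured proteins; skipped")
            continue
        sub = values[proteins].astype(float)
        sub = sub.fillna(sub.mean())
        sd = sub.std(ddof=0).replace(0.0, 1.0)
        z = (sub - sub.mean()) / sd
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        loading = vt[0]
        if loading[np.argmax(np.abs(loading))] < 0:
            loading = -loading
            u[:, 0] = -u[:, 0]
        scores = pd.Series(u[:, 0] * s[0], index=values.index, name=organ)
        evr = float(s[0] ** 2 / np.sum(s**2)) if s.size else float("nan")
        profiles[organ] = OrganPCProfile(
            organ=organ,
            subject_scores=scores,
            loading_vector=pd.Series(loading, index=proteins),
            explained_variance_ratio=evr,
        )
    score_df = pd.DataFrame({o: p.subject_scores for o, p in profiles.items()})
    return profiles, score_df.corr()
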