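"""Transfer of a trained latent space to new studies, plus covariate testing.

A held-out study with z-scored expression ``Y_target`` is projected into the
trained latent space with the ridge closed form

    B_target = (Z^T Z + lambda2 I)^-1 Z^T Y_target .

Each latent variable is then tested for a linear trend in a numeric covariate
(mouse age in months) by ordinary least squares, separately within each
stratum (e.g. genotype x cell type), and p-values are Benjamini-Hochberg
adjusted within each stratum.  LVs with FDR below the threshold (0.05 by
default) are flagged significant.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .plier import PlierModel


def project(Y_target, Z, lambda2: float) -> np.ndarray:
    """Project gene-space data into the latent space (closed-form ridge).

    Solves ``(Z^T Z + lambda2 I) B = Z^T Y_target`` via a Cholesky
    factorization of the (symmetric positive definite for ``lambda2 > 0``)
    normal matrix.
    """
    Y_target = np.asarray(Y_target, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Y_target.shape[0] != Z.shape[0]:
        raise ValueError(
            f"Y_target has {Y_target.shape[0]} genes but Z has {Z.shape[0]}"
        )
    L = Z.shape[1]
    A = Z.T @ Z + lambda2 * np.eye(L)
    rhs = Z.T @ Y_target
    try:
        c, low = linalg.cho_factor(A)
        return linalg.cho_solve((c, low), rhs)
    except linalg.LinAlgError:
        return linalg.solve(A, rhs, assume_a="sym")


def project_study(
    expr: ExpressionMatrix,
    model: PlierModel,
    lambda2: float | None = None,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Project an :class:`ExpressionMatrix` through a trained model, by gene id.

    Genes in the model but absent from the target are filled with 0 (the
    z-scored mean) and reported via a warning; target genes unknown to the
    model are ignored.  Fewer than ``min_overlap`` of the model's genes
    present is an error.  ``lambda2`` defaults to the value stored in the
    trained model's config.
    """
    if lambda2 is None:
        lambda2 = model.config.lambda2
        if lambda2 is None:
            raise ValueError("model config has no lambda2; pass one explicitly")
    target_index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [target_index.get(g) for g in model.gene_ids]
    present = sum(r is not None for r in rows)
    if present < min_overlap * len(model.gene_ids):
        raise ValueError(
            f"only {present}/{len(model.gene_ids)} model genes present in the "
            f"target (need >= {min_overlap:.0%})"
        )
    Y = np.zeros((len(model.gene_ids), expr.n_samples))
    missing = []
    for i, r in enumerate(rows):
        if r is None:
            missing.append(model.gene_ids[i])
        else:
            Y[i] = expr.values[r]
    if missing:
        warnings.warn(
            f"{len(missing)} model gene(s) absent from the target filled with 0: "
            f"{missing[:10]}",
            UserWarning,
            stacklevel=2,
        )
    B = project(Y, model.Z, lambda2)
    return pd.DataFrame(B, index=model.lv_ids, columns=expr.sample_ids)


def fit_lv_age_model(lv_values, ages) -> tuple[float, float, float]:
    """OLS of latent values on age (months): returns (slope, se, two-sided p)."""
    lv_values = np.asarray(lv_values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if lv_values.shape != ages.shape or lv_values.ndim != 1:
        raise ValueError("lv_values and ages must be 1-D and equal length")
    if lv_values.size < 3:
        raise ValueError("need at least 3 samples to test a slope")
    if np.unique(ages).size < 2:
        raise ValueError("all ages identical; slope is not estimable")
    res = stats.linregress(ages, lv_values)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a nonempty 1-D array")
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def associate_lvs(
    B_target: pd.DataFrame,
    metadata: pd.DataFrame,
    stratum_cols: Sequence[str] = ("condition", "cell_type"),
    age_col: str = "age_months",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-stratum, per-LV linear age model with within-stratum BH adjustment.

    ``B_target`` is LVs x samples (as returned by :func:`project_study`);
    ``metadata`` must carry one row per sample with the stratum columns and a
    numeric age column.  Returns a table with columns ``lv_id, stratum,
    slope, se, p, p_adj, significant``.
    """
    meta = metadata.set_index("sample_id").loc[list(B_target.columns)]
    stratum = meta[list(stratum_cols)].astype(str).agg("/".join, axis=1)
    rows = []
    for label in sorted(stratum.unique()):
        samples = stratum.index[stratum == label]
        ages = meta.loc[samples, age_col].to_numpy(dtype=float)
        sub = B_target[list(samples)]
        stats_rows = [fit_lv_age_model(sub.loc[lv].to_numpy(), ages) for lv in sub.index]
        p_adj = bh_adjust([r[2] for r in stats_rows])
        for lv, (slope, se, p), q in zip(sub.index, stats_rows, p_adj):
            rows.append(
                {
                    "lv_id": lv,
                    "stratum": label,
                    "slope": slope,
                    "se": se,
                    "p": p,
                    "p_adj": float(q),
                    "significant": bool(q < fdr),
                }
            )
    return pd.DataFrame(rows)


def significant_lvs(
    table: pd.DataFrame, fdr: float = 0.05
) -> tuple[dict[str, set[str]], dict[tuple[str, ...], int]]:
    """Per-stratum significant LV sets plus all intersection counts.

    Returns ``(sets, overlaps)`` where ``sets[stratum]`` is the set of LV ids
    with adjusted p below ``fdr`` and ``overlaps[(s1, ..., sk)]`` is the size
    of the intersection of those strata's sets, for every subset of strata of
    size >= 1 (Venn-style reporting).
    """
    required = {"lv_id", "stratum", "p_adj"}
    if not required.issubset(table.columns):
        raise ValueError(f"association table missing columns {required - set(table.columns)}")
    sets: dict[str, set[str]] = {}
    for label, sub in table.groupby("stratum"):
        sets[str(label)] = set(sub.loc[sub["p_adj"] < fdr, "lv_id"])
    strata = sorted(sets)
    overlaps: dict[tuple[str, ...], int] = {}
    for k in range(1, len(strata) + 1):
        for combo in itertools.combinations(strata, k):
            inter = set.intersection(*(sets[s] for s in combo))
            overlaps[combo] = len(inter)
    return sets, overlaps


def top_weighted_genes(
    model: PlierModel, lv_id: str | int, k: int = 20
) -> list[tuple[str, float]]:
    """Top-``k`` genes by descending loading on one LV (ties by gene id)."""
    idx = model.lv_index(lv_id)
    if k > len(model.gene_ids):
        raise ValueError(f"k={k} exceeds the {len(model.gene_ids)} genes in the model")
    col = model.Z[:, idx]
    order = sorted(range(len(col)), key=lambda i: (-col[i], model.gene_ids[i]))
    return [(model.gene_ids[i], float(col[i])) for i in order[:k]]
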