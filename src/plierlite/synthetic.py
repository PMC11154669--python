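"""Synthetic compendia with planted latent structure.

Real pathway-constrained factor models are trained on very large multi-study
compendia.  This module generates small stand-ins whose generative process
matches the statistical assumptions of the factorization and the downstream
tests: ``Y = Z_true @ B_true + noise`` with a subset of latent variables (LVs)
supported on known prior gene sets, per-study two-condition shifts that plant
a 2-means separation, and a held-out target study whose latent values follow a
linear trend in age for chosen LVs.

Every generator takes an explicit ``seed`` and draws all randomness from a
single ``numpy.random.Generator``, so identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PriorKnowledgeMatrix, ZSCORED

#: Loading placed on member genes of a prior-aligned LV.
ALIGNED_LOADING = 1.0
#: Standard deviation of background loadings on prior-aligned LV columns.
BACKGROUND_SD = 0.05

CONDITIONS = ("control", "case")
CELL_TYPES = ("microglia", "astrocyte", "neuron")
#: Adult ages in months used to fill compendium metadata.
COMPENDIUM_AGES = (2.0, 6.0, 12.0, 18.0, 24.0)


@dataclass
class StudyEffect:
    """Additive shift (in latent sd units) on one LV for one condition of a study."""

    lv: int
    shift: float
    condition: str = "case"


@dataclass
class SyntheticTruth:
    """Ground-truth bundle emitted next to every synthetic compendium."""

    Z_true: np.ndarray
    B_true: np.ndarray
    U_true: np.ndarray
    prior_aligned_lvs: list[int]
    study_effect_map: dict[str, StudyEffect]
    age_effect_map: dict[int, float]
    noise_sd: float
    seed: int
    gene_ids: list[str] = field(default_factory=list)
    set_ids: list[str] = field(default_factory=list)


@dataclass
class TargetTruth:
    """Ground truth for a generated target study."""

    B_true: np.ndarray
    age_effect_map: dict[int, float]
    noise_sd: float
    seed: int


def generate_prior(
    n_genes: int,
    n_sets: int,
    genes_per_set: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[PriorKnowledgeMatrix, list[tuple[str, str]]]:
    """Generate a binary membership matrix plus a two-level set hierarchy.

    Sets are paired into siblings ``(0,1), (2,3), ...``; each sibling shares
    ``round(overlap_fraction * genes_per_set)`` genes with its partner (for an
    odd number of sets the last set shares with its predecessor).  Every set is
    a leaf under one synthetic parent node, giving a two-level hierarchy for
    exercising leaf filters.

    Returns the prior matrix and the hierarchy as ``(parent, child)`` edges.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if n_sets < 1 or genes_per_set < 1:
        raise ValueError("n_sets and genes_per_set must be positive")
    shared = int(round(overlap_fraction * genes_per_set))
    if shared >= genes_per_set:
        raise ValueError("overlap_fraction leaves no exclusive genes per set")

    # Which sets borrow their shared genes from the previous set.
    def borrows(i: int) -> bool:
        if i == 0:
            return False
        return i % 2 == 1 or (i == n_sets - 1 and n_sets % 2 == 1)

    n_borrowing = sum(borrows(i) for i in range(n_sets)) if shared > 0 else 0
    fresh_needed = n_sets * genes_per_set - n_borrowing * shared
    if fresh_needed > n_genes:
        raise ValueError(
            f"infeasible sizing: {n_sets} sets x {genes_per_set} genes with "
            f"overlap {overlap_fraction} need {fresh_needed} distinct genes "
            f"but only {n_genes} are available"
        )

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    set_ids = [f"SET{j:03d}" for j in range(n_sets)]
    pool = rng.permutation(n_genes)
    ptr = 0
    membership = np.zeros((n_genes, n_sets))
    fresh_of: list[np.ndarray] = []
    for j in range(n_sets):
        take = shared if (shared > 0 and borrows(j)) else 0
        if take:
            inherited = fresh_of[j - 1][:take]
        else:
            inherited = np.empty(0, dtype=int)
        fresh = pool[ptr : ptr + genes_per_set - take]
        ptr += genes_per_set - take
        fresh_of.append(fresh)
        membership[np.concatenate([inherited, fresh]).astype(int), j] = 1.0

    parents = [f"PARENT{j // 2:03d}" for j in range(n_sets)]
    hierarchy = [(parents[j], set_ids[j]) for j in range(n_sets)]
    prior = PriorKnowledgeMatrix(
        membership=membership,
        gene_ids=gene_ids,
        set_ids=set_ids,
        set_provenance={s: "synthetic" for s in set_ids},
    )
    return prior, hierarchy


def sibling_of(i: int, n_sets: int) -> int | None:
    """The sibling set index used by :func:`generate_prior`'s overlap rule."""
    if n_sets < 2:
        return None
    if i == n_sets - 1 and n_sets % 2 == 1:
        return i - 1
    return i + 1 if i % 2 == 0 else i - 1


def generate_compendium(
    prior: PriorKnowledgeMatrix,
    n_lvs: int,
    n_prior_aligned: int,
    studies: int,
    samples_per_study: int,
    noise_sd: float = 0.5,
    study_effects: Mapping[str, StudyEffect] | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a multi-study compendium ``Y = Z_true B_true + eps``.

    The first ``n_prior_aligned`` LV columns of ``Z_true`` are supported on
    gene sets ``0 .. n_prior_aligned-1`` of ``prior`` (loading 1.0 on member
    genes, small Gaussian background elsewhere); remaining columns are dense
    Gaussian, rescaled to the same column norm so all LVs carry comparable
    signal.  ``B_true`` rows are iid standard normal except for rows named in
    ``study_effects``, which get an additive shift in the stated study and
    condition.  Half of every study's samples are labeled ``control``, half
    ``case``.
    """
    if n_prior_aligned > min(n_lvs, prior.n_sets):
        raise ValueError(
            f"n_prior_aligned={n_prior_aligned} exceeds min(n_lvs={n_lvs}, "
            f"n_sets={prior.n_sets})"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    study_effects = dict(study_effects or {})
    study_ids = [f"STUDY{k:03d}" for k in range(studies)]
    for sid, eff in study_effects.items():
        if sid not in study_ids:
            raise KeyError(f"study_effects references unknown study id {sid!r}")
        if not 0 <= eff.lv < n_lvs:
            raise ValueError(f"study effect LV index {eff.lv} out of range")
        if eff.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {eff.condition!r}")

    rng = np.random.default_rng(seed)
    n_genes = prior.n_genes

    Z = np.zeros((n_genes, n_lvs))
    mean_set_size = float(prior.set_sizes().mean()) if prior.n_sets else 10.0
    target_norm = np.sqrt(mean_set_size) * ALIGNED_LOADING
    for l in range(n_lvs):
        if l < n_prior_aligned:
            col = rng.normal(0.0, BACKGROUND_SD, size=n_genes)
            members = prior.membership[:, l] > 0
            col[members] = ALIGNED_LOADING
        else:
            col = rng.normal(0.0, 1.0, size=n_genes)
            col *= target_norm / np.linalg.norm(col)
        Z[:, l] = col

    n_samples = studies * samples_per_study
    B = rng.normal(0.0, 1.0, size=(n_lvs, n_samples))

    sample_ids, study_col, cond_col = [], [], []
    for k, sid in enumerate(study_ids):
        for s in range(samples_per_study):
            sample_ids.append(f"{sid}_S{s:03d}")
            study_col.append(sid)
            cond_col.append(CONDITIONS[0] if s < samples_per_study // 2 else CONDITIONS[1])
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "study_id": study_col,
            "condition": cond_col,
            "age_months": rng.choice(COMPENDIUM_AGES, size=n_samples),
            "cell_type": rng.choice(CELL_TYPES, size=n_samples),
        }
    )

    for sid, eff in study_effects.items():
        mask = ((meta["study_id"] == sid) & (meta["condition"] == eff.condition)).to_numpy()
        B[eff.lv, mask] += eff.shift

    Y = Z @ B
    if noise_sd > 0:
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)

    # U_true: one dominant set per aligned LV.
    U_true = np.zeros((prior.n_sets, n_lvs))
    for l in range(n_prior_aligned):
        U_true[l, l] = 1.0

    expr = ExpressionMatrix(
        values=Y, gene_ids=list(prior.gene_ids), sample_ids=sample_ids, state=ZSCORED
    )
    truth = SyntheticTruth(
        Z_true=Z,
        B_true=B,
        U_true=U_true,
        prior_aligned_lvs=list(range(n_prior_aligned)),
        study_effect_map=study_effects,
        age_effect_map={},
        noise_sd=noise_sd,
        seed=seed,
        gene_ids=list(prior.gene_ids),
        set_ids=list(prior.set_ids),
    )
    return expr, meta, truth


def generate_target_study(
    Z_true: np.ndarray,
    gene_ids: Sequence[str],
    ages: Sequence[float],
    replicates_per_age: int,
    strata: Sequence[str] = ("WT",),
    age_effect_map: Mapping[int, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    cell_type: str = "bulk",
) -> tuple[ExpressionMatrix, pd.DataFrame, TargetTruth]:
    """Generate a held-out study with planted linear age trends on chosen LVs.

    For each stratum the same design is repeated: ``replicates_per_age``
    samples at each age (in months).  LVs named in ``age_effect_map`` have
    latent expression ``slope * age + Normal(0, noise_sd)``; every other LV is
    pure ``Normal(0, noise_sd)`` noise.  Expression is emitted in gene space
    as ``Z_true @ B``.
    """
    Z_true = np.asarray(Z_true, dtype=float)
    ages = [float(a) for a in ages]
    if len(set(ages)) < 3:
        raise ValueError("need at least 3 distinct age values for a testable slope")
    n_per_stratum = len(ages) * replicates_per_age
    n_samples = n_per_stratum * len(strata)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    age_effect_map = {int(k): float(v) for k, v in (age_effect_map or {}).items()}
    n_lvs = Z_true.shape[1]
    for lv in age_effect_map:
        if not 0 <= lv < n_lvs:
            raise ValueError(f"age effect LV index {lv} out of range for {n_lvs} LVs")

    rng = np.random.default_rng(seed)
    age_vec = np.array([a for a in ages for _ in range(replicates_per_age)] * len(strata))
    B = rng.normal(0.0, noise_sd, size=(n_lvs, n_samples)) if noise_sd > 0 else np.zeros((n_lvs, n_samples))
    for lv, slope in age_effect_map.items():
        B[lv, :] += slope * age_vec

    sample_ids, cond_col = [], []
    for stratum in strata:
        for a in ages:
            for r in range(replicates_per_age):
                sample_ids.append(f"TGT_{stratum}_A{a:g}_R{r}")
                cond_col.append(stratum)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "study_id": "TARGET",
            "condition": cond_col,
            "age_months": age_vec,
            "cell_type": cell_type,
        }
    )
    expr = ExpressionMatrix(
        values=Z_true @ B, gene_ids=list(gene_ids), sample_ids=sample_ids, state=ZSCORED
    )
    truth = TargetTruth(B_true=B, age_effect_map=age_effect_map, noise_sd=noise_sd, seed=seed)
    return expr, meta, truth
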