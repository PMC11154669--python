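"""Data preparation: gene intersection, TPM normalization, z-scoring, prior matrix.

The training pipeline expects a gene-by-sample matrix restricted to the genes
covered by prior knowledge, normalized to transcripts per million (TPM) when
starting from raw counts, and z-scored per gene so every gene contributes on a
comparable scale.  The prior matrix is built from GMT-style gene sets with a
minimum-size filter (counting genes *present in the expression universe*) and
an optional leaf-only filter over a pathway parent->child hierarchy.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .containers import (
    RAW_COUNTS,
    TPM,
    ZSCORED,
    ExpressionMatrix,
    PriorKnowledgeMatrix,
)
from .io import GeneSet


def intersect_genes(
    expr: ExpressionMatrix, prior: PriorKnowledgeMatrix
) -> tuple[ExpressionMatrix, PriorKnowledgeMatrix]:
    """Restrict both matrices to their shared genes, in ``expr``'s gene order."""
    if expr.n_genes == 0 or prior.n_genes == 0:
        raise ValueError("cannot intersect empty inputs")
    prior_genes = set(prior.gene_ids)
    shared = [g for g in expr.gene_ids if g in prior_genes]
    if not shared:
        raise ValueError(
            f"no shared genes between expression ({expr.n_genes} genes) and "
            f"prior knowledge ({prior.n_genes} genes)"
        )
    if shared == expr.gene_ids and shared == prior.gene_ids:
        return expr, prior
    return expr.subset_genes(shared), prior.subset_genes(shared)


def tpm_normalize(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million using gene lengths (bases).

    Per sample, ``rate_g = count_g / length_g`` and
    ``tpm_g = 1e6 * rate_g / sum_g rate_g`` so every column sums to ``1e6``.
    """
    if counts.state != RAW_COUNTS:
        raise ValueError(f"tpm_normalize expects raw counts, got state {counts.state!r}")
    missing = [g for g in counts.gene_ids if g not in gene_lengths]
    if missing:
        raise ValueError(f"missing gene lengths for: {missing[:10]}")
    lengths = np.array([float(gene_lengths[g]) for g in counts.gene_ids])
    bad = [g for g, ln in zip(counts.gene_ids, lengths) if ln <= 0]
    if bad:
        raise ValueError(f"nonpositive gene lengths for: {bad[:10]}")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")

    rate = counts.values / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero_cols = [s for s, c in zip(counts.sample_ids, colsum) if c == 0]
    if zero_cols:
        raise ValueError(f"all-zero count columns (TPM undefined) for samples: {zero_cols}")
    tpm = 1e6 * rate / colsum
    return ExpressionMatrix(tpm, list(counts.gene_ids), list(counts.sample_ids), TPM)


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise ``log2(x + pseudocount)``, keeping the declared state."""
    if (expr.values + pseudocount <= 0).any():
        raise ValueError("log transform undefined: values + pseudocount not positive")
    return ExpressionMatrix(
        np.log2(expr.values + pseudocount),
        list(expr.gene_ids),
        list(expr.sample_ids),
        expr.state,
    )


def zscore_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sd 1 (sample sd, n-1 denominator).

    Constant rows cannot be standardized; they become all-zero rows (keeping
    gene indexing aligned with the prior matrix) and a ``UserWarning`` lists
    them.
    """
    if expr.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (expr.values - mean) / safe_sd
    if constant.any():
        genes = [g for g, c in zip(expr.gene_ids, constant) if c]
        z[constant, :] = 0.0
        warnings.warn(
            f"{len(genes)} constant gene row(s) set to zero after z-scoring: "
            f"{genes[:10]}",
            UserWarning,
            stacklevel=2,
        )
    return ExpressionMatrix(z, list(expr.gene_ids), list(expr.sample_ids), ZSCORED)


def _check_acyclic(edges: Iterable[tuple[str, str]]) -> None:
    children: dict[str, list[str]] = {}
    for parent, child in edges:
        children.setdefault(parent, []).append(child)
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str) -> None:
        color[node] = GRAY
        stack = [(node, iter(children.get(node, ())))]
        while stack:
            current, it = stack[-1]
            advanced = False
            for nxt in it:
                c = color.get(nxt, WHITE)
                if c == GRAY:
                    raise ValueError(f"cyclic pathway hierarchy at node {nxt!r}")
                if c == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, iter(children.get(nxt, ()))))
                    advanced = True
                    break
            if not advanced:
                color[current] = BLACK
                stack.pop()

    for node in list(children):
        if color.get(node, WHITE) == WHITE:
            visit(node)


def build_prior_matrix(
    gene_sets: Sequence[GeneSet],
    gene_universe: Sequence[str],
    hierarchy: Sequence[tuple[str, str]] | None = None,
    min_genes: int = 5,
    leaf_only: bool = True,
) -> tuple[PriorKnowledgeMatrix, dict[str, str]]:
    """Build the binary membership matrix over ``gene_universe``.

    Sets are dropped when fewer than ``min_genes`` of their genes are present
    in ``gene_universe``, or (with ``leaf_only``) when they have any child in
    ``hierarchy``.  Returns the prior matrix and a ``{set_name: reason}`` map
    of dropped sets.
    """
    names = [gs.name for gs in gene_sets]
    if len(set(names)) != len(names):
        raise ValueError("gene set names must be unique")
    hierarchy = list(hierarchy or [])
    _check_acyclic(hierarchy)
    non_leaves = {parent for parent, _ in hierarchy}

    universe = list(gene_universe)
    gene_index = {g: i for i, g in enumerate(universe)}
    kept: list[GeneSet] = []
    dropped: dict[str, str] = {}
    for gs in gene_sets:
        present = [g for g in gs.genes if g in gene_index]
        if leaf_only and gs.name in non_leaves:
            dropped[gs.name] = "not a leaf in the pathway hierarchy"
        elif len(present) < min_genes:
            dropped[gs.name] = (
                f"only {len(present)} member genes present (min_genes={min_genes})"
            )
        else:
            kept.append(GeneSet(gs.name, gs.description, present))

    membership = np.zeros((len(universe), len(kept)))
    for j, gs in enumerate(kept):
        for g in gs.genes:
            membership[gene_index[g], j] = 1.0
    prior = PriorKnowledgeMatrix(
        membership=membership,
        gene_ids=universe,
        set_ids=[gs.name for gs in kept],
        set_provenance={gs.name: gs.description for gs in kept},
    )
    return prior, dropped
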