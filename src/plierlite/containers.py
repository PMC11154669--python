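"""Core in-memory containers for expression data and prior knowledge.

The two matrices that anchor the pipeline are a gene-by-sample expression
matrix ``Y`` and a binary gene-by-gene-set membership matrix ``C``.  Both are
carried as thin dataclasses around NumPy arrays with explicit, ordered
identifier lists so every downstream stage can align genes by id rather than
by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised normalization states of an :class:`ExpressionMatrix`.
RAW_COUNTS = "raw_counts"
TPM = "tpm"
ZSCORED = "zscored"
STATES = (RAW_COUNTS, TPM, ZSCORED)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))[:10]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with a declared normalization state.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_samples)`` array.
    gene_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    state
        One of ``"raw_counts"``, ``"tpm"`` or ``"zscored"``.  The exact
        per-row moment guarantee of the z-scored state is established by
        :func:`plierlite.preprocess.zscore_genes`; the constructor checks
        shapes and id uniqueness only.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    state: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, state: str) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            state=state,
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` (which must all be present), in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None
        return replace(self, values=self.values[rows], gene_ids=list(gene_ids))


@dataclass
class PriorKnowledgeMatrix:
    """Binary gene-by-gene-set membership matrix (the prior matrix ``C``)."""

    membership: np.ndarray
    gene_ids: list[str]
    set_ids: list[str]
    set_provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        if self.membership.ndim != 2:
            raise ValueError("membership must be a 2-D genes x sets array")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.set_ids = _check_unique(self.set_ids, "gene-set")
        if self.membership.shape != (len(self.gene_ids), len(self.set_ids)):
            raise ValueError(
                f"membership shape {self.membership.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.set_ids)} sets"
            )
        bad = ~np.isin(self.membership, (0.0, 1.0))
        if bad.any():
            raise ValueError("membership must be binary (0/1)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_sets(self) -> int:
        return len(self.set_ids)

    def set_sizes(self) -> np.ndarray:
        return self.membership.sum(axis=0).astype(int)

    def genes_of(self, set_id: str) -> list[str]:
        j = self.set_ids.index(set_id)
        return [g for g, m in zip(self.gene_ids, self.membership[:, j]) if m > 0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.membership, index=self.gene_ids, columns=self.set_ids)
        df.index.name = "gene_id"
        return df

    def subset_genes(self, gene_ids: Sequence[str]) -> "PriorKnowledgeMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in gene_ids]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in prior matrix") from None
        return PriorKnowledgeMatrix(
            membership=self.membership[rows],
            gene_ids=list(gene_ids),
            set_ids=list(self.set_ids),
            set_provenance=dict(self.set_provenance),
        )
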