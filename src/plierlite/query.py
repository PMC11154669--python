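"""Query training studies by how cleanly one LV splits their samples.

For a chosen latent variable, each training study's samples are clustered
into two groups on that LV's values (exact one-dimensional 2-means by a
sorted-split scan) and studies are ranked by mean silhouette score, surfacing
experiments in which some condition moves the latent variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .plier import PlierModel


def kmeans_two(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Exact 2-means on one-dimensional data.

    In one dimension the optimal 2-partition is contiguous in sorted order,
    so scanning all ``n - 1`` sorted split points finds the global minimum of
    the within-cluster sum of squares — no random restarts, no seed.  Returns
    ``(labels, (low_mean, high_mean))`` with label 0 for the lower cluster;
    ties in the split objective break toward the smallest low cluster.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D array of at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("all values identical; 2-means is degenerate")
    order = np.argsort(values, kind="stable")
    x = values[order]
    n = x.size
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total_sum, total_sq = csum[-1], csq[-1]
    splits = np.arange(1, n)          # size of the low cluster
    low_ss = csq[:-1] - csum[:-1] ** 2 / splits
    high_ss = (total_sq - csq[:-1]) - (total_sum - csum[:-1]) ** 2 / (n - splits)
    wcss = low_ss + high_ss
    t = int(splits[np.argmin(wcss)])
    labels = np.zeros(n, dtype=int)
    labels[order[t:]] = 1
    low_mean = float(csum[t - 1] / t)
    high_mean = float((total_sum - csum[t - 1]) / (n - t))
    return labels, (low_mean, high_mean)


def silhouette(values, labels) -> float:
    """Mean silhouette score for a 2-clustering of one-dimensional values.

    Per sample ``i``: ``a(i)`` is the mean absolute difference to co-members,
    ``b(i)`` the mean to the other cluster, and
    ``s(i) = (b - a) / max(a, b)``.  Conventions: ``s(i) = 0`` for members of
    singleton clusters and when ``max(a, b) = 0``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 clusters, got {uniq.size}")
    scores = np.empty(values.size)
    for i in range(values.size):
        own = (labels == labels[i])
        own[i] = False
        other = labels != labels[i]
        if not own.any():              # singleton cluster
            scores[i] = 0.0
            continue
        a = float(np.mean(np.abs(values[own] - values[i])))
        b = float(np.mean(np.abs(values[other] - values[i])))
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


@dataclass
class StudyClusterResult:
    study_id: str
    silhouette: float
    rank: int
    labels: dict[str, int]
    cluster_sizes: tuple[int, int]
    cluster_means: tuple[float, float]


@dataclass
class StudyRanking:
    """Ranked 2-cluster separations of training studies on one LV."""

    lv_id: str
    entries: list[StudyClusterResult]
    top_n: int
    excluded: dict[str, str] = field(default_factory=dict)

    def top(self) -> list[StudyClusterResult]:
        return self.entries[: self.top_n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": e.rank,
                    "study_id": e.study_id,
                    "silhouette": e.silhouette,
                    "n_samples": len(e.labels),
                    "cluster_sizes": f"{e.cluster_sizes[0]}|{e.cluster_sizes[1]}",
                }
                for e in self.entries
            ]
        )


def rank_studies(
    model: PlierModel | np.ndarray,
    study_map: Mapping[str, str] | pd.Series,
    lv_id: str | int,
    top_n: int = 10,
    min_samples: int = 4,
    sample_ids: list[str] | None = None,
) -> StudyRanking:
    """Rank studies by silhouette of the 2-means split on one LV's values.

    ``study_map`` maps sample id -> study id and must cover every sample.
    Studies with fewer than ``min_samples`` samples, or with all-identical
    values on the LV, are excluded (with a reason).  Ties in silhouette break
    lexicographically by study id; ranks are 1..N.  ``entries`` holds every
    eligible study; ``top()`` returns the first ``top_n``.
    """
    if isinstance(model, PlierModel):
        idx = model.lv_index(lv_id)
        row = model.B[idx]
        sample_ids = model.sample_ids
        lv_label = model.lv_ids[idx]
    else:
        B = np.asarray(model, dtype=float)
        idx = int(lv_id)
        if not 0 <= idx < B.shape[0]:
            raise KeyError(f"LV index {idx} out of range")
        row = B[idx]
        if sample_ids is None:
            raise ValueError("sample_ids required when passing a bare matrix")
        lv_label = f"LV{idx + 1}"
    if isinstance(study_map, pd.Series):
        study_map = study_map.to_dict()
    missing = [s for s in sample_ids if s not in study_map]
    if missing:
        raise ValueError(f"samples missing from study_map: {missing[:10]}")

    by_study: dict[str, list[int]] = {}
    for i, s in enumerate(sample_ids):
        by_study.setdefault(str(study_map[s]), []).append(i)

    excluded: dict[str, str] = {}
    scored: list[StudyClusterResult] = []
    for study in sorted(by_study):
        cols = by_study[study]
        vals = row[cols]
        if len(cols) < min_samples:
            excluded[study] = f"only {len(cols)} samples (min_samples={min_samples})"
            continue
        if np.ptp(vals) == 0:
            excluded[study] = "degenerate: all LV values identical"
            continue
        labels, means = kmeans_two(vals)
        score = silhouette(vals, labels)
        scored.append(
            StudyClusterResult(
                study_id=study,
                silhouette=score,
                rank=0,
                labels={sample_ids[c]: int(l) for c, l in zip(cols, labels)},
                cluster_sizes=(int(np.sum(labels == 0)), int(np.sum(labels == 1))),
                cluster_means=means,
            )
        )
    scored.sort(key=lambda e: (-e.silhouette, e.study_id))
    for r, entry in enumerate(scored, start=1):
        entry.rank = r
    return StudyRanking(lv_id=lv_label, entries=scored, top_n=top_n, excluded=excluded)
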