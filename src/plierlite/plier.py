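"""Prior-constrained matrix factorization of an expression compendium.

Given a z-scored gene-by-sample matrix ``Y`` and a binary gene-by-gene-set
prior matrix ``C``, the model finds loadings ``Z`` (genes x LVs), a latent
representation ``B`` (LVs x samples) and a nonnegative gene-set assignment
``U`` (gene sets x LVs) minimizing the four-term objective

    ||Y - Z B||_F^2  +  lambda1 ||Z - C U||_F^2
                     +  lambda2 ||B||_F^2  +  lambda3 ||U||_L1 .

The reconstruction term keeps the factorization faithful to the data; the
``lambda1`` term pulls each LV's loading pattern toward a sparse nonnegative
combination of prior gene sets; the ridge on ``B`` keeps any single LV from
absorbing too much variance; the L1 on ``U`` keeps each LV associated with
only a few gene sets.

Optimization is block coordinate descent.  ``B`` and ``Z`` have closed-form
ridge solutions; each column of ``U`` is solved by exact coordinate descent on
a (optionally nonnegative) lasso.  Starting from a truncated-SVD
initialization with ``U = 0``, each full ``U -> Z -> B`` cycle can only lower
the objective (when negative-loading clipping is off), so the recorded
objective trace is non-increasing.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, PriorKnowledgeMatrix


def _as_2d(name: str, arr) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class PlierConfig:
    """Hyper-parameters of the factorization.

    ``None`` penalties are resolved from the data scale at fit time:
    ``lambda1 = sigma_L / 2`` and ``lambda2 = sigma_L`` where ``sigma_L`` is
    the L-th singular value of ``Y`` (the scale the SVD initialization gives
    the smallest latent dimension), and ``lambda3`` is chosen by a short path
    search over pilot fits so that roughly half the LVs keep at least one
    gene set.
    """

    n_lvs: int | str = "auto"
    lambda1: float | None = None
    lambda2: float | None = None
    lambda3: float | None = None
    max_iterations: int = 350
    rel_tolerance: float = 1e-6
    enforce_nonneg_U: bool = True
    clip_negative_Z: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lvs != "auto":
            self.n_lvs = int(self.n_lvs)
            if self.n_lvs < 1:
                raise ValueError("n_lvs must be positive or 'auto'")
        for name in ("lambda1", "lambda2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lambda3 is not None and self.lambda3 < 0:
            raise ValueError("lambda3 must be nonnegative")
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be positive")


@dataclass
class PlierModel:
    """A fitted model: loadings, latent representation and gene-set assignment."""

    Z: np.ndarray
    B: np.ndarray
    U: np.ndarray
    config: PlierConfig
    objective_trace: list[float]
    gene_ids: list[str]
    sample_ids: list[str]
    set_ids: list[str]

    @property
    def n_lvs(self) -> int:
        return self.Z.shape[1]

    @property
    def lv_ids(self) -> list[str]:
        return [f"LV{i + 1}" for i in range(self.n_lvs)]

    def lv_index(self, lv_id: str | int) -> int:
        if isinstance(lv_id, (int, np.integer)):
            idx = int(lv_id)
            if not 0 <= idx < self.n_lvs:
                raise KeyError(f"LV index {idx} out of range (model has {self.n_lvs} LVs)")
            return idx
        try:
            return self.lv_ids.index(str(lv_id))
        except ValueError:
            raise KeyError(f"unknown LV id {lv_id!r}") from None


def objective(Y, C, Z, B, U, lambda1: float, lambda2: float, lambda3: float) -> float:
    """Evaluate the four-term objective for given factors."""
    Y, C, Z, B, U = (_as_2d(n, a) for n, a in
                     zip(("Y", "C", "Z", "B", "U"), (Y, C, Z, B, U)))
    if Z.shape[1] != B.shape[0]:
        raise ValueError(f"Z {Z.shape} and B {B.shape} are not conformable")
    if Y.shape != (Z.shape[0], B.shape[1]):
        raise ValueError(f"Y {Y.shape} does not match Z B {(Z.shape[0], B.shape[1])}")
    if C.shape[1] != U.shape[0]:
        raise ValueError(f"C {C.shape} and U {U.shape} are not conformable")
    if (C.shape[0], U.shape[1]) != Z.shape:
        raise ValueError(f"C U {(C.shape[0], U.shape[1])} does not match Z {Z.shape}")
    recon = Y - Z @ B
    align = Z - C @ U
    return float(
        np.sum(recon * recon)
        + lambda1 * np.sum(align * align)
        + lambda2 * np.sum(B * B)
        + lambda3 * np.sum(np.abs(U))
    )


def init_factors(Y, n_lvs: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-SVD initialization: ``Z0 = U_L S_L``, ``B0 = V_L^T``.

    ``Z0 @ B0`` is the best rank-``n_lvs`` approximation of ``Y``.
    """
    Y = _as_2d("Y", Y)
    if n_lvs > min(Y.shape):
        raise ValueError(f"n_lvs={n_lvs} exceeds min(Y.shape)={min(Y.shape)}")
    U_, s, Vt = np.linalg.svd(Y, full_matrices=False)
    return U_[:, :n_lvs] * s[:n_lvs], Vt[:n_lvs]


def select_num_lvs(Y, edge_inflation: float = 1.05, max_rounds: int = 100) -> int:
    """Estimate the number of latent dimensions from the singular spectrum.

    Counts singular values above a Marchenko-Pastur-style bulk edge
    ``sigma_hat (sqrt(n) + sqrt(m))``, where ``sigma_hat`` is the residual
    noise level re-estimated from the singular values below the current
    threshold (iterated to a fixed point).  A relative floor of ``1e-8`` times
    the leading singular value guards the noiseless case.  Deterministic for
    fixed ``Y``.
    """
    Y = _as_2d("Y", Y)
    n, m = Y.shape
    if m < 10:
        raise ValueError("need at least 10 samples to estimate the rank")
    s = np.linalg.svd(Y, compute_uv=False)
    if s[0] == 0:
        return 0
    r = 0
    for _ in range(max_rounds):
        resid = float(np.sum(s[r:] ** 2))
        sigma = np.sqrt(resid / (n * m))
        threshold = max(edge_inflation * sigma * (np.sqrt(n) + np.sqrt(m)),
                        1e-8 * s[0])
        r_new = int(np.sum(s > threshold))
        if r_new == r:
            break
        r = r_new
    return r


def update_B(Y, Z, lambda2: float) -> np.ndarray:
    """Closed-form ridge solution ``B = (Z^T Z + lambda2 I)^-1 Z^T Y``."""
    Y, Z = _as_2d("Y", Y), _as_2d("Z", Z)
    if Y.shape[0] != Z.shape[0]:
        raise ValueError(f"Y {Y.shape} and Z {Z.shape} have different gene counts")
    L = Z.shape[1]
    A = Z.T @ Z + lambda2 * np.eye(L)
    if lambda2 == 0 and np.linalg.matrix_rank(Z.T @ Z) < L:
        raise np.linalg.LinAlgError(
            "Z^T Z is singular with lambda2=0; use a strictly positive lambda2"
        )
    return np.linalg.solve(A, Z.T @ Y)


def update_Z(Y, B, C, U, lambda1: float, clip_negative: bool = False) -> np.ndarray:
    """Closed-form solution ``Z = (Y B^T + lambda1 C U)(B B^T + lambda1 I)^-1``."""
    Y, B, C, U = (_as_2d(n, a) for n, a in zip(("Y", "B", "C", "U"), (Y, B, C, U)))
    L = B.shape[0]
    M = B @ B.T + lambda1 * np.eye(L)
    rhs = Y @ B.T + lambda1 * (C @ U)
    Z = np.linalg.solve(M.T, rhs.T).T
    if clip_negative:
        np.maximum(Z, 0.0, out=Z)
    return Z


def update_U(
    Z,
    C,
    lambda1: float,
    lambda3: float,
    enforce_nonneg: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Exact coordinate descent on the (nonnegative) lasso, one LV at a time.

    For each LV column ``z`` of ``Z``, minimizes
    ``lambda1 ||z - C u||^2 + lambda3 ||u||_1`` (subject to ``u >= 0`` when
    ``enforce_nonneg``).  Each coordinate step is the exact one-dimensional
    minimizer (soft-thresholding, clipped at zero under the constraint);
    sweeps repeat until the largest coordinate change falls below ``tol``
    relative to the solution scale.  All columns are updated simultaneously
    since the problem is separable across LVs.
    """
    Z, C = _as_2d("Z", Z), _as_2d("C", C)
    if Z.shape[0] != C.shape[0]:
        raise ValueError(f"Z {Z.shape} and C {C.shape} have different gene counts")
    k, L = C.shape[1], Z.shape[1]
    G = C.T @ C                      # (k, k) Gram matrix
    R = C.T @ Z                      # (k, L)
    colnorm = np.diag(G).copy()
    dead = colnorm == 0
    if dead.any():
        names = np.flatnonzero(dead).tolist()
        warnings.warn(
            f"{int(dead.sum())} all-zero gene-set column(s) in C (indices "
            f"{names[:10]}); their U rows are forced to 0",
            UserWarning,
            stacklevel=2,
        )
    threshold = lambda3 / (2.0 * lambda1)
    U = np.zeros((k, L))
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(k):
            if dead[j]:
                continue
            # rho = C_j^T (z - C u + C_j u_j), vectorized over LV columns
            rho = R[j] - G[j] @ U + colnorm[j] * U[j]
            if enforce_nonneg:
                new = np.maximum(0.0, rho - threshold) / colnorm[j]
            else:
                new = np.sign(rho) * np.maximum(0.0, np.abs(rho) - threshold) / colnorm[j]
            max_delta = max(max_delta, float(np.max(np.abs(new - U[j]))))
            U[j] = new
        scale = max(1.0, float(np.max(np.abs(U)))) if U.size else 1.0
        if max_delta <= tol * scale:
            break
    return U


def _block_descent(
    Y: np.ndarray,
    C: np.ndarray,
    Z: np.ndarray,
    B: np.ndarray,
    lambda1: float,
    lambda2: float,
    lambda3: float,
    max_iterations: int,
    rel_tolerance: float,
    enforce_nonneg_U: bool,
    clip_negative_Z: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Cycle ``U -> Z -> B`` from the given ``(Z, B)`` with ``U = 0``."""
    U = np.zeros((C.shape[1], Z.shape[1]))
    trace = [objective(Y, C, Z, B, U, lambda1, lambda2, lambda3)]
    for _ in range(max_iterations):
        U = update_U(Z, C, lambda1, lambda3, enforce_nonneg=enforce_nonneg_U)
        Z = update_Z(Y, B, C, U, lambda1, clip_negative=clip_negative_Z)
        B = update_B(Y, Z, lambda2)
        current = objective(Y, C, Z, B, U, lambda1, lambda2, lambda3)
        previous = trace[-1]
        trace.append(current)
        if abs(previous - current) <= rel_tolerance * max(abs(previous), 1e-300):
            break
    return Z, B, U, trace


#: lambda3 path-search grid, as multiples of lambda1 (sparsest first).
_LAMBDA3_GRID = (40.0, 20.0, 10.0, 5.0, 2.0)
_PILOT_ITERATIONS = 40


def _resolve_penalties(
    config: PlierConfig,
    s: np.ndarray,
    n_lvs: int,
    Y: np.ndarray,
    C: np.ndarray,
    Z0: np.ndarray,
    B0: np.ndarray,
) -> tuple[float, float, float]:
    sigma_L = float(s[n_lvs - 1])
    lambda1 = config.lambda1 if config.lambda1 is not None else sigma_L / 2.0
    lambda2 = config.lambda2 if config.lambda2 is not None else sigma_L
    if config.lambda3 is not None:
        return lambda1, lambda2, config.lambda3
    if C.size == 0:
        return lambda1, lambda2, lambda1
    # Path search, sparsest first: run a short pilot fit per candidate and
    # keep the largest lambda3 for which at least half the LVs stay attached
    # to >= 1 gene set; fall back to the densest candidate.
    chosen = _LAMBDA3_GRID[-1] * lambda1
    for mult in _LAMBDA3_GRID:
        lam3 = mult * lambda1
        _, _, U_pilot, _ = _block_descent(
            Y, C, Z0.copy(), B0.copy(), lambda1, lambda2, lam3,
            _PILOT_ITERATIONS, config.rel_tolerance,
            config.enforce_nonneg_U, config.clip_negative_Z,
        )
        attached = int(np.sum((U_pilot > 1e-8).any(axis=0)))
        if attached >= n_lvs / 2.0:
            chosen = lam3
            break
    return lambda1, lambda2, float(chosen)


def fit(
    Y: ExpressionMatrix | np.ndarray,
    C: PriorKnowledgeMatrix | np.ndarray,
    config: PlierConfig | None = None,
    gene_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
    set_ids: Sequence[str] | None = None,
) -> PlierModel:
    """Fit the factorization by block coordinate descent.

    ``Y`` should be z-scored with its gene rows aligned to ``C``'s.  The
    solver initializes ``(Z, B)`` from the truncated SVD with ``U = 0``, then
    cycles ``U -> Z -> B`` updates, recording the objective after every full
    cycle, until the relative objective change drops below
    ``config.rel_tolerance`` or ``config.max_iterations`` cycles.
    """
    config = config if config is not None else PlierConfig()
    if isinstance(Y, ExpressionMatrix):
        gene_ids = list(Y.gene_ids)
        sample_ids = list(Y.sample_ids)
        Y_arr = Y.values
    else:
        Y_arr = _as_2d("Y", Y)
    if isinstance(C, PriorKnowledgeMatrix):
        if gene_ids is not None and list(C.gene_ids) != list(gene_ids):
            raise ValueError("gene rows of Y and C are not aligned; run intersect_genes first")
        set_ids = list(C.set_ids)
        C_arr = C.membership
    else:
        C_arr = _as_2d("C", C)
    if Y_arr.shape[0] != C_arr.shape[0]:
        raise ValueError(f"Y has {Y_arr.shape[0]} genes but C has {C_arr.shape[0]}")
    if not np.isfinite(Y_arr).all():
        raise ValueError("Y contains non-finite values")
    gene_ids = list(gene_ids) if gene_ids is not None else [f"G{i:05d}" for i in range(Y_arr.shape[0])]
    sample_ids = list(sample_ids) if sample_ids is not None else [f"S{i:05d}" for i in range(Y_arr.shape[1])]
    set_ids = list(set_ids) if set_ids is not None else [f"SET{j:03d}" for j in range(C_arr.shape[1])]

    s = np.linalg.svd(Y_arr, compute_uv=False)
    n_lvs = select_num_lvs(Y_arr) if config.n_lvs == "auto" else int(config.n_lvs)
    n_lvs = max(1, min(n_lvs, min(Y_arr.shape)))

    Z0, B0 = init_factors(Y_arr, n_lvs)
    lambda1, lambda2, lambda3 = _resolve_penalties(
        config, s, n_lvs, Y_arr, C_arr, Z0, B0
    )
    resolved = dataclasses.replace(
        config, n_lvs=n_lvs, lambda1=lambda1, lambda2=lambda2, lambda3=lambda3
    )
    Z, B, U, trace = _block_descent(
        Y_arr, C_arr, Z0, B0, lambda1, lambda2, lambda3,
        config.max_iterations, config.rel_tolerance,
        config.enforce_nonneg_U, config.clip_negative_Z,
    )

    return PlierModel(
        Z=Z, B=B, U=U, config=resolved, objective_trace=trace,
        gene_ids=gene_ids, sample_ids=sample_ids, set_ids=set_ids,
    )


def lv_gene_sparsity(model: PlierModel, tolerance: float = 0.01) -> tuple[np.ndarray, float]:
    """Per-LV fraction of genes with |loading| below ``tolerance * max|column|``.

    Returns the per-LV fractions and their mean.  Columns that are entirely
    zero count as fully sparse.
    """
    absZ = np.abs(model.Z)
    colmax = absZ.max(axis=0)
    fractions = np.empty(model.n_lvs)
    for l in range(model.n_lvs):
        if colmax[l] == 0:
            fractions[l] = 1.0
        else:
            fractions[l] = float(np.mean(absZ[:, l] < tolerance * colmax[l]))
    return fractions, float(fractions.mean())


def lv_pathway_counts(model: PlierModel, u_threshold: float = 1e-6) -> np.ndarray:
    """Per-LV count of gene sets with assignment weight above ``u_threshold``."""
    return (model.U > u_threshold).sum(axis=0).astype(int)


def top_set_per_lv(model: PlierModel, u_threshold: float = 1e-6) -> list[str | None]:
    """The strongest-assigned gene set per LV (``None`` if no set passes).

    Exact ties in ``U`` are broken toward the lowest set index.
    """
    tops: list[str | None] = []
    for l in range(model.n_lvs):
        col = model.U[:, l]
        if col.size == 0 or col.max() <= u_threshold:
            tops.append(None)
        else:
            tops.append(model.set_ids[int(np.argmax(col))])
    return tops
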