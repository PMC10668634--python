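"""Non-negative matrix factorization by Lee-Seung multiplicative updates.

Minimizes the Frobenius reconstruction error ||V - W H||_F with the
classic multiplicative update rules, which provably never increase the
objective — a property the model records (``objective_trace``) and the
test suite asserts.  The best of ``n_restarts`` seeded random
initializations is kept.  Log-scale inputs with negative entries are made
nonnegative by subtracting the global minimum (logged) before fitting.

Used both to cluster study samples (argmax of each sample's factor
weights) and to build the reference decomposition behind the oncogenic
state map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

EPS = 1e-10

DEFAULT_RESTARTS = 20
DEFAULT_MAX_ITER = 2000
DEFAULT_TOL = 1e-6


@dataclass
class NMFModel:
    """Fitted factorization V ~ W H.

    ``W`` (genes x k) carries the factor scale; ``H`` (k x samples) holds
    the raw sample loadings of the best restart.  ``sample_weights`` is the
    column-L1-normalized view of H (each sample's weights sum to 1), the
    representation used for cluster assignment and map projection; column
    normalization is per-sample positive scaling, so argmax assignments are
    identical between the two views.
    """

    W: pd.DataFrame
    H: pd.DataFrame
    rank: int
    seed: int
    objective_trace: list[float] = field(default_factory=list)
    shift: float = 0.0

    def __post_init__(self) -> None:
        if (self.W.to_numpy() < 0).any() or (self.H.to_numpy() < 0).any():
            raise ValidationError("NMF factors must be nonnegative")
        trace = np.asarray(self.objective_trace)
        if trace.size and np.any(np.diff(trace) > 1e-9 * np.maximum(trace[:-1], 1.0)):
            raise ValidationError("objective trace is not non-increasing")

    @property
    def factor_names(self) -> list[str]:
        return list(self.W.columns)

    @property
    def sample_weights(self) -> pd.DataFrame:
        h = self.H.to_numpy()
        sums = h.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(sums > 0, h / sums, 0.0)
        return pd.DataFrame(norm, index=self.H.index, columns=self.H.columns)

    @property
    def reconstruction_error(self) -> float:
        return self.objective_trace[-1]


def _frobenius(v: np.ndarray, w: np.ndarray, h: np.ndarray) -> float:
    return float(np.linalg.norm(v - w @ h, "fro"))


def _multiplicative_fit(
    v: np.ndarray,
    w: np.ndarray,
    h: np.ndarray,
    max_iter: int,
    tol: float,
    update_w: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    trace = [_frobenius(v, w, h)]
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + EPS)
        if update_w:
            w *= (v @ h.T) / (w @ h @ h.T + EPS)
        err = _frobenius(v, w, h)
        trace.append(err)
        prev = trace[-2]
        if prev > 0 and (prev - err) / prev < tol:
            break
    return w, h, trace


def nonnegative_view(matrix: ExpressionMatrix) -> tuple[np.ndarray, float]:
    """Return (nonnegative values, shift applied); log-scale data is shifted."""
    v = matrix.values
    low = v.min()
    if low < 0:
        logger.info("shifting matrix by %.4g to enforce nonnegativity", -low)
        return v - low, float(-low)
    return v, 0.0


def fit_nmf(
    matrix: ExpressionMatrix,
    rank: int,
    n_restarts: int = DEFAULT_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 7,
) -> NMFModel:
    """Fit NMF at the given rank; best of ``n_restarts`` by final objective."""
    n_genes, n_samples = matrix.shape
    if rank < 1 or rank > min(n_genes, n_samples):
        raise ValidationError(f"rank must lie in [1, {min(n_genes, n_samples)}]")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    v, shift = nonnegative_view(matrix)

    scale = np.sqrt(v.mean() / rank)
    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng((seed + 1000 * r) % 2**31)
        w0 = scale * rng.uniform(0.1, 1.0, size=(n_genes, rank))
        h0 = scale * rng.uniform(0.1, 1.0, size=(rank, n_samples))
        w, h, trace = _multiplicative_fit(v, w0, h0, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (w, h, trace)

    w, h, trace = best
    factor_names = [f"F{i}" for i in range(rank)]
    return NMFModel(
        W=pd.DataFrame(w, index=matrix.gene_ids, columns=factor_names),
        H=pd.DataFrame(h, index=factor_names, columns=matrix.sample_ids),
        rank=rank,
        seed=seed,
        objective_trace=trace,
        shift=shift,
    )


def assign_clusters(model: NMFModel) -> dict[str, str]:
    """Assign each sample to the argmax factor of its loading column.

    Exact ties resolve to the lowest factor index.
    """
    h = model.H.to_numpy()
    winners = np.argmax(h, axis=0)  # first maximum wins
    return {
        sample: model.factor_names[w]
        for sample, w in zip(model.H.columns, winners)
    }


def project_onto_W(
    W: pd.DataFrame,
    profiles: ExpressionMatrix,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 7,
) -> pd.DataFrame:
    """Nonnegative projection of new profiles onto a fixed factor matrix.

    Solves min ||V - W H|| over H >= 0 with W frozen and returns the
    column-L1-normalized H (factor weights per sample).  All-zero profiles
    stay all-zero and are flagged with a warning.
    """
    shared = [g for g in W.index if g in set(profiles.gene_ids)]
    if len(shared) < 0.5 * len(W.index):
        raise ValidationError(
            f"profiles cover only {len(shared)}/{len(W.index)} of the factor genes"
        )
    w = W.loc[shared].to_numpy()
    sub = profiles.data.loc[shared]
    v = sub.to_numpy()
    if v.min() < 0:
        v = v - v.min()

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(v.mean(), EPS) / w.shape[1])
    h0 = scale * rng.uniform(0.1, 1.0, size=(w.shape[1], v.shape[1]))
    _, h, _ = _multiplicative_fit(v, w, h0, max_iter, tol, update_w=False)

    sums = h.sum(axis=0)
    zero = sums <= EPS
    if zero.any():
        logger.warning("%d projected profiles have all-zero weights", int(zero.sum()))
        h[:, zero] = 0.0
        sums[zero] = 1.0
    return pd.DataFrame(h / sums, index=list(W.columns), columns=profiles.sample_ids)
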