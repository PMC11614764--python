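"""Compositionally-aware correlation estimation (SparCC) with permutation p-values.

Sequencing-derived abundance profiles are compositional: per-sample totals
are arbitrary, so naive Pearson correlations between taxa are spurious.
SparCC works around the closure by operating on log-ratio variances

    t_ij = Var[ log(x_i / x_j) ]

which are invariant to per-sample scaling, and inferring latent ("basis")
log-abundance variances w_i under a sparsity assumption from the
approximate linear relation t_ij ~= w_i + w_j - 2 rho_ij sqrt(w_i w_j).
Correlations follow as

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Strongly correlated pairs violate the sparsity assumption, so the pair
with the largest |rho| above a threshold is iteratively removed from the
linear system and the solve repeated.  The whole procedure is run over
many Dirichlet resamplings of the count table (posterior fractions given
counts) and the element-wise median taken; significance comes from a
permutation null in which each taxon's counts are shuffled independently
across samples.

Everything here is vectorized over a leading batch axis so that the many
Dirichlet rounds and permutation rounds of a full run amortize into a few
large linear-algebra calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .profiles import AbundanceTable

__all__ = [
    "SparccParams",
    "CorrelationEstimate",
    "PermutationPvalues",
    "draw_fractions",
    "logratio_variance",
    "solve_basis_variances",
    "correlations_from_basis",
    "sparcc_single_iteration",
    "sparcc",
    "permutation_pvalues",
    "write_square_tsv",
    "read_square_tsv",
]

_W_FLOOR = 1e-12  # basis variances floored here to avoid division by zero
_CHUNK = 256  # batch elements processed per linear-algebra call


@dataclass(frozen=True)
class SparccParams:
    """Estimation parameters.

    ``iterations``
        Rounds of Dirichlet resampling whose correlation estimates are
        combined by an element-wise median.
    ``exclude_iterations``
        Maximum number of strongly-correlated pairs removed from the
        basis-variance linear system within one round.
    ``exclusion_threshold``
        Minimum |rho| for a pair to be excluded.
    ``n_permutations``
        Permutation rounds for the null distribution.
    ``permutation_iterations`` / ``permutation_exclude_iterations``
        Reduced internal settings used when re-estimating rho on permuted
        data; null medians stabilize quickly, so a handful of rounds per
        permutation keeps large permutation counts tractable.
    """

    iterations: int = 100
    exclude_iterations: int = 20
    exclusion_threshold: float = 0.1
    n_permutations: int = 1000
    permutation_iterations: int = 5
    permutation_exclude_iterations: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValueError("exclusion_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.exclude_iterations < 0 or self.permutation_exclude_iterations < 0:
            raise ValueError("exclusion iteration counts must be >= 0")


@dataclass
class CorrelationEstimate:
    """Median-over-iterations SparCC correlation matrix."""

    taxa: list[str]
    rho: np.ndarray  # (D, D), symmetric, |rho| <= 1, diagonal exactly 1
    params: SparccParams


@dataclass
class PermutationPvalues:
    """Two-sided (on |rho|) permutation p-values, add-one estimator."""

    taxa: list[str]
    p: np.ndarray  # (D, D), symmetric, entries in (0, 1]
    n_permutations: int


# ---------------------------------------------------------------------------
# batched primitives
# ---------------------------------------------------------------------------


def _dirichlet_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Posterior fractions: one Dirichlet(counts + 1) draw per leading element."""
    gam = rng.standard_gamma(np.asarray(counts, dtype=float) + 1.0)
    return gam / gam.sum(axis=-1, keepdims=True)


def _logratio_variance_batch(fractions: np.ndarray) -> np.ndarray:
    """T[..., i, j] = Var(log f_i - log f_j) across samples (ddof=1)."""
    lf = np.log(fractions)
    n = lf.shape[-2]
    x = lf - lf.mean(axis=-2, keepdims=True)
    cov = np.swapaxes(x, -1, -2) @ x / (n - 1)
    v = np.diagonal(cov, axis1=-2, axis2=-1)
    t = v[..., :, None] + v[..., None, :] - 2.0 * cov
    t = 0.5 * (t + np.swapaxes(t, -1, -2))
    idx = np.arange(t.shape[-1])
    t[..., idx, idx] = 0.0
    return np.maximum(t, 0.0)


def _solve_basis_batch(t: np.ndarray, excluded: np.ndarray) -> np.ndarray:
    """Least-squares basis variances with excluded pairs' equations removed.

    Solves ``min_w sum_{i<j not excluded} (w_i + w_j - t_ij)^2`` via its
    normal equations; with no exclusions this reduces to the closed form
    ``w_i = (t_i - W) / (D - 2)`` with ``t_i = sum_j t_ij`` and
    ``W = sum_i t_i / (2 (D - 1))``.
    """
    d = t.shape[-1]
    eye = np.eye(d, dtype=bool)
    include = ~excluded & ~eye
    m = include.astype(float)
    idx = np.arange(d)
    m[..., idx, idx] = include.sum(axis=-1)
    rhs = (t * include).sum(axis=-1)
    try:
        w = np.linalg.solve(m, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        w = _lstsq_batch(m, rhs)
    return np.maximum(w, _W_FLOOR)


def _lstsq_batch(m: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    flat_m = m.reshape(-1, m.shape[-2], m.shape[-1])
    flat_r = rhs.reshape(-1, rhs.shape[-1])
    out = np.empty_like(flat_r)
    for i in range(flat_m.shape[0]):
        out[i] = np.linalg.lstsq(flat_m[i], flat_r[i], rcond=None)[0]
    return out.reshape(rhs.shape)


def _rho_from_basis(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(w[..., :, None] * w[..., None, :])
    rho = (w[..., :, None] + w[..., None, :] - t) / denom
    rho = np.clip(rho, -1.0, 1.0)
    idx = np.arange(rho.shape[-1])
    rho[..., idx, idx] = 1.0
    return rho


def _estimate_batch(
    counts: np.ndarray,
    exclude_iterations: int,
    threshold: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One SparCC estimate per leading batch element of ``counts`` (B, n, D)."""
    b, _, d = counts.shape
    frac = _dirichlet_fractions(counts, rng)
    t = _logratio_variance_batch(frac)
    excluded = np.zeros((b, d, d), dtype=bool)
    w = _solve_basis_batch(t, excluded)
    rho = _rho_from_basis(t, w)
    upper = np.triu(np.ones((d, d), dtype=bool), k=1)
    active = np.ones(b, dtype=bool)
    for _ in range(exclude_iterations):
        mask = upper & ~excluded
        absr = np.where(mask, np.abs(rho), -np.inf)
        flat = absr.reshape(b, -1)
        arg = flat.argmax(axis=1)  # row-major argmax = lexicographic tie-break
        mx = flat[np.arange(b), arg]
        todo = active & (mx > threshold)
        if not todo.any():
            break
        ii, jj = np.unravel_index(arg[todo], (d, d))
        which = np.flatnonzero(todo)
        excluded[which, ii, jj] = True
        excluded[which, jj, ii] = True
        w_t = _solve_basis_batch(t[todo], excluded[todo])
        rho[todo] = _rho_from_basis(t[todo], w_t)
        active = todo
    return rho


def _estimate_chunked(
    counts: np.ndarray,
    exclude_iterations: int,
    threshold: float,
    rng: np.random.Generator,
    chunk: int = _CHUNK,
) -> np.ndarray:
    parts = [
        _estimate_batch(counts[i : i + chunk], exclude_iterations, threshold, rng)
        for i in range(0, counts.shape[0], chunk)
    ]
    return np.concatenate(parts, axis=0)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def draw_fractions(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(counts + 1) posterior fraction draw for one sample.

    The +1 pseudocount makes the draw strictly positive even for all-zero
    count vectors (yielding the symmetric Dirichlet), so downstream log
    transforms are always defined.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1:
        raise ValueError("draw_fractions expects a single sample's count vector")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    return _dirichlet_fractions(counts[None, :], rng)[0]


def logratio_variance(fractions: np.ndarray) -> np.ndarray:
    """Pairwise log-ratio variance matrix T of a (samples x taxa) matrix."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 2 or fractions.shape[0] < 2:
        raise ValueError("need a 2-D (samples x taxa) matrix with >= 2 samples")
    if (fractions <= 0).any():
        raise ValueError("fractions must be strictly positive")
    return _logratio_variance_batch(fractions[None])[0]


def solve_basis_variances(
    t: np.ndarray, excluded_pairs: Iterable[tuple[int, int]] = ()
) -> np.ndarray:
    """Basis (latent log-abundance) variances from the log-ratio matrix."""
    t = np.asarray(t, dtype=float)
    d = t.shape[0]
    if d < 4:
        raise ValueError("basis-variance system needs at least 4 taxa")
    excluded = np.zeros((d, d), dtype=bool)
    for i, j in excluded_pairs:
        excluded[i, j] = excluded[j, i] = True
    return _solve_basis_batch(t[None], excluded[None])[0]


def correlations_from_basis(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    """rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)), clipped to [-1, 1]."""
    w = np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValueError("basis variances must be positive")
    return _rho_from_basis(np.asarray(t, dtype=float)[None], w[None])[0]


def sparcc_single_iteration(
    counts: np.ndarray, params: SparccParams, rng: np.random.Generator
) -> np.ndarray:
    """One Dirichlet round: draw fractions, solve, iteratively exclude pairs.

    After each solve, the unexcluded off-diagonal pair with the largest
    |rho| is removed from the linear system if it exceeds the exclusion
    threshold (ties broken by lexicographic taxon order); at most
    ``exclude_iterations`` pairs are removed.  The rho of the final solve
    is returned, excluded pairs included.
    """
    counts = np.asarray(counts)
    if counts.shape[1] < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    return _estimate_batch(
        counts[None].astype(float),
        params.exclude_iterations,
        params.exclusion_threshold,
        rng,
    )[0]


def _as_counts(data: AbundanceTable | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, AbundanceTable):
        return data.counts, data.taxon_labels
    arr = np.asarray(data)
    return arr, [f"taxon_{j}" for j in range(arr.shape[1])]


def sparcc(
    data: AbundanceTable | np.ndarray,
    params: SparccParams | None = None,
    seed: int | None = None,
) -> CorrelationEstimate:
    """Median-over-iterations SparCC correlation estimate.

    Runs ``params.iterations`` independent Dirichlet rounds and combines
    them with an element-wise median, which is robust to occasional
    degenerate draws.  Deterministic given the seed.
    """
    params = params or SparccParams()
    counts, taxa = _as_counts(data)
    if counts.shape[1] < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    if counts.shape[0] < 3:
        raise ValueError("SparCC needs at least 3 samples")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    batch = np.broadcast_to(
        counts.astype(float), (params.iterations, *counts.shape)
    ).copy()
    rhos = _estimate_chunked(
        batch, params.exclude_iterations, params.exclusion_threshold, rng
    )
    rho = np.median(rhos, axis=0)
    rho = 0.5 * (rho + rho.T)
    np.fill_diagonal(rho, 1.0)
    return CorrelationEstimate(taxa=list(taxa), rho=rho, params=params)


def permutation_pvalues(
    data: AbundanceTable | np.ndarray,
    observed: CorrelationEstimate,
    params: SparccParams | None = None,
    seed: int | None = None,
) -> PermutationPvalues:
    """Permutation null: shuffle each taxon's counts independently across samples.

    For each permutation round the SparCC rho is re-estimated (with the
    reduced internal iteration counts in ``params``) and compared against
    the observed magnitudes.  p-values use the add-one estimator

        p_ij = (1 + #{null |rho| >= observed |rho|}) / (n_permutations + 1)

    so the smallest attainable p is 1 / (n_permutations + 1); the test is
    two-sided through the magnitude.
    """
    params = params or observed.params
    counts, taxa = _as_counts(data)
    n, d = counts.shape
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n_perm = params.n_permutations
    k = params.permutation_iterations
    obs_abs = np.abs(observed.rho)
    exceed = np.zeros((d, d), dtype=np.int64)
    block = max(1, _CHUNK // max(k, 1))
    for start in range(0, n_perm, block):
        b = min(block, n_perm - start)
        order = rng.random((b, n, d)).argsort(axis=1)
        permuted = np.take_along_axis(
            np.broadcast_to(counts.astype(float), (b, n, d)), order, axis=1
        )
        rep = np.repeat(permuted, k, axis=0)
        rhos = _estimate_batch(
            rep, params.permutation_exclude_iterations, params.exclusion_threshold, rng
        )
        null_rho = np.median(rhos.reshape(b, k, d, d), axis=1)
        exceed += (np.abs(null_rho) >= obs_abs[None]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 1.0)
    return PermutationPvalues(taxa=list(taxa), p=p, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# square-matrix TSV writers (shared by rho and p matrices)
# ---------------------------------------------------------------------------


def write_square_tsv(matrix: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_square_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
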