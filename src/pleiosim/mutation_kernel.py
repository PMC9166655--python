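"""Mutation matrices for cell division and offspring-genotype sampling.

Three row-stochastic 8x8 matrices over the genotype space:

* ``Q`` (null): each trait mutates independently at division, losing
  function with probability ``mu`` and gaining function with
  probability ``nu * mu``.
* ``P`` (pleiotropic): identical to ``Q`` except in the row of the
  fully active genotype g8, where loss-of-function mutations to the
  cooperative or private trait are coupled -- a single hit removes
  both, landing on g1 with probability ``2*mu - mu**2`` and on g7
  (loss of pleiotropy only) with probability ``(1-mu)**2 * mu``.
* ``H = phi * P + (1 - phi) * Q``: the effective matrix, where ``phi``
  in [0, 1] scales the strength of pleiotropy.

Matrices are state- and age-independent, so they are built once per
parameter set (and memoised).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from pleiosim.genotype_space import N_GENOTYPES, TRAIT_MATRIX, genotype_labels

_ROW_SUM_TOL = 1e-12


def _validate(mu: float, nu: float, phi: float = 0.0) -> None:
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    if not 0.0 < nu <= 1.0:
        raise ValueError(f"nu must be in (0, 1], got {nu}")
    if nu * mu > 1.0:
        raise ValueError(f"nu * mu must be <= 1, got {nu * mu}")
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")


@lru_cache(maxsize=64)
def _null_matrix_cached(mu: float, nu: float) -> np.ndarray:
    # Per-trait channel: active->inactive mu, inactive->active nu*mu.
    q = np.ones((N_GENOTYPES, N_GENOTYPES))
    for i in range(N_GENOTYPES):
        for j in range(N_GENOTYPES):
            for t in range(3):
                a, b = TRAIT_MATRIX[i, t], TRAIT_MATRIX[j, t]
                if a == 1:
                    q[i, j] *= mu if b == 0 else 1.0 - mu
                else:
                    q[i, j] *= nu * mu if b == 1 else 1.0 - nu * mu
    q.setflags(write=False)
    return q


def null_matrix(mu: float, nu: float) -> np.ndarray:
    """Null mutation matrix ``Q``: independent per-trait mutation."""
    _validate(mu, nu)
    return _null_matrix_cached(float(mu), float(nu))


@lru_cache(maxsize=64)
def _pleiotropic_matrix_cached(mu: float, nu: float) -> np.ndarray:
    p = _null_matrix_cached(mu, nu).copy()
    # g8 row: coupled loss of cooperative + private trait.  The double
    # loss lands on g1 and the pure pleiotropy loss on g7, exactly as
    # printed; there are no gain-of-function terms in this row.
    row8 = np.zeros(N_GENOTYPES)
    row8[0] = 2.0 * mu - mu**2
    row8[6] = (1.0 - mu) ** 2 * mu
    row8[7] = 1.0 - row8[0] - row8[6]
    p[7] = row8
    p.setflags(write=False)
    return p


def pleiotropic_matrix(mu: float, nu: float) -> np.ndarray:
    """Pleiotropic mutation matrix ``P``: differs from ``Q`` only in row g8."""
    _validate(mu, nu)
    return _pleiotropic_matrix_cached(float(mu), float(nu))


@lru_cache(maxsize=64)
def _effective_matrix_cached(mu: float, nu: float, phi: float) -> np.ndarray:
    h = phi * _pleiotropic_matrix_cached(mu, nu) + (1.0 - phi) * _null_matrix_cached(
        mu, nu
    )
    h.setflags(write=False)
    return h


def effective_matrix(mu: float, nu: float, phi: float) -> np.ndarray:
    """Effective mutation matrix ``H = phi * P + (1 - phi) * Q``."""
    _validate(mu, nu, phi)
    return _effective_matrix_cached(float(mu), float(nu), float(phi))


def assert_row_stochastic(matrix: np.ndarray, tol: float = _ROW_SUM_TOL) -> None:
    """Raise if any entry is outside [0, 1] or any row sum deviates from 1."""
    if np.any(matrix < -tol) or np.any(matrix > 1.0 + tol):
        raise ValueError("mutation matrix has entries outside [0, 1]")
    err = np.abs(matrix.sum(axis=1) - 1.0).max()
    if err > tol:
        raise ValueError(f"mutation matrix rows deviate from 1 by {err:.3e}")


def row_cumulative(matrix: np.ndarray) -> np.ndarray:
    """Row-wise cumulative sums, used for inverse-CDF offspring sampling."""
    cum = np.cumsum(matrix, axis=1)
    cum[:, -1] = 1.0  # guard against round-off at the right edge
    return cum


def sample_offspring(i: int, matrix: np.ndarray, rng: np.random.Generator) -> int:
    """Sample a descendant genotype (1-based) from row ``i`` of ``matrix``.

    Uses inverse-CDF sampling on the cached cumulative row so a single
    uniform draw determines the offspring.
    """
    if not 1 <= int(i) <= N_GENOTYPES:
        raise ValueError(f"invalid genotype index {i!r}")
    cum = np.cumsum(matrix[int(i) - 1])
    cum[-1] = 1.0
    return int(np.searchsorted(cum, rng.random(), side="right")) + 1


def matrix_to_csv(matrix: np.ndarray, path) -> None:
    """Export an 8x8 mutation matrix as CSV with g1..g8 header and index."""
    import pandas as pd

    labels = list(genotype_labels())
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path)
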