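"""Stochastic birth-death-mutation dynamics of cells within an ageing group.

A group starts from its founding cell(s) and grows logistically toward a
carrying capacity ``K`` while cells divide, die, and mutate.  Sample
paths are generated with Gillespie's Direct method: at each event the 8
birth and 8 death propensities are recomputed in full (rates are
frequency-dependent), a waiting time is drawn, and on a birth the
offspring genotype is drawn from the ancestor's row of the effective
mutation matrix.  The expected development of each group type is
characterised by averaging many replicates onto a shared age grid
(last-value-carried-forward between events).

Within-group rates (ratio form, relative to the group mean):

* birth of genotype i:  ``(1 - s_c * z_u_i) / (1 - s_c * zbar_u)``
* death of genotype i:  ``(1 - s_c * z_v_i) / (1 - s_c * zbar_v) * (N - 1) / K``

so a clonal group equilibrates near ``N = K + 1`` and the death
propensity vanishes at ``N = 1`` (a group cannot go extinct from
within).  Under the two-private-traits control variant the birth rate
becomes ``(1 - s_c + s_c * z_w_i) / (1 - s_c + s_c * zbar_w)`` with the
second private trait ``z_w`` occupying the cooperative-trait slot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from pleiosim.genotype_space import (
    N_GENOTYPES,
    TRAIT_MATRIX,
    founder_counts,
    genotype_labels,
    group_label,
)
from pleiosim.mutation_kernel import effective_matrix, row_cumulative

_ZU = TRAIT_MATRIX[:, 0].astype(np.float64)
_ZV = TRAIT_MATRIX[:, 1].astype(np.float64)


# ---------------------------------------------------------------------------
# Parameters and state


@dataclass(frozen=True)
class ModelParams:
    """All scalar model parameters with their default values.

    ``rho = 1 / lam`` (the expected group reproduction rate) is always
    derived, never stored.
    """

    s_c: float = 0.95  # strength of within-group selection
    s_g: float = 0.95  # strength of between-group selection
    lam: float = 20.0  # expected group life span (time units)
    K: int = 200  # carrying capacity of groups
    mu: float = 0.0001  # loss-of-function mutation rate per trait per division
    nu: float = 0.01  # gain-of-function rate relative to loss-of-function
    phi: float = 0.0  # strength of pleiotropy
    zeta: float = 0.0  # cost of pleiotropy on group function
    alpha: float = 0.0  # maturity fraction of the expected life span
    gamma: float = 0.0  # strength of germ-line transmission
    control_private: bool = False  # two-private-traits control variant

    def __post_init__(self):
        checks = [
            ("s_c", self.s_c, 0.0, True, 1.0, False),
            ("s_g", self.s_g, 0.0, True, 1.0, False),
            ("mu", self.mu, 0.0, True, 1.0, True),
            ("phi", self.phi, 0.0, True, 1.0, True),
            ("zeta", self.zeta, 0.0, True, 1.0, True),
            ("alpha", self.alpha, 0.0, True, 1.0, True),
            ("gamma", self.gamma, 0.0, True, 1.0, True),
        ]
        for name, val, lo, lo_inc, hi, hi_inc in checks:
            ok = (val >= lo if lo_inc else val > lo) and (
                val <= hi if hi_inc else val < hi
            )
            if not ok:
                raise ValueError(f"{name}={val} outside admissible range")
        if not 0.0 < self.nu <= 1.0:
            raise ValueError(f"nu={self.nu} outside (0, 1]")
        if self.lam <= 1.0:
            raise ValueError(f"lam={self.lam} must exceed 1")
        if int(self.K) < 2:
            raise ValueError(f"K={self.K} must be an integer >= 2")

    @property
    def rho(self) -> float:
        """Expected group reproduction rate, ``1 / lam``."""
        return 1.0 / self.lam

    def mutation_matrix(self) -> np.ndarray:
        """Effective 8x8 mutation matrix for these parameters."""
        return effective_matrix(self.mu, self.nu, self.phi)

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class GroupState:
    """Cell counts per genotype and the group's age."""

    counts: np.ndarray
    age: float = 0.0

    @property
    def size(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# Rates


def _rates(counts: np.ndarray, params: ModelParams):
    n_total = counts.sum()
    if n_total < 1:
        raise ValueError("empty group: within-group rates undefined at N=0")
    s = params.s_c
    zbar_u = float(counts @ _ZU) / n_total
    zbar_v = float(counts @ _ZV) / n_total
    if params.control_private:
        b = (1.0 - s + s * _ZU) / (1.0 - s + s * zbar_u)
    else:
        b = (1.0 - s * _ZU) / (1.0 - s * zbar_u)
    d = (1.0 - s * _ZV) / (1.0 - s * zbar_v) * (n_total - 1.0) / params.K
    return b, d


def cell_birth_rate(i: int, state: GroupState, params: ModelParams) -> float:
    """Per-capita birth rate of genotype ``i`` (1-based) in ``state``."""
    b, _ = _rates(state.counts, params)
    return float(b[int(i) - 1])


def cell_death_rate(i: int, state: GroupState, params: ModelParams) -> float:
    """Per-capita death rate of genotype ``i`` (1-based) in ``state``."""
    _, d = _rates(state.counts, params)
    return float(d[int(i) - 1])


# ---------------------------------------------------------------------------
# Gillespie core (numba)


@njit(cache=True)
def _run_one(counts, sc, K, control, hcum, grid, out):
    """One Gillespie sample path recorded on ``grid`` by LVCF.

    ``counts`` is modified in place; ``out`` has shape (len(grid), 8).
    """
    t = 0.0
    gi = 0
    ng = grid.shape[0]
    horizon = grid[ng - 1]
    bprop = np.empty(N_GENOTYPES)
    dprop = np.empty(N_GENOTYPES)
    while True:
        n_total = 0.0
        zbar_u = 0.0
        zbar_v = 0.0
        for i in range(N_GENOTYPES):
            c = counts[i]
            n_total += c
            zbar_u += c * _ZU[i]
            zbar_v += c * _ZV[i]
        zbar_u /= n_total
        zbar_v /= n_total
        total = 0.0
        for i in range(N_GENOTYPES):
            if control:
                b = (1.0 - sc + sc * _ZU[i]) / (1.0 - sc + sc * zbar_u)
            else:
                b = (1.0 - sc * _ZU[i]) / (1.0 - sc * zbar_u)
            d = (1.0 - sc * _ZV[i]) / (1.0 - sc * zbar_v) * (n_total - 1.0) / K
            bprop[i] = counts[i] * b
            dprop[i] = counts[i] * d
            total += bprop[i] + dprop[i]
        if not np.isfinite(total) or total <= 0.0:
            raise ValueError("non-finite or non-positive total propensity")
        t_next = t + (-math.log(np.random.random()) / total)
        while gi < ng and grid[gi] < t_next:
            for i in range(N_GENOTYPES):
                out[gi, i] = counts[i]
            gi += 1
        if gi >= ng or t_next > horizon:
            while gi < ng:
                for i in range(N_GENOTYPES):
                    out[gi, i] = counts[i]
                gi += 1
            return
        t = t_next
        r = np.random.random() * total
        acc = 0.0
        event_i = -1
        is_birth = True
        for i in range(N_GENOTYPES):
            acc += bprop[i]
            if r < acc:
                event_i = i
                break
        if event_i < 0:
            is_birth = False
            for i in range(N_GENOTYPES):
                acc += dprop[i]
                if r < acc:
                    event_i = i
                    break
            if event_i < 0:
                event_i = N_GENOTYPES - 1  # round-off guard
        if is_birth:
            u = np.random.random()
            j = 0
            row = hcum[event_i]
            while j < N_GENOTYPES - 1 and u >= row[j]:
                j += 1
            counts[j] += 1
        else:
            counts[event_i] -= 1


@njit(cache=True)
def _run_seeded(founder, seed, sc, K, control, hcum, grid, out):
    np.random.seed(seed)
    counts = founder.copy()
    _run_one(counts, sc, K, control, hcum, grid, out)


@njit(cache=True)
def _accumulate(founder, seeds, sc, K, control, hcum, grid, sum_counts, sum_freqs):
    ng = grid.shape[0]
    out = np.empty((ng, N_GENOTYPES), dtype=np.int64)
    for r in range(seeds.shape[0]):
        np.random.seed(seeds[r])
        counts = founder.copy()
        _run_one(counts, sc, K, control, hcum, grid, out)
        for g in range(ng):
            n_total = 0.0
            for i in range(N_GENOTYPES):
                n_total += out[g, i]
            for i in range(N_GENOTYPES):
                sum_counts[g, i] += out[g, i]
                sum_freqs[g, i] += out[g, i] / n_total


def _replicate_seeds(master_seed: int, n_replicates: int) -> np.ndarray:
    """Counter-based split of a master seed into per-replicate seeds."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_replicates, dtype=np.uint32).astype(np.int64)


def default_age_grid(horizon: float, spacing: float = 0.25) -> np.ndarray:
    """Uniform age grid from 0 to ``horizon`` inclusive."""
    n = int(round(horizon / spacing))
    return np.linspace(0.0, horizon, n + 1)


def simulate_group(founders, params: ModelParams, horizon: float, seed: int,
                   age_grid: np.ndarray | None = None):
    """One exact stochastic trajectory of a group, recorded on an age grid.

    Returns ``(age_grid, counts)`` with ``counts`` of shape
    ``(len(age_grid), 8)``.  Bit-identical under a fixed seed.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    founder = founder_counts(tuple(founders))
    if founder.sum() < 1:
        raise ValueError("founders must be non-empty")
    if age_grid is None:
        age_grid = default_age_grid(horizon)
    age_grid = np.asarray(age_grid, dtype=np.float64)
    hcum = row_cumulative(params.mutation_matrix())
    out = np.empty((len(age_grid), N_GENOTYPES), dtype=np.int64)
    _run_seeded(
        founder,
        np.int64(np.uint32(seed)),
        float(params.s_c),
        float(params.K),
        params.control_private,
        hcum,
        age_grid,
        out,
    )
    return age_grid, out


# ---------------------------------------------------------------------------
# Replicate-averaged development per group type


@dataclass
class GroupTypeProfile:
    """Replicate-averaged within-group summaries of one group type."""

    gtype: tuple
    age_grid: np.ndarray
    mean_counts: np.ndarray  # (n_ages, 8)
    mean_freqs: np.ndarray  # (n_ages, 8), rows sum to 1
    n_replicates: int
    seed: int

    @property
    def mean_size(self) -> np.ndarray:
        """Replicate-mean group size N(y)."""
        return self.mean_counts.sum(axis=1)

    @property
    def trait_means(self) -> np.ndarray:
        """(n_ages, 3) array of mean trait expression (z_u, z_v, z_p)."""
        return self.mean_freqs @ TRAIT_MATRIX.astype(float)

    def group_function(self, zeta: float = 0.0) -> np.ndarray:
        """Group function z_f(y) from the replicate-mean trait values."""
        z = self.trait_means
        return group_function(z[:, 0], z[:, 1], z[:, 2], zeta)

    def maturity(self, alpha: float, lam: float) -> np.ndarray:
        """Maturity indicator z_r(y) on the age grid."""
        return (self.age_grid >= alpha * lam).astype(float)

    def offspring_dist(self, matrix: np.ndarray) -> np.ndarray:
        """Per-age descendant-founder genotype distribution x(y) @ H."""
        return self.mean_freqs @ matrix

    def cheater_frequency(self) -> np.ndarray:
        """Summed mean frequency of genotypes lacking the cooperative trait."""
        return self.mean_freqs[:, _ZU == 0].sum(axis=1)

    def crossing_age(self, threshold: float = 0.25) -> float:
        """First age at which the cheater frequency reaches ``threshold``.

        Returns ``nan`` if the threshold is never reached on the grid.
        """
        hit = np.nonzero(self.cheater_frequency() >= threshold)[0]
        return float(self.age_grid[hit[0]]) if hit.size else float("nan")

    def to_frame(self):
        """Long-format table: group_type, age, genotype, mean_count, mean_freq."""
        import pandas as pd

        labels = genotype_labels()
        recs = []
        for g, age in enumerate(self.age_grid):
            for i in range(N_GENOTYPES):
                recs.append(
                    (
                        group_label(self.gtype),
                        float(age),
                        labels[i],
                        float(self.mean_counts[g, i]),
                        float(self.mean_freqs[g, i]),
                    )
                )
        return pd.DataFrame(
            recs, columns=["group_type", "age", "genotype", "mean_count", "mean_freq"]
        )


def average_profile(gtype, params: ModelParams, n_replicates: int,
                    age_grid: np.ndarray, seed: int = 0) -> GroupTypeProfile:
    """Average ``n_replicates`` stochastic trajectories of one group type.

    Deterministic given the master ``seed`` (replicates use seeds split
    from it).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    gtype = tuple(gtype)
    founder = founder_counts(gtype)
    age_grid = np.asarray(age_grid, dtype=np.float64)
    hcum = row_cumulative(params.mutation_matrix())
    sum_counts = np.zeros((len(age_grid), N_GENOTYPES))
    sum_freqs = np.zeros((len(age_grid), N_GENOTYPES))
    seeds = _replicate_seeds(seed, n_replicates)
    _accumulate(
        founder,
        seeds,
        float(params.s_c),
        float(params.K),
        params.control_private,
        hcum,
        age_grid,
        sum_counts,
        sum_freqs,
    )
    return GroupTypeProfile(
        gtype=gtype,
        age_grid=age_grid,
        mean_counts=sum_counts / n_replicates,
        mean_freqs=sum_freqs / n_replicates,
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Group-level trait functions


def group_function(z_u, z_v, z_p, zeta: float = 0.0):
    """Group function ``z_f = z_u * z_v * (1 - zeta * z_p)``."""
    return z_u * z_v * (1.0 - zeta * np.asarray(z_p, dtype=float))


def maturity_indicator(y, alpha: float, lam: float):
    """Maturity status: 0 below age ``alpha * lam``, 1 at or above it."""
    y = np.asarray(y, dtype=float)
    out = (y >= alpha * lam).astype(int)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Distribution of fitness effects


_DFE_CLASSES = {
    (1, 0, 0): "loss-cooperation",
    (0, 1, 0): "loss-private",
    (0, 0, 1): "loss-pleiotropy",
    (1, 1, 0): "pleiotropic-double-loss",
    (1, 1, 1): "pleiotropic-double-loss",
}


@dataclass(frozen=True)
class DFERecord:
    """Fitness effect of one ancestor -> descendant mutation in context."""

    ancestor: int
    descendant: int
    effect: float
    mutation_class: str = field(default="other")


def classify_mutation(ancestor: int, descendant: int) -> str:
    """Mutation class from the trait-vector difference (losses only)."""
    diff = TRAIT_MATRIX[int(ancestor) - 1] - TRAIT_MATRIX[int(descendant) - 1]
    if np.any(diff < 0) or not np.any(diff):
        return "other"
    return _DFE_CLASSES.get(tuple(int(x) for x in diff.clip(0)), "other")


def fitness_effect(ancestor: int, descendant: int, state: GroupState,
                   params: ModelParams) -> DFERecord:
    """Within-group fitness effect ``ln(b_mut/b_wt) - ln(d_mut/d_wt)``.

    Both rates are evaluated in the current group background; requires
    ``N >= 2`` so all four rates are strictly positive.
    """
    if state.size < 2:
        raise ValueError("fitness effect undefined at N=1 (zero death rate)")
    b, d = _rates(state.counts, params)
    i, j = int(ancestor) - 1, int(descendant) - 1
    effect = math.log(b[j] / b[i]) - math.log(d[j] / d[i])
    return DFERecord(
        ancestor=int(ancestor),
        descendant=int(descendant),
        effect=effect,
        mutation_class=classify_mutation(ancestor, descendant),
    )
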