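"""Age-structured PDE for the group population.

The relative density ``n_k(t, y)`` of ``k``-type groups aged ``y``
obeys a conservation law (ageing at unit speed) plus source and sink
terms for group reproduction and death.  The solver uses operator
splitting per time step:

1. conservative finite-volume advection in age with a superbee flux
   limiter (total-variation diminishing, outflow at ``y_max``), then
2. explicit-Euler sources/sinks -- deaths remove ``d_k * n_k * dt``
   from every cell and the total birth flux enters the age-0 cell of
   the descendant type (newborn groups always have age 0).

Group rates are normalised so the population-average birth and death
rates both equal ``rho = 1/lam``, which conserves total density:

* birth:  ``rho * (1 - s_g + s_g * z_r_k(y)) / (1 - s_g + s_g * zbar_r(t))``
* death:  ``rho * (1 - s_g * z_f_k(y)) / (1 - s_g * zbar_f(t))``

where ``z_r`` is the maturity indicator, ``z_f`` the group function,
and the population means ``zbar_r`` / ``zbar_f`` are group-density
weighted.  Every age-dependent quantity comes from the cached
replicate-averaged within-group profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from pleiosim.genotype_space import (
    N_GENOTYPES,
    founder_trait_means,
    group_label,
)
from pleiosim.within_group import (
    GroupTypeProfile,
    ModelParams,
    group_function,
    maturity_indicator,
)


# ---------------------------------------------------------------------------
# Grids and state


@dataclass(frozen=True)
class AgeGrid:
    """Uniform finite-volume age grid on [0, y_max], ageing speed 1."""

    dy: float
    n_cells: int

    @property
    def y_max(self) -> float:
        return self.dy * self.n_cells

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.y_max, self.n_cells + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dy

    @classmethod
    def for_params(cls, params: ModelParams, dy: float = 0.1,
                   ymax_mult: float = 10.0) -> "AgeGrid":
        """Grid truncated at ``ymax_mult * lam`` (default 10 life spans)."""
        return cls(dy=dy, n_cells=int(round(ymax_mult * params.lam / dy)))


@dataclass
class PopulationDensity:
    """Relative density of groups on a (type x age-cell) grid."""

    density: np.ndarray  # (n_types, n_cells), non-negative
    grid: AgeGrid
    group_types: list
    time: float = 0.0

    @property
    def total_mass(self) -> float:
        return float(self.density.sum()) * self.grid.dy

    def normalized(self) -> "PopulationDensity":
        return PopulationDensity(
            density=self.density / self.total_mass,
            grid=self.grid,
            group_types=self.group_types,
            time=self.time,
        )


@dataclass
class GlobalSummaries:
    """Population-level summaries at one time point."""

    time: float
    zbar_u: float  # cell-weighted global trait means
    zbar_v: float
    zbar_p: float
    zbar_f: float  # group-density-weighted mean group function
    zbar_r: float  # fraction of groups at reproductive maturity
    genotype_freqs: np.ndarray  # (8,) global cell genotype frequencies
    load_u: float = 0.0  # per-trait mutational load
    load_v: float = 0.0
    load_p: float = 0.0


# ---------------------------------------------------------------------------
# Stacked per-type profile arrays (precomputed once per run)


class StackedProfiles:
    """Profile-derived arrays aligned with an AgeGrid, stacked over types."""

    def __init__(self, profiles: dict, group_types: list, grid: AgeGrid,
                 params: ModelParams):
        centers = grid.centers
        n_types, m = len(group_types), grid.n_cells
        self.group_types = list(group_types)
        self.trait_means = np.empty((n_types, m, 3))
        self.mean_size = np.empty((n_types, m))
        self.mean_counts = np.empty((n_types, m, N_GENOTYPES))
        self.founder_traits = np.empty((n_types, 3))
        matrix = params.mutation_matrix()
        cell_dist = np.empty((n_types, m, N_GENOTYPES))
        for k, gtype in enumerate(group_types):
            prof = profiles.get(tuple(gtype))
            if prof is None:
                raise KeyError(f"missing within-group profile for {group_label(gtype)}")
            if len(prof.age_grid) < m or not np.allclose(
                prof.age_grid[:m], centers, atol=grid.dy * 1e-6
            ):
                raise ValueError(
                    f"profile for {group_label(gtype)} does not cover the age grid"
                )
            self.trait_means[k] = prof.trait_means[:m]
            self.mean_size[k] = prof.mean_size[:m]
            self.mean_counts[k] = prof.mean_counts[:m]
            self.founder_traits[k] = founder_trait_means(gtype)
            # gamma-blended per-cell transmission distribution
            resident = prof.offspring_dist(matrix)[:m]
            germ = np.mean([matrix[i - 1] for i in gtype], axis=0)
            cell_dist[k] = params.gamma * germ + (1.0 - params.gamma) * resident
        self.z_f = group_function(
            self.trait_means[:, :, 0],
            self.trait_means[:, :, 1],
            self.trait_means[:, :, 2],
            params.zeta,
        )
        self.z_r = maturity_indicator(centers, params.alpha, params.lam).astype(float)
        self.offspring_types = self._pair_distribution(cell_dist, group_types)

    @staticmethod
    def _pair_distribution(cell_dist: np.ndarray, group_types: list) -> np.ndarray:
        """(n_types, n_cells, n_types) descendant-group-type distribution."""
        n_founders = len(group_types[0])
        if n_founders == 1:
            return cell_dist  # group types == cell genotypes
        # two founders drawn independently from the same cell distribution
        n_types, m, _ = cell_dist.shape
        out = np.empty((n_types, m, n_types))
        for l, pair in enumerate(group_types):
            a, b = pair[0] - 1, pair[1] - 1
            if a == b:
                out[:, :, l] = cell_dist[:, :, a] * cell_dist[:, :, b]
            else:
                out[:, :, l] = 2.0 * cell_dist[:, :, a] * cell_dist[:, :, b]
        return out


# ---------------------------------------------------------------------------
# Group-level rates


def group_birth_rate(k: int, y: float, summaries: GlobalSummaries,
                     params: ModelParams) -> float:
    """Birth rate of a ``k``-type group aged ``y`` (maturity-weighted)."""
    s = params.s_g
    z_r = float(maturity_indicator(y, params.alpha, params.lam))
    return params.rho * (1.0 - s + s * z_r) / (1.0 - s + s * summaries.zbar_r)


def group_death_rate(z_f: float, summaries: GlobalSummaries,
                     params: ModelParams) -> float:
    """Death rate of a group with function ``z_f`` (survival advantage)."""
    s = params.s_g
    return params.rho * (1.0 - s * z_f) / (1.0 - s * summaries.zbar_f)


def offspring_type_distribution(k, y: float, stacked: StackedProfiles,
                                grid: AgeGrid) -> np.ndarray:
    """Descendant-group-type distribution of a ``k``-type group aged ``y``."""
    try:
        ki = stacked.group_types.index(tuple(k))
    except ValueError:
        raise KeyError(f"unknown group type {k!r}") from None
    yi = min(int(y / grid.dy), grid.n_cells - 1)
    return stacked.offspring_types[ki, yi]


# ---------------------------------------------------------------------------
# Finite-volume solver


def _superbee(r: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.maximum(np.minimum(1.0, 2.0 * r), np.minimum(2.0, r)))


def advect_age_step(density: np.ndarray, dy: float, dt: float) -> np.ndarray:
    """One conservative superbee-limited advection step (speed 1, outflow).

    ``density`` has shape (n_types, n_cells); the CFL condition
    ``dt <= dy`` must hold.
    """
    c = dt / dy
    if c > 1.0 + 1e-12:
        raise ValueError(f"CFL violation: dt/dy = {c:.4f} > 1")
    n = np.asarray(density, dtype=float)
    # slope ratios at interfaces i+1/2 for i = 0..m-1 (zero-gradient ghosts)
    padded = np.pad(n, ((0, 0), (1, 1)), mode="edge")
    diff = np.diff(padded, axis=1)  # (T, m+1): diff[:, i] = n_i - n_{i-1}
    upwind = diff[:, :-1]
    local = diff[:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(local != 0.0, upwind / local, 0.0)
    # flux through interface i+1/2: donor cell value plus limited correction
    flux = n + 0.5 * (1.0 - c) * _superbee(r) * local
    flux_in = np.concatenate([np.zeros((n.shape[0], 1)), flux[:, :-1]], axis=1)
    return n - c * (flux - flux_in)


def apply_sources_sinks(density: np.ndarray, dt: float, b: np.ndarray,
                        d: np.ndarray, offspring_types: np.ndarray,
                        dy: float) -> np.ndarray:
    """Explicit-Euler group births and deaths.

    Deaths remove ``d * n * dt`` per cell; the total birth flux
    ``B_l = sum_k int n_k b_k h_kl dy * dt`` is injected into the
    age-0 cell of type ``l``.
    """
    new = density * (1.0 - d * dt)
    if np.any(new < 0.0):
        raise ValueError("negative density after death step: dt too large")
    births = np.einsum("km,kml->l", density * b * dy, offspring_types) * dt
    new[:, 0] += births / dy
    return new


# ---------------------------------------------------------------------------
# Summaries


def global_trait_averages(pop: PopulationDensity, stacked: StackedProfiles,
                          with_load: bool = True) -> GlobalSummaries:
    """Cell-weighted global trait means plus group-weighted z_f and z_r."""
    n = pop.density
    dy = pop.grid.dy
    mass = n.sum() * dy
    cell_w = n * stacked.mean_size  # (T, M)
    total_cells = cell_w.sum()
    trait = np.einsum("km,kmz->z", cell_w, stacked.trait_means) / total_cells
    freqs = np.einsum("km,kmi->i", n, stacked.mean_counts) / total_cells
    zbar_f = float((n * stacked.z_f).sum() / n.sum())
    zbar_r = float((n * stacked.z_r[None, :]).sum() / n.sum())
    loads = (0.0, 0.0, 0.0)
    if with_load:
        loads = mutational_load(pop, stacked)
    return GlobalSummaries(
        time=pop.time,
        zbar_u=float(trait[0]),
        zbar_v=float(trait[1]),
        zbar_p=float(trait[2]),
        zbar_f=zbar_f,
        zbar_r=zbar_r,
        genotype_freqs=freqs,
        load_u=loads[0],
        load_v=loads[1],
        load_p=loads[2],
    )


def mutational_load(pop: PopulationDensity, stacked: StackedProfiles) -> tuple:
    """Per-trait, group-density-weighted mean of (founder value - mean at age y)."""
    n = pop.density
    deficit = stacked.founder_traits[:, None, :] - stacked.trait_means  # (T, M, 3)
    load = np.einsum("km,kmz->z", n, deficit) / n.sum()
    return tuple(float(x) for x in load)


# ---------------------------------------------------------------------------
# Driver


def initial_density(group_types: list, grid: AgeGrid,
                    init_type=None) -> PopulationDensity:
    """All mass (total 1) in the age-0 cell of one group type (default: all-g1)."""
    group_types = [tuple(g) for g in group_types]
    if init_type is None:
        init_type = (1,) * len(group_types[0])
    density = np.zeros((len(group_types), grid.n_cells))
    density[group_types.index(tuple(init_type)), 0] = 1.0 / grid.dy
    return PopulationDensity(density=density, grid=grid, group_types=group_types)


def run_to_steady_state(params: ModelParams, profiles: dict, grid: AgeGrid,
                        init: PopulationDensity | None = None,
                        tol: float = 1e-4, t_max: float = 10_000.0,
                        cfl_safety: float = 0.9, record_every: float = 1.0,
                        renormalize: bool = True):
    """Integrate the group-population PDE until the trait means settle.

    Stops when the sup-norm change of the global trait means
    ``(zbar_u, zbar_v, zbar_p)`` over a sliding window of ``5 * lam``
    time units falls below ``tol``, or at ``t_max`` (with a warning).
    Returns ``(PopulationDensity, list[GlobalSummaries])``; the final
    density is renormalised to total mass 1.
    """
    group_types = sorted({tuple(g) for g in profiles})
    stacked = StackedProfiles(profiles, group_types, grid, params)
    if init is None:
        init = initial_density(group_types, grid)
    density = init.density.copy()
    dt = cfl_safety * grid.dy
    rho = params.rho
    s = params.s_g
    t = float(init.time)
    summaries: list[GlobalSummaries] = []
    window = 5.0 * params.lam
    next_record = t
    converged = False
    n_steps = int(np.ceil((t_max - t) / dt))
    for _ in range(n_steps + 1):
        mass = density.sum() * grid.dy
        pop = PopulationDensity(density, grid, group_types, time=t)
        if t >= next_record - 1e-9:
            summaries.append(global_trait_averages(pop, stacked))
            next_record += record_every
            # convergence: sup-norm change of trait means over the window
            t0 = t - window
            past = [
                x for x in summaries if x.time >= t0 - record_every / 2
            ]
            if t - summaries[0].time >= window and len(past) > 2:
                sup = max(
                    max(abs(x.zbar_u - past[-1].zbar_u) for x in past),
                    max(abs(x.zbar_v - past[-1].zbar_v) for x in past),
                    max(abs(x.zbar_p - past[-1].zbar_p) for x in past),
                )
                if sup < tol:
                    converged = True
                    break
        if t >= t_max:
            break
        # population means (group-density weighted)
        zbar_f = float((density * stacked.z_f).sum() / density.sum())
        zbar_r = float((density * stacked.z_r[None, :]).sum() / density.sum())
        b = rho * (1.0 - s + s * stacked.z_r[None, :]) / (1.0 - s + s * zbar_r)
        d = rho * (1.0 - s * stacked.z_f) / (1.0 - s * zbar_f)
        density = advect_age_step(density, grid.dy, dt)
        density = apply_sources_sinks(
            density, dt, np.broadcast_to(b, density.shape), d,
            stacked.offspring_types, grid.dy,
        )
        if renormalize:
            density /= density.sum() * grid.dy
        t += dt
    if not converged and t >= t_max - dt:
        warnings.warn(
            f"steady state not reached by t_max={t_max}; returning final state",
            RuntimeWarning,
            stacklevel=2,
        )
    pop = PopulationDensity(density, grid, group_types, time=t).normalized()
    return pop, summaries


def summaries_to_frame(summaries: list):
    """Summary time series as a tidy DataFrame."""
    import pandas as pd

    from pleiosim.genotype_space import genotype_labels

    rows = []
    for s in summaries:
        row = {
            "time": s.time,
            "zbar_u": s.zbar_u,
            "zbar_v": s.zbar_v,
            "zbar_p": s.zbar_p,
            "zbar_f": s.zbar_f,
            "zbar_r": s.zbar_r,
            "load_u": s.load_u,
            "load_v": s.load_v,
            "load_p": s.load_p,
        }
        for lab, f in zip(genotype_labels(), s.genotype_freqs):
            row[f"freq_{lab}"] = float(f)
        rows.append(row)
    return pd.DataFrame(rows)
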