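"""Scripted computational experiments.

Drivers that compose the within-group simulator and the between-group
PDE into the standard analyses: within-group invasion dynamics per
pleiotropy strength, steady-state trait means over parameter sweeps,
and long-run global dynamics with trait invasion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from pleiosim.between_group import (
    AgeGrid,
    global_trait_averages,
    run_to_steady_state,
    summaries_to_frame,
    StackedProfiles,
)
from pleiosim.genotype_space import (
    N_GENOTYPES,
    TRAIT_MATRIX,
    enumerate_group_types,
    genotype_labels,
)
from pleiosim.within_group import (
    GroupState,
    GroupTypeProfile,
    ModelParams,
    average_profile,
    classify_mutation,
    default_age_grid,
    fitness_effect,
)


# ---------------------------------------------------------------------------
# Within-group dynamics per pleiotropy strength


def dfe_table(profile: GroupTypeProfile, params: ModelParams,
              ages=None) -> pd.DataFrame:
    """Fitness effects of loss-of-function mutations in the mean background.

    For each requested age and each (ancestor, descendant) pair reachable
    by losing at least one trait, the effect is evaluated in the
    replicate-mean group composition, weighted by the expected mutation
    flux ``x_anc * b_anc * h[anc, desc]``.
    """
    if ages is None:
        ages = profile.age_grid[:: max(1, len(profile.age_grid) // 20)]
    matrix = params.mutation_matrix()
    labels = genotype_labels()
    records = []
    for age in ages:
        gi = int(np.searchsorted(profile.age_grid, age))
        gi = min(gi, len(profile.age_grid) - 1)
        counts = profile.mean_counts[gi]
        if counts.sum() < 2:
            continue
        state = GroupState(counts=counts, age=float(age))
        freqs = profile.mean_freqs[gi]
        for anc in range(1, N_GENOTYPES + 1):
            if freqs[anc - 1] <= 0:
                continue
            for desc in range(1, N_GENOTYPES + 1):
                if desc == anc:
                    continue
                diff = TRAIT_MATRIX[anc - 1] - TRAIT_MATRIX[desc - 1]
                if np.any(diff < 0):
                    continue  # gains excluded: losses only
                rec = fitness_effect(anc, desc, state, params)
                records.append(
                    {
                        "age": float(profile.age_grid[gi]),
                        "ancestor": labels[anc - 1],
                        "descendant": labels[desc - 1],
                        "mutation_class": rec.mutation_class,
                        "effect": rec.effect,
                        "weight": float(freqs[anc - 1] * matrix[anc - 1, desc - 1]),
                    }
                )
    return pd.DataFrame(records)


def within_group_figure(params: ModelParams, phis, gtype=(8,),
                        n_replicates: int = 10_000, horizon: float = 50.0,
                        seed: int = 0, age_spacing: float = 0.25,
                        threshold: float = 0.25) -> dict:
    """Within-group invasion dynamics of one founder type per phi value.

    Returns profiles, threshold-crossing ages of the noncooperative
    (z_u = 0) frequency, and a loss-of-function DFE table per phi.
    """
    age_grid = default_age_grid(horizon, age_spacing)
    profiles: dict = {}
    crossing: dict = {}
    dfe_frames = []
    for phi in phis:
        p = params.with_(phi=float(phi))
        prof = average_profile(tuple(gtype), p, n_replicates, age_grid, seed=seed)
        profiles[float(phi)] = prof
        crossing[float(phi)] = prof.crossing_age(threshold)
        frame = dfe_table(prof, p)
        frame.insert(0, "phi", float(phi))
        dfe_frames.append(frame)
    return {
        "profiles": profiles,
        "crossing_ages": crossing,
        "dfe": pd.concat(dfe_frames, ignore_index=True) if dfe_frames else pd.DataFrame(),
    }


# ---------------------------------------------------------------------------
# Steady-state sweeps


@dataclass
class SweepSpec:
    """Grid specification for steady-state sweeps.

    ``base`` supplies every setting not swept (a RunConfig-like object
    with ``model_params()``, grid and run fields).
    """

    base: object
    phis: list = field(default_factory=lambda: [0.0, 1.0])
    lams: list = field(default_factory=lambda: [20.0])
    Ks: list = field(default_factory=list)
    gammas: list = field(default_factory=list)
    alphas: list = field(default_factory=list)
    zetas: list = field(default_factory=list)
    mus: list = field(default_factory=list)
    nus: list = field(default_factory=list)
    s_gs: list = field(default_factory=list)

    def grid_points(self):
        import itertools

        axes = {
            "phi": self.phis or [self.base.phi],
            "lam": self.lams or [self.base.lam],
            "K": self.Ks or [self.base.K],
            "gamma": self.gammas or [self.base.gamma],
            "alpha": self.alphas or [self.base.alpha],
            "zeta": self.zetas or [self.base.zeta],
            "mu": self.mus or [self.base.mu],
            "nu": self.nus or [self.base.nu],
            "s_g": self.s_gs or [self.base.s_g],
        }
        names = list(axes)
        for values in itertools.product(*(axes[n] for n in names)):
            yield dict(zip(names, values))


def _profiles_for(params: ModelParams, config, cache, grid: AgeGrid) -> dict:
    gtypes = enumerate_group_types(config.n_founders)
    profiles = {}
    for gt in gtypes:
        if cache is not None:
            profiles[gt] = cache.get(
                gt, params, config.n_replicates, grid.centers, seed=config.seed
            )
        else:
            profiles[gt] = average_profile(
                gt, params, config.n_replicates, grid.centers, seed=config.seed
            )
    return profiles


def steady_state_run(params: ModelParams, config, cache=None,
                     record_every: float = 1.0):
    """Profiles + PDE integration to steady state for one parameter set."""
    grid = AgeGrid(dy=config.dy, n_cells=int(round(config.ymax_mult * params.lam / config.dy)))
    profiles = _profiles_for(params, config, cache, grid)
    pop, summaries = run_to_steady_state(
        params,
        profiles,
        grid,
        tol=config.steady_tol,
        t_max=config.t_max,
        cfl_safety=config.cfl_safety,
        record_every=record_every,
    )
    return pop, summaries, profiles


def steady_state_heatmap(spec: SweepSpec, cache=None) -> pd.DataFrame:
    """Steady-state global trait means for every grid point of a sweep.

    Failures at individual grid points are reported in the ``error``
    column; the sweep continues.
    """
    import warnings

    rows = []
    for point in spec.grid_points():
        row = dict(point)
        try:
            cfg = replace(spec.base, **point)
            params = cfg.model_params()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                pop, summaries, _ = steady_state_run(params, cfg, cache)
            final = summaries[-1]
            row.update(
                zbar_u=final.zbar_u,
                zbar_v=final.zbar_v,
                zbar_p=final.zbar_p,
                zbar_f=final.zbar_f,
                time=final.time,
                error="",
            )
        except Exception as exc:  # keep sweeping; report per grid point
            row.update(
                zbar_u=np.nan, zbar_v=np.nan, zbar_p=np.nan, zbar_f=np.nan,
                time=np.nan, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Long-run dynamics


def invasion_order(summaries_frame: pd.DataFrame, threshold: float = 0.25) -> list:
    """Genotypes ordered by the first time their global frequency exceeds
    ``threshold`` (strictly); genotypes that never do are omitted."""
    order = []
    for lab in genotype_labels():
        col = summaries_frame[f"freq_{lab}"].to_numpy()
        hit = np.nonzero(col > threshold)[0]
        if hit.size:
            order.append((float(summaries_frame["time"].iloc[hit[0]]), lab))
    return [lab for _, lab in sorted(order)]


def longrun_dynamics(params: ModelParams, phis, config, cache=None,
                     threshold: float = 0.25) -> dict:
    """Global summary time series and invasion order per phi value."""
    import warnings

    results = {}
    for phi in phis:
        p = params.with_(phi=float(phi))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pop, summaries, _ = steady_state_run(p, config, cache)
        frame = summaries_to_frame(summaries)
        results[float(phi)] = {
            "summaries": frame,
            "invasion_order": invasion_order(frame, threshold),
            "final": summaries[-1],
            "population": pop,
        }
    return results
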