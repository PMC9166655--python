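# pleiosim

An age-structured multilevel-selection simulator for the evolution of
cooperation and pleiotropy in cellular groups.

Cells carry three binary traits — a cooperative (public) trait, a
private trait, and a pleiotropy trait — giving 8 genotypes. Within each
group, cells divide, die, and mutate under frequency-dependent selection
(exact Gillespie simulation, logistic growth to a carrying capacity
`K`). When pleiotropy is active, a loss-of-function mutation in a fully
active cell couples the loss of the cooperative and private traits with
probability `phi`, which suppresses the emergence of cheater lineages.
Replicate-averaged within-group development then drives an
age-structured PDE for an infinite population of competing groups
(finite-volume solver with a superbee flux limiter), in which group
function — the product of mean cooperative and private trait expression
— confers a survival advantage. Variants cover a two-private-traits
control, two-cell founding (36 group types), a pleiotropy cost `zeta`,
germ-line transmission `gamma`, and delayed reproductive maturity
`alpha`.

## Layout

| Module | Contents |
| --- | --- |
| `pleiosim.genotype_space` | trait/genotype map, group-type enumeration |
| `pleiosim.mutation_kernel` | null (`Q`), pleiotropic (`P`), and blended (`H`) mutation matrices; offspring sampling |
| `pleiosim.within_group` | Gillespie birth–death–mutation core (numba), replicate-averaged profiles, fitness effects of mutations |
| `pleiosim.between_group` | age-structured PDE: superbee advection, group births/deaths, steady-state driver, global summaries, mutational load |
| `pleiosim.experiments` | scripted drivers: within-group dynamics per `phi`, steady-state sweeps, long-run dynamics and invasion order |
| `pleiosim.cli_io` | YAML/JSON config, content-addressed profile cache, run manifests, CLI |

## CLI

Each subcommand takes an optional `--config` (YAML/JSON; unknown keys
rejected, all fields defaulted) plus `--seed`, `--replicates`, `--out`.

```sh
# within-group cheater invasion for a g8 founder at three pleiotropy strengths
pleiosim within-group --phi 0 --phi 0.5 --phi 1 --seed 1 --out results/wg

# long-run global dynamics (profiles + PDE) per phi
pleiosim evolve --phi 0 --phi 1 --seed 1 --out results/evolve

# steady-state trait means over a (phi, lambda) grid
pleiosim sweep --phi 0 --phi 1 --lam 10 --lam 20 --seed 1 --out results/sweep
```

Outputs are CSV tables plus a JSON manifest (config, seed, version).
Within-group profiles are cached under `cache_dir` keyed by a hash of
exactly the inputs that determine them.

## Reproducibility

Every stochastic entry point takes a master seed; replicate seeds are
split from it with `numpy.random.SeedSequence`, so runs are bit-for-bit
reproducible at fixed seed and replicate count.
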