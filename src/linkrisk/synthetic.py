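"""Synthetic metawebs with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a shared species pool with hierarchical taxonomy sampled into many
local networks, heavy-tailed degree distributions, log-normally dispersed
visitation rates obeying a planted degree power law with mutualistic
trade-off ``true_delta``, and (optionally) interaction-level consistency in
link frequency.

Each local network is assembled as a union of complete bipartite modules
with equal numbers of plants and animals, plus sparse cross-module links
(``cross_link_prob``).  Module sizes are drawn from a discretised
log-normal, so degrees — approximately the module size on both sides of a
core link — are heterogeneous and heavy-tailed, mixing specialist pairs
(size-1 modules) with generalist cliques; cross links blur the module
degree classes the way imperfect compartmentalisation does in field data,
which keeps link generalisation (and hence vulnerability) effectively
free of ties.  The planted frequency law on realised degrees,

    ln f_ij = a0 + ln(d_i d_j) - true_delta * (ln d_i + ln d_j) / 2,

satisfies both guild-wise trade-off regressions exactly on pure modules
(d_i = d_j per link), so with every noise channel off — frequency noise 0
and cross_link_prob 0 — the trade-off estimator is exactly identified.

Within a guild, at most one species per genus enters a given network (a
random representative of each included genus), so genus-level interactions
recur only across networks and carry no within-network structural
correlation: with ``consistency_planted=False`` the generator is a true
null for the taxonomic-consistency test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_io import TAXONOMY_COLUMNS, WeightedBipartiteNetwork, validate_taxonomy


class GenerationError(RuntimeError):
    """Raised when a configuration cannot produce valid networks."""


def dataclasses_replace_connectance(cfg: "MetawebConfig", q: float) -> "MetawebConfig":
    """Copy of ``cfg`` whose module-core connectance compensates for the
    extra links added at cross-link probability ``q`` (C = C_mod + q(1-C_mod))."""
    import dataclasses

    c_mod = max(0.01, (cfg.target_connectance - q) / (1.0 - q))
    return dataclasses.replace(cfg, target_connectance=c_mod)


@dataclass
class MetawebConfig:
    """Configuration of the synthetic metaweb generator.

    Defaults describe a modest regional study: 10 local networks drawn from
    pools of 60 plant / 90 animal species, yielding roughly 40 links per
    network at connectance ~0.25, with the mutualistic trade-off planted at
    the empirical estimate 0.339 and log-normal visitation noise sigma 0.3
    (natural-log units).
    """

    n_networks: int = 10
    n_plant_species: int = 60
    n_animal_species: int = 90
    species_per_genus: int = 3
    genera_per_family: int = 2
    families_per_order: int = 3
    inclusion_prob: float = 0.7
    target_connectance: float = 0.25
    cross_link_prob: float = 0.08
    true_delta: float = 0.339
    base_log_rate: float = 1.6  # a0: ln visits for a specialist pair link
    frequency_noise_scale: float = 0.3
    consistency_planted: bool = True
    within_interaction_sd: float = 0.2
    between_interaction_sd: float = 0.8
    module_size_log_sd: float = 0.8
    network_type: str = "pollination"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.inclusion_prob <= 1):
            raise ValueError("inclusion_prob must be in (0, 1]")
        if not (0 < self.target_connectance < 1):
            raise ValueError("target_connectance must be in (0, 1)")
        if not (0 <= self.cross_link_prob < 1):
            raise ValueError("cross_link_prob must be in [0, 1)")
        if self.true_delta < 0 or self.frequency_noise_scale < 0:
            raise ValueError("true_delta and frequency_noise_scale must be >= 0")
        if self.within_interaction_sd < 0 or self.between_interaction_sd < 0:
            raise ValueError("interaction sds must be >= 0")
        if self.n_plant_species < 4 or self.n_animal_species < 4:
            raise ValueError("species pools must have >= 4 species")
        for name in ("n_networks", "species_per_genus", "genera_per_family", "families_per_order"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class MetawebTruth:
    """Latent ground truth of a generated metaweb, for testing."""

    true_delta: float
    base_log_rate: float
    interaction_latents: pd.DataFrame = field(repr=False)  # genus-pair level mu
    link_truths: pd.DataFrame = field(repr=False)  # per realised link


def _build_taxonomy(cfg: MetawebConfig) -> pd.DataFrame:
    rows = []
    for guild, prefix, n_species in [
        ("plant", "P", cfg.n_plant_species),
        ("animal", "A", cfg.n_animal_species),
    ]:
        for s in range(n_species):
            g = s // cfg.species_per_genus
            f = g // cfg.genera_per_family
            o = f // cfg.families_per_order
            rows.append(
                {
                    "species": f"{prefix}gen{g:03d}_sp{s % cfg.species_per_genus}",
                    "guild": guild,
                    "genus": f"{prefix}gen{g:03d}",
                    "family": f"{prefix}fam{f:03d}",
                    "order": f"{prefix}ord{o:02d}",
                }
            )
    return validate_taxonomy(pd.DataFrame(rows, columns=TAXONOMY_COLUMNS))


def _discrete_lognormal_pmf(mu: float, sigma: float, s_max: int) -> np.ndarray:
    """pmf of s = max(1, round(LogNormal(mu, sigma))) truncated at s_max."""
    from scipy.stats import norm

    s = np.arange(1, s_max + 1)
    upper = norm.cdf((np.log(s + 0.5) - mu) / sigma)
    lower = norm.cdf((np.log(s - 0.5) - mu) / sigma)
    pmf = upper - lower
    pmf[0] = upper[0]  # mass below 1.5 all maps to size 1
    pmf[-1] += 1.0 - upper[-1]
    return pmf / pmf.sum()


def _draw_module_sizes(rng: np.random.Generator, m: int, cfg: MetawebConfig) -> list[int]:
    """Module sizes covering ``m`` species pairs, heavy-tailed, with the
    size-weighted mean targeting ``target_connectance * m``.

    For complete bipartite modules of size s the network connectance is
    (sum s^2) / m^2 = (weighted mean size) / m.  Sizes follow a rounded
    log-normal whose location is solved by bisection against the weighted
    mean of the discretised distribution, so the realised connectance
    tracks the target despite rounding.
    """
    sigma = cfg.module_size_log_sd
    t = float(np.clip(cfg.target_connectance * m, 1.0, m))

    def weighted_mean(mu: float) -> float:
        pmf = _discrete_lognormal_pmf(mu, sigma, m)
        s = np.arange(1, m + 1)
        return float((pmf * s**2).sum() / (pmf * s).sum())

    lo, hi = -3.0, np.log(m) + 1.0
    if weighted_mean(lo) >= t:
        mu = lo
    elif weighted_mean(hi) <= t:
        mu = hi
    else:
        for _ in range(60):
            mid = (lo + hi) / 2.0
            if weighted_mean(mid) < t:
                lo = mid
            else:
                hi = mid
        mu = (lo + hi) / 2.0

    sizes: list[int] = []
    remaining = m
    while remaining > 0:
        s = 0
        for _retry in range(20):  # avoid clipping bias from oversize draws
            s = max(1, round(float(rng.lognormal(mu, sigma))))
            if s <= remaining:
                break
        sizes.append(min(s, remaining))
        remaining -= sizes[-1]
    return sizes


def generate_metaweb(
    cfg: MetawebConfig,
) -> tuple[list[WeightedBipartiteNetwork], pd.DataFrame, MetawebTruth]:
    """Generate local networks, their shared taxonomy, and latent truths."""
    rng = np.random.default_rng(cfg.seed)
    taxonomy = _build_taxonomy(cfg)

    plant_genera = sorted(taxonomy.loc[taxonomy.guild == "plant", "genus"].unique())
    animal_genera = sorted(taxonomy.loc[taxonomy.guild == "animal", "genus"].unique())
    species_of = {
        (row.guild, row.genus): []
        for row in taxonomy.itertuples()
    }
    for row in taxonomy.itertuples():
        species_of[(row.guild, row.genus)].append(row.species)

    # genus-pair latent offsets for planted consistency (drawn regardless of
    # the flag so the same seed gives the same graph structure either way)
    latent_mu = rng.normal(0.0, cfg.between_interaction_sd, (len(plant_genera), len(animal_genera)))
    pg_index = {g: i for i, g in enumerate(plant_genera)}
    ag_index = {g: j for j, g in enumerate(animal_genera)}
    latents = pd.DataFrame(
        [
            {"plant_genus": pg, "animal_genus": ag, "mu": latent_mu[i, j]}
            for i, pg in enumerate(plant_genera)
            for j, ag in enumerate(animal_genera)
        ]
    )

    networks: list[WeightedBipartiteNetwork] = []
    truth_rows = []
    for k in range(cfg.n_networks):
        for _attempt in range(200):
            incl_p = [g for g in plant_genera if rng.random() < cfg.inclusion_prob]
            incl_a = [g for g in animal_genera if rng.random() < cfg.inclusion_prob]
            if len(incl_p) >= 2 and len(incl_a) >= 2:
                break
        else:
            raise GenerationError(
                "could not draw >=2 genera per guild; raise inclusion_prob or pool size"
            )
        plants = [species_of[("plant", g)][rng.integers(len(species_of[("plant", g)]))] for g in incl_p]
        animals = [species_of[("animal", g)][rng.integers(len(species_of[("animal", g)]))] for g in incl_a]
        rng.shuffle(plants)
        rng.shuffle(animals)
        m = min(len(plants), len(animals))
        # module connectance adjusted so cross links keep the overall target
        q = cfg.cross_link_prob
        mod_cfg = cfg if q == 0 else dataclasses_replace_connectance(cfg, q)
        sizes = _draw_module_sizes(rng, m, mod_cfg)

        # module cores: complete bipartite blocks with matched plant/animal counts
        adjacency = np.zeros((m, m), dtype=bool)
        module_of = np.empty(m, dtype=int)
        start = 0
        for b, s in enumerate(sizes):
            adjacency[start : start + s, start : start + s] = True
            module_of[start : start + s] = b
            start += s
        # sparse cross-module links break the degree ties of perfect modules
        if q > 0:
            adjacency |= (~adjacency) & (rng.random((m, m)) < q)

        d_plant = adjacency.sum(axis=1).astype(float)
        d_animal = adjacency.sum(axis=0).astype(float)
        weights = np.zeros((m, m))
        for i, j in np.argwhere(adjacency):
            # symmetric planted trade-off law on realised degrees; reduces to
            # ln f = a0 + (2 - delta) ln s on pure modules (d_p = d_a = s)
            ln_f = cfg.base_log_rate + (1.0 - cfg.true_delta / 2.0) * (
                np.log(d_plant[i]) + np.log(d_animal[j])
            )
            pg = plants[i].split("_sp")[0]
            ag = animals[j].split("_sp")[0]
            latent = 0.0
            if cfg.consistency_planted:
                mu = latent_mu[pg_index[pg], ag_index[ag]]
                latent = mu + rng.normal(0.0, cfg.within_interaction_sd)
                ln_f += latent
            noise = rng.normal(0.0, cfg.frequency_noise_scale) if cfg.frequency_noise_scale > 0 else 0.0
            weights[i, j] = np.exp(ln_f + noise)
            truth_rows.append(
                {
                    "network_id": f"net{k:03d}",
                    "plant": plants[i],
                    "animal": animals[j],
                    "plant_genus": pg,
                    "animal_genus": ag,
                    "same_module": bool(module_of[i] == module_of[j]),
                    "d_plant": d_plant[i],
                    "d_animal": d_animal[j],
                    "latent": latent,
                    "ln_noise": noise,
                }
            )

        net = WeightedBipartiteNetwork(
            network_id=f"net{k:03d}",
            network_type=cfg.network_type,
            plant_names=plants[:m],
            animal_names=animals[:m],
            weights=weights,
        )
        networks.append(net)

    truth = MetawebTruth(
        true_delta=cfg.true_delta,
        base_log_rate=cfg.base_log_rate,
        interaction_latents=latents,
        link_truths=pd.DataFrame(truth_rows),
    )
    return networks, taxonomy, truth


def generate_glv_fixture(
    n_plants: int, n_animals: int, connectance: float, seed: int
) -> WeightedBipartiteNetwork:
    """Single random network where every species has at least one link.

    Cells are filled independently with probability ``connectance``
    (rejection-sampled until no species is isolated); weights are uniform
    integer counts in 1..9.  Intended for feasibility-domain tests.
    """
    if not (0 < connectance <= 1):
        raise ValueError("connectance must be in (0, 1]")
    if connectance * n_animals < 1 or connectance * n_plants < 1:
        raise GenerationError("connectance too low to give every species a link")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        adj = rng.random((n_plants, n_animals)) < connectance
        if adj.sum(axis=1).min() >= 1 and adj.sum(axis=0).min() >= 1:
            weights = adj * rng.integers(1, 10, size=adj.shape)
            return WeightedBipartiteNetwork(
                network_id=f"glv_fixture_{seed}",
                network_type="pollination",
                plant_names=[f"P{i}" for i in range(n_plants)],
                animal_names=[f"A{j}" for j in range(n_animals)],
                weights=weights.astype(float),
            )
    raise GenerationError(
        f"no isolate-free network found at connectance={connectance} in 1000 draws"
    )
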