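"""Taxonomic consistency of link properties via a variance null model.

An interaction is the metaweb-level identity of a link after aggregating
its two endpoint species to genus, family or order.  An interaction is
taxonomically consistent in a property (vulnerability, feasibility
contribution, frequency or generalisation) when its links vary less across
their occurrences than random same-size sets of links drawn from the rest
of the dataset.

For each interaction with >= 2 links, the observed sample variance is
compared against ``n_null`` null sets sampled without replacement from all
other links' property values.  P is the proportion of null sets whose
variance is strictly lower than the observed variance; consistency is the
mean of (Var_null - Var_obs), positive when occurrences are more similar
than chance; significance is declared at P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHA = 0.05
LEVELS = ("genus", "family", "order")
PROPERTIES = {
    "vulnerability": "V",
    "feasibility_contribution": "I_percent",
    "frequency": "f_std",
    "generalisation": "D_std",
}


def _minmax_mid(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def rescale_relative(table: pd.DataFrame, property_name: str) -> pd.Series:
    """Per-network relative values of a property.

    Vulnerability, frequency and generalisation are min-max rescaled within
    each network (constant groups map to 0.5) so only relative roles are
    compared across networks; feasibility contribution is already a
    relative (percent-ratio) quantity and passes through unchanged.
    """
    if property_name not in PROPERTIES:
        raise ValueError(f"unknown property {property_name!r}")
    column = PROPERTIES[property_name]
    values = table[column]
    if values.isna().all():
        raise ValueError(f"property column {column!r} is not populated")
    if property_name == "feasibility_contribution":
        return values.copy()
    out = values.astype(float).copy()
    for _, grp in table.groupby("network_id", sort=False):
        if grp.empty:
            raise ValueError("empty network group")
        out.loc[grp.index] = _minmax_mid(grp[column].to_numpy(dtype=float))
    return out


@dataclass
class AggregatedInteraction:
    """All links sharing one (plant taxon, animal taxon) identity."""

    level: str
    plant_taxon: str
    animal_taxon: str
    link_index: np.ndarray  # positional indices into the link table

    @property
    def n_links(self) -> int:
        return len(self.link_index)


def aggregate_links(
    table: pd.DataFrame, taxonomy: pd.DataFrame, level: str
) -> list[AggregatedInteraction]:
    """Group links by taxon pair at a level, dropping singleton groups.

    Multiple links of one interaction may come from the same network (two
    congeneric species each linking the same partner).  Raises if any link
    species is missing from the taxonomy.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    plant_map = taxonomy.loc[taxonomy.guild == "plant"].set_index("species")[level]
    animal_map = taxonomy.loc[taxonomy.guild == "animal"].set_index("species")[level]
    missing_p = sorted(set(table["plant"]) - set(plant_map.index))
    missing_a = sorted(set(table["animal"]) - set(animal_map.index))
    if missing_p or missing_a:
        raise KeyError(
            f"species missing from taxonomy: plants {missing_p[:5]}, animals {missing_a[:5]}"
        )
    plant_taxon = table["plant"].map(plant_map)
    animal_taxon = table["animal"].map(animal_map)
    groups: list[AggregatedInteraction] = []
    n_singletons = 0
    keys = pd.DataFrame({"p": plant_taxon.to_numpy(), "a": animal_taxon.to_numpy()})
    for (p, a), grp in keys.groupby(["p", "a"], sort=True):
        if len(grp) < 2:
            n_singletons += 1
            continue
        groups.append(AggregatedInteraction(level, str(p), str(a), grp.index.to_numpy()))
    if n_singletons:
        import logging

        logging.getLogger(__name__).info(
            "%s level: dropped %d singleton interactions, kept %d",
            level, n_singletons, len(groups),
        )
    return groups


@dataclass
class ConsistencyResult:
    """Null-model outcome for one aggregated interaction and property."""

    level: str
    plant_taxon: str
    animal_taxon: str
    property: str
    n_links: int
    var_obs: float
    mean_paired_diff: float  # mean(Var_null - Var_obs); > 0 = consistent
    p_value: float
    significant: bool
    n_null: int
    seed: int | None


def null_variance_test(
    group: AggregatedInteraction,
    values: np.ndarray,
    property_name: str,
    n_null: int = 1000,
    seed: int | None = None,
) -> ConsistencyResult:
    """Compare a group's property variance against same-size random link sets.

    ``values`` holds the (rescaled) property values of ALL links at this
    level; the focal group's own links are excluded from the sampling pool.
    Null sets are drawn without replacement.  Ties (Var_null == Var_obs)
    count as not lower, per the strict-inequality definition of P.
    """
    values = np.asarray(values, dtype=float)
    k = group.n_links
    if k < 2:
        raise ValueError("group must have >= 2 links (singletons are pre-filtered)")
    obs = values[group.link_index]
    pool = np.delete(values, group.link_index)
    if len(pool) < k:
        raise ValueError(
            f"pool of {len(pool)} links too small for null sets of size {k}"
        )
    var_obs = float(np.var(obs, ddof=1))
    rng = np.random.default_rng(seed)
    # vectorised without-replacement draws: argpartition of uniform keys
    keys = rng.random((n_null, len(pool)))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_sets = pool[idx]
    var_null = np.var(null_sets, axis=1, ddof=1)
    return ConsistencyResult(
        level=group.level,
        plant_taxon=group.plant_taxon,
        animal_taxon=group.animal_taxon,
        property=property_name,
        n_links=k,
        var_obs=var_obs,
        mean_paired_diff=float(np.mean(var_null - var_obs)),
        p_value=float(np.mean(var_null < var_obs)),
        significant=bool(np.mean(var_null < var_obs) < ALPHA),
        n_null=n_null,
        seed=seed,
    )


def exhaustive_variance_test(
    group: AggregatedInteraction, values: np.ndarray, property_name: str
) -> ConsistencyResult:
    """Exact analogue of :func:`null_variance_test` enumerating all null sets.

    Feasible only for small pools; used as an oracle for the sampled test.
    """
    from itertools import combinations

    values = np.asarray(values, dtype=float)
    obs = values[group.link_index]
    pool = np.delete(values, group.link_index)
    k = group.n_links
    var_obs = float(np.var(obs, ddof=1))
    var_null = np.array(
        [np.var(c, ddof=1) for c in combinations(pool, k)], dtype=float
    )
    return ConsistencyResult(
        level=group.level,
        plant_taxon=group.plant_taxon,
        animal_taxon=group.animal_taxon,
        property=property_name,
        n_links=k,
        var_obs=var_obs,
        mean_paired_diff=float(np.mean(var_null - var_obs)),
        p_value=float(np.mean(var_null < var_obs)),
        significant=bool(np.mean(var_null < var_obs) < ALPHA),
        n_null=len(var_null),
        seed=None,
    )


def run_consistency(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    property_name: str,
    level: str,
    n_null: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Null-model test for every aggregated interaction at one level.

    Excluded links (missing feasibility contribution) are dropped first
    when testing that property.  Returns one row per interaction.
    """
    work = table.reset_index(drop=True)
    if property_name == "feasibility_contribution":
        work = work.loc[~work["excluded"]].reset_index(drop=True)
    if work.empty or work[PROPERTIES[property_name]].isna().all():
        # e.g. every link excluded by the isolation rule: nothing to test
        return pd.DataFrame(
            columns=[f.name for f in ConsistencyResult.__dataclass_fields__.values()]
        )
    rescaled = rescale_relative(work, property_name).to_numpy(dtype=float)
    groups = aggregate_links(work, taxonomy, level)
    rng = np.random.default_rng(seed)
    results = []
    for group in groups:
        sub_seed = int(rng.integers(2**31))
        results.append(
            null_variance_test(group, rescaled, property_name, n_null=n_null, seed=sub_seed)
        )
    return pd.DataFrame([r.__dict__ for r in results])


def consistency_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Per (level, property) proportions of positive and significant consistency."""
    if results.empty:
        raise ValueError("no consistency results to summarise")
    rows = []
    for (level, prop), grp in results.groupby(["level", "property"]):
        rows.append(
            {
                "level": level,
                "property": prop,
                "n_interactions": len(grp),
                "prop_positive": float((grp["mean_paired_diff"] > 0).mean()),
                "prop_significant": float(grp["significant"].mean()),
            }
        )
    return pd.DataFrame(rows)
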