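"""Readers, writers and containers for weighted bipartite mutualistic networks.

Networks follow the web-of-life CSV layout: the header row holds animal
(pollinator / seed-disperser) names, the first column holds plant names, and
the body holds non-negative visitation counts or rates.  Blank cells and
``0`` both mean "no link".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NETWORK_TYPES = ("pollination", "seed_dispersal")

#: Column schema of the per-link table assembled across networks.
LINK_TABLE_COLUMNS = [
    "network_id",
    "plant",
    "animal",
    "weight",
    "f_std",
    "D_raw",
    "D_std",
    "V",
    "I_percent",
    "excluded",
]


class NetworkFormatError(ValueError):
    """Raised when an incidence matrix violates the expected format."""


class DegenerateNetworkError(ValueError):
    """Raised when a network has fewer than 2 species in a guild."""


@dataclass
class WeightedBipartiteNetwork:
    """One local network: plants x animals visitation weight matrix.

    Parameters
    ----------
    network_id : str
        Unique identifier of the local network.
    network_type : str
        Either ``"pollination"`` or ``"seed_dispersal"``.
    plant_names, animal_names : list of str
        Row and column labels; unique within their guild.
    weights : ndarray of shape (n_plants, n_animals)
        Non-negative visitation counts/rates; ``w[i, j] > 0`` marks a link.
    """

    network_id: str
    network_type: str
    plant_names: list[str]
    animal_names: list[str]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.network_type not in NETWORK_TYPES:
            raise NetworkFormatError(
                f"network_type must be one of {NETWORK_TYPES}, got {self.network_type!r}"
            )
        if self.weights.shape != (len(self.plant_names), len(self.animal_names)):
            raise NetworkFormatError("weights shape does not match species name lists")
        if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
            raise NetworkFormatError("weights must be finite and non-negative")
        if len(set(self.plant_names)) != len(self.plant_names):
            raise NetworkFormatError("duplicate plant names")
        if len(set(self.animal_names)) != len(self.animal_names):
            raise NetworkFormatError("duplicate animal names")
        if len(self.plant_names) < 2 or len(self.animal_names) < 2:
            raise DegenerateNetworkError(
                f"{self.network_id}: need >=2 species per guild, got "
                f"{len(self.plant_names)} plants x {len(self.animal_names)} animals"
            )
        if np.any(self.weights.sum(axis=1) == 0) or np.any(self.weights.sum(axis=0) == 0):
            raise NetworkFormatError(
                f"{self.network_id}: every species must have at least one link "
                "(prune all-zero rows/columns before constructing)"
            )

    # -- basic descriptors -------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plant_names)

    @property
    def n_animals(self) -> int:
        return len(self.animal_names)

    @property
    def adjacency(self) -> np.ndarray:
        """Binary link matrix L (1 where a link is present)."""
        return (self.weights > 0).astype(int)

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def connectance(self) -> float:
        return self.n_links / (self.n_plants * self.n_animals)

    def plant_degrees(self) -> np.ndarray:
        """Binary degree of each plant (number of animal partners)."""
        return self.adjacency.sum(axis=1)

    def animal_degrees(self) -> np.ndarray:
        """Binary degree of each animal (number of plant partners)."""
        return self.adjacency.sum(axis=0)

    def link_indices(self) -> np.ndarray:
        """(n_links, 2) array of (plant_idx, animal_idx) for present links, row-major."""
        return np.argwhere(self.weights > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.plant_names, columns=self.animal_names)


def prune_empty(
    weights: np.ndarray,
    plant_names: Sequence[str],
    animal_names: Sequence[str],
    network_id: str = "",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop all-zero rows/columns, warning once per removed species.

    Removal is iterated because dropping a column can empty a row.
    """
    weights = np.asarray(weights, dtype=float)
    plants = list(plant_names)
    animals = list(animal_names)
    while True:
        row_keep = weights.sum(axis=1) > 0
        col_keep = weights.sum(axis=0) > 0
        if row_keep.all() and col_keep.all():
            break
        for name, keep in zip(plants, row_keep):
            if not keep:
                logger.warning("%s: dropping plant %r with no links", network_id, name)
        for name, keep in zip(animals, col_keep):
            if not keep:
                logger.warning("%s: dropping animal %r with no links", network_id, name)
        weights = weights[np.ix_(row_keep, col_keep)]
        plants = [n for n, k in zip(plants, row_keep) if k]
        animals = [n for n, k in zip(animals, col_keep) if k]
    return weights, plants, animals


def read_incidence_matrix(
    path: str | Path, network_id: str, network_type: str
) -> WeightedBipartiteNetwork:
    """Read a web-of-life style CSV incidence matrix.

    First row = animal names, first column = plant names, numeric body.
    Blank cells count as 0.  All-zero rows/columns are pruned with a warning;
    negative entries raise :class:`NetworkFormatError` and a pruned matrix
    with fewer than two species in either guild raises
    :class:`DegenerateNetworkError`.
    """
    df = pd.read_csv(path, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(body).any():
        body = np.nan_to_num(body, nan=0.0) if df.isna().any().any() else body
    if np.isnan(body).any():
        raise NetworkFormatError(f"{path}: non-numeric entries in matrix body")
    if (body < 0).any():
        raise NetworkFormatError(f"{path}: negative entries in matrix body")
    weights, plants, animals = prune_empty(
        body, [str(i) for i in df.index], [str(c) for c in df.columns], network_id
    )
    if len(plants) < 2 or len(animals) < 2:
        raise DegenerateNetworkError(
            f"{path}: fewer than 2 species per guild after pruning empty rows/columns"
        )
    return WeightedBipartiteNetwork(network_id, network_type, plants, animals, weights)


def write_incidence_matrix(net: WeightedBipartiteNetwork, path: str | Path) -> None:
    """Write a network in the same CSV layout `read_incidence_matrix` expects."""
    net.to_frame().to_csv(path)


# -- taxonomy ---------------------------------------------------------------

TAXONOMY_COLUMNS = ["species", "guild", "genus", "family", "order"]


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a species -> genus/family/order table and validate it."""
    tax = pd.read_csv(path, dtype=str)
    return validate_taxonomy(tax)


def validate_taxonomy(tax: pd.DataFrame) -> pd.DataFrame:
    """Check taxonomy invariants.

    ``species`` unique within guild; each genus maps to exactly one family
    and each family to one order (the ranks form a tree).
    """
    missing = set(TAXONOMY_COLUMNS) - set(tax.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    bad_guild = set(tax["guild"]) - {"plant", "animal"}
    if bad_guild:
        raise ValueError(f"unknown guild values: {sorted(bad_guild)}")
    dup = tax.duplicated(subset=["species", "guild"])
    if dup.any():
        raise ValueError(f"duplicate species within guild: {tax.loc[dup, 'species'].tolist()}")
    for child, parent in [("genus", "family"), ("family", "order")]:
        # taxonomy names may repeat across guilds; the mapping must be a function per guild
        n_parents = tax.groupby(["guild", child])[parent].nunique()
        bad = n_parents[n_parents > 1]
        if not bad.empty:
            raise ValueError(f"{child} mapped to multiple {parent} values: {bad.index.tolist()}")
    return tax.reset_index(drop=True)


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax[TAXONOMY_COLUMNS].to_csv(path, index=False)


# -- dataset descriptors ----------------------------------------------------


def sampling_intensity(net: WeightedBipartiteNetwork) -> float:
    """Root of mean interaction events per possible link.

    sqrt( sum_ij w_ij / (n_plants * n_animals) ): a dimensionless measure of
    how thoroughly a network was sampled relative to its size.
    """
    return float(np.sqrt(net.weights.sum() / (net.n_plants * net.n_animals)))


def assemble_link_table(nets: Iterable[WeightedBipartiteNetwork]) -> pd.DataFrame:
    """One record per positive cell per network; metric columns start unset.

    Raises on duplicate network ids.  Record order is (network, plant row,
    animal column) but downstream code treats the table as a set of records.
    """
    nets = list(nets)
    ids = [n.network_id for n in nets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate network_id in collection")
    rows = []
    for net in nets:
        for i, j in net.link_indices():
            rows.append(
                {
                    "network_id": net.network_id,
                    "plant": net.plant_names[i],
                    "animal": net.animal_names[j],
                    "weight": net.weights[i, j],
                }
            )
    table = pd.DataFrame(rows, columns=["network_id", "plant", "animal", "weight"])
    for col in ("f_std", "D_raw", "D_std", "V", "I_percent"):
        table[col] = np.nan
    table["excluded"] = False
    return table[LINK_TABLE_COLUMNS]


def write_link_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the link table; missing I_percent becomes an empty cell."""
    table.to_csv(path, index=False)


def read_link_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    table["excluded"] = table["excluded"].astype(bool)
    return table
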