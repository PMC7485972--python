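"""Per-link vulnerability: frequency, generalisation, and V = (1-f)(1-D).

Vulnerability scores how likely a link is to be lost under stress: rare
links between specialists score near 1, frequent links between generalists
near 0.  Frequencies are log10-transformed and min-max standardised to
[0, 1] within each network; generalisation (mean binary degree of the two
endpoint species) is min-max standardised without a log transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network_io import WeightedBipartiteNetwork


def _minmax(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all 0.5.

    Ties carry no ranking information, so a degenerate (all-equal) column
    is placed at the midpoint rather than dividing by zero.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full(values.shape, 0.5)
    return (values - lo) / (hi - lo)


def standardize_frequency(net: WeightedBipartiteNetwork) -> np.ndarray:
    """f_std per present link (row-major link order), in [0, 1]."""
    w = net.weights[net.weights > 0]
    if np.any(w <= 0):
        raise ValueError("present links must have positive weight")
    return _minmax(np.log10(w))


def link_generalisation(net: WeightedBipartiteNetwork) -> tuple[np.ndarray, np.ndarray]:
    """(D_raw, D_std) per present link (row-major link order).

    D_raw is the mean of the two endpoint binary degrees; D_std its
    within-network min-max rescaling.
    """
    dp = net.plant_degrees()
    da = net.animal_degrees()
    idx = net.link_indices()
    d_raw = (dp[idx[:, 0]] + da[idx[:, 1]]) / 2.0
    return d_raw, _minmax(d_raw)


def vulnerability_index(f_std, d_std):
    """V = (1 - f_std)(1 - D_std), elementwise; inputs must lie in [0, 1]."""
    f_std = np.asarray(f_std, dtype=float)
    d_std = np.asarray(d_std, dtype=float)
    if np.any((f_std < 0) | (f_std > 1) | (d_std < 0) | (d_std > 1)):
        raise ValueError("standardised inputs must lie in [0, 1]")
    return (1.0 - f_std) * (1.0 - d_std)


def annotate_link_table(
    table: pd.DataFrame, nets: list[WeightedBipartiteNetwork]
) -> pd.DataFrame:
    """Fill f_std, D_raw, D_std and V columns of an assembled link table.

    Link order within each network follows row-major order of the weight
    matrix, matching ``assemble_link_table``.
    """
    table = table.copy()
    by_id = {net.network_id: net for net in nets}
    for nid, grp in table.groupby("network_id", sort=False):
        net = by_id[nid]
        f_std = standardize_frequency(net)
        d_raw, d_std = link_generalisation(net)
        if len(grp) != len(f_std):
            raise ValueError(f"{nid}: link table rows do not match network links")
        table.loc[grp.index, "f_std"] = f_std
        table.loc[grp.index, "D_raw"] = d_raw
        table.loc[grp.index, "D_std"] = d_std
        table.loc[grp.index, "V"] = vulnerability_index(f_std, d_std)
    return table
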