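"""Generalized Lotka-Volterra feasibility of mutualistic networks.

The community model couples plants P and animals A through

    dP_i/dt = P_i ( r_i - sum_j alpha_ij P_j + sum_j gamma_ij A_j )
    dA_i/dt = A_i ( r_i - sum_j alpha_ij A_j + sum_j gamma_ij P_j )

with mean-field within-guild competition (alpha_ii = 1, alpha_ij = rho) and
mutualistic benefit gamma_ij = gamma0 * L_ij / d_i**delta, where L is the
binary link matrix, d_i the partner count (degree) of species i and delta
the mutualistic trade-off.  At equilibrium r = B N with the block matrix

    B = [[ alpha^(P), -gamma^(P) ],
         [ -gamma^(A), alpha^(A) ]]

so the set of intrinsic growth-rate vectors r admitting a positive
equilibrium N > 0 — the feasibility domain — is the cone spanned by B's
columns.  Its size Omega is the community's safe operating space; the
feasibility contribution of a link is the percent change in Omega caused by
its removal.

Two Omega estimators are provided.  ``solid_angle`` measures the fraction
of uniformly random growth-rate directions inside the cone; it is unbiased
and analytically checkable, but the cone's solid angle shrinks roughly like
2**-S with community size S, so hits vanish beyond S of about 12.
``center_deviation`` starts from the analytic center of the cone and
measures, along random great-circle arcs, the mean angular deviation the
community tolerates before feasibility is lost (normalised by pi); it
remains informative at any S and is the default for network-scale runs.
Both are invariant to positive rescaling of B's columns, so the removal
ratio Omega_O / Omega_R is well defined under either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from .network_io import WeightedBipartiteNetwork

logger = logging.getLogger(__name__)

ESTIMATORS = ("solid_angle", "center_deviation")


class UnidentifiableError(ValueError):
    """Raised when the trade-off regression has no degree variation."""


class InfeasibleCenterError(RuntimeError):
    """Raised when the analytic center is not inside the feasibility cone."""


# ---------------------------------------------------------------------------
# trade-off estimation


@dataclass
class DeltaRegressionResult:
    """Pooled two-guild trade-off regression.

    ``delta`` is the sign-flipped common slope of the two guild regressions
    of log(f_ij / (d_i * d_j)) on the log focal-species degree, fitted
    jointly with guild-specific intercepts.
    """

    delta: float
    intercept_plants: float
    intercept_animals: float
    n_obs: int


def add_degree_columns(
    table: pd.DataFrame, nets: list[WeightedBipartiteNetwork]
) -> pd.DataFrame:
    """Attach binary endpoint degrees d_plant / d_animal to a link table."""
    table = table.copy()
    table["d_plant"] = np.nan
    table["d_animal"] = np.nan
    by_id = {net.network_id: net for net in nets}
    for nid, grp in table.groupby("network_id", sort=False):
        net = by_id[nid]
        dp = dict(zip(net.plant_names, net.plant_degrees()))
        da = dict(zip(net.animal_names, net.animal_degrees()))
        table.loc[grp.index, "d_plant"] = grp["plant"].map(dp).to_numpy()
        table.loc[grp.index, "d_animal"] = grp["animal"].map(da).to_numpy()
    return table


def estimate_delta(table: pd.DataFrame) -> DeltaRegressionResult:
    """Estimate the mutualistic trade-off delta from pooled link frequencies.

    Every link contributes one plant-side and one animal-side observation;
    a single least-squares fit with two guild intercepts and one common
    slope is run on the stacked design, and delta is minus that slope.
    Requires ``weight``, ``d_plant`` and ``d_animal`` columns.
    """
    w = table["weight"].to_numpy(dtype=float)
    dp = table["d_plant"].to_numpy(dtype=float)
    da = table["d_animal"].to_numpy(dtype=float)
    if np.any(w <= 0) or np.any(dp < 1) or np.any(da < 1):
        raise ValueError("links need positive weight and endpoint degrees >= 1")
    y_link = np.log(w / (dp * da))
    y = np.concatenate([y_link, y_link])
    x = np.concatenate([np.log(dp), np.log(da)])
    n = len(w)
    design = np.zeros((2 * n, 3))
    design[:n, 0] = 1.0  # plant intercept
    design[n:, 1] = 1.0  # animal intercept
    design[:, 2] = x
    if np.ptp(x) == 0:
        raise UnidentifiableError("no degree variation: trade-off slope unidentifiable")
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 3:
        raise UnidentifiableError("rank-deficient trade-off design")
    return DeltaRegressionResult(
        delta=float(-coef[2]),
        intercept_plants=float(coef[0]),
        intercept_animals=float(coef[1]),
        n_obs=2 * n,
    )


# ---------------------------------------------------------------------------
# system assembly


@dataclass
class GLVParameterSet:
    """Parameters defining one GLV mutualism system.

    ``adjacency`` is the binary plant x animal link matrix; degrees are
    derived from it, and gamma_ij = gamma0 * L_ij / d_i**delta.
    """

    rho: float
    delta: float
    gamma0: float
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.adjacency = (np.asarray(self.adjacency) > 0).astype(float)
        if self.rho < 0 or self.delta < 0 or self.gamma0 < 0:
            raise ValueError("rho, delta and gamma0 must be non-negative")

    @property
    def plant_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def animal_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)


@dataclass
class GLVSystem:
    """Assembled interaction matrix B with r = B N at equilibrium."""

    B: np.ndarray = field(repr=False)
    n_plants: int
    n_animals: int

    @property
    def size(self) -> int:
        return self.n_plants + self.n_animals


def _gamma_block(adjacency: np.ndarray, degrees: np.ndarray, gamma0: float, delta: float) -> np.ndarray:
    # degree**delta on the focal (row) side; degree-0 rows are all-zero links
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(degrees > 0, degrees, 1.0) ** delta
    return gamma0 * adjacency / scale[:, None]


def _mean_field_block(n: int, rho: float) -> np.ndarray:
    return (1.0 - rho) * np.eye(n) + rho * np.ones((n, n))


def build_system(net: WeightedBipartiteNetwork, params: GLVParameterSet) -> GLVSystem:
    """Assemble the block matrix B for a network and parameter set."""
    L = params.adjacency
    if L.shape != (net.n_plants, net.n_animals):
        raise ValueError("adjacency shape does not match network")
    gamma_p = _gamma_block(L, params.plant_degrees, params.gamma0, params.delta)
    gamma_a = _gamma_block(L.T, params.animal_degrees, params.gamma0, params.delta)
    top = np.hstack([_mean_field_block(net.n_plants, params.rho), -gamma_p])
    bottom = np.hstack([-gamma_a, _mean_field_block(net.n_animals, params.rho)])
    return GLVSystem(B=np.vstack([top, bottom]), n_plants=net.n_plants, n_animals=net.n_animals)


def _is_stable(B: np.ndarray) -> bool:
    """Positive definiteness of the symmetric part (global stability)."""
    sym = (B + B.T) / 2.0
    try:
        np.linalg.cholesky(sym)
        return True
    except np.linalg.LinAlgError:
        return False


def stability_threshold(
    net: WeightedBipartiteNetwork,
    delta: float,
    rho: float,
    adjacency: np.ndarray | None = None,
    rel_tol: float = 1e-6,
) -> float:
    """Largest gamma0 keeping (B + B^T)/2 positive definite, by bisection.

    The symmetric part's smallest eigenvalue is concave in gamma0, so the
    stable region is an interval [0, gamma0_max) and bisection is valid.
    """
    L = net.adjacency if adjacency is None else adjacency
    n_evals = 0

    def stable(g0: float) -> bool:
        nonlocal n_evals
        n_evals += 1
        sys = build_system(net, GLVParameterSet(rho=rho, delta=delta, gamma0=g0, adjacency=L))
        return _is_stable(sys.B)

    if not stable(0.0):
        raise RuntimeError(f"system unstable at gamma0=0 (rho={rho}); no threshold exists")
    if not L.any():
        raise ValueError("network without links has no mutualistic stability threshold")
    lo, hi = 0.0, 1.0
    while stable(hi):
        lo, hi = hi, hi * 2.0
        if hi > 2**40:
            raise RuntimeError("stability threshold bracket exceeded 2^40")
    while (hi - lo) / hi > rel_tol:
        mid = (lo + hi) / 2.0
        if stable(mid):
            lo = mid
        else:
            hi = mid
    logger.debug("stability_threshold: %d stability evaluations, gamma0_max=%.8g", n_evals, lo)
    return float((lo + hi) / 2.0)


# ---------------------------------------------------------------------------
# feasibility estimation


@dataclass
class FeasibilityEstimate:
    """Omega with estimator metadata and a Monte Carlo standard error."""

    omega: float
    estimator: str
    n_directions: int
    seed: int | None
    mc_standard_error: float


def structural_center(sys: GLVSystem) -> np.ndarray:
    """Unit growth-rate vector at the analytic center of the feasibility cone.

    The cone is generated by B's columns; the center is the normalised sum
    of the normalised generators, which lies strictly inside the cone
    whenever B is invertible (B^-1 r_c is a positive combination of basis
    vectors).
    """
    B = sys.B
    norms = np.linalg.norm(B, axis=0)
    if np.any(norms == 0):
        raise ValueError("B has a zero column; cone is degenerate")
    r_c = (B / norms).sum(axis=1)
    return r_c / np.linalg.norm(r_c)


def sample_directions(size: int, n_directions: int, seed: int | None) -> np.ndarray:
    """(size, n_directions) standard normal draws (isotropic directions)."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((size, n_directions))


def _checked_lu(B: np.ndarray):
    if not np.all(np.isfinite(B)) or np.linalg.cond(B) > 1e12:
        raise np.linalg.LinAlgError("B is singular or ill-conditioned; Omega undefined")
    return lu_factor(B)


def _omega_solid_angle_from_dirs(B: np.ndarray, dirs: np.ndarray) -> tuple[float, float]:
    lu = _checked_lu(B)
    inside = np.all(lu_solve(lu, dirs) > 0, axis=0)
    omega = float(inside.mean())
    se = float(np.sqrt(omega * (1.0 - omega) / dirs.shape[1]))
    return omega, se


def _omega_center_deviation_from_dirs(
    B: np.ndarray, dirs: np.ndarray, tol: float = 1e-4
) -> tuple[float, float]:
    lu = _checked_lu(B)
    S, n = dirs.shape
    r_c = structural_center(GLVSystem(B=B, n_plants=S, n_animals=0))
    if not np.all(lu_solve(lu, r_c) > 0):
        raise InfeasibleCenterError("analytic center outside feasibility cone")
    # orthonormal perturbation directions on the sphere, orthogonal to r_c
    u = dirs - np.outer(r_c, r_c @ dirs)
    norms = np.linalg.norm(u, axis=0)
    norms[norms == 0] = 1.0  # measure-zero degenerate draws stay at r_c (theta*=pi arc)
    u = u / norms

    def feasible(theta: np.ndarray, cols: np.ndarray) -> np.ndarray:
        v = r_c[:, None] * np.cos(theta) + u[:, cols] * np.sin(theta)
        return np.all(lu_solve(lu, v) > 0, axis=0)

    all_cols = np.arange(n)
    theta_star = np.full(n, np.pi)
    at_pi = feasible(np.full(n, np.pi), all_cols)
    active = ~at_pi
    lo = np.zeros(active.sum())
    hi = np.full(active.sum(), np.pi)
    cols = all_cols[active]
    while hi.size and (hi - lo).max() > tol:
        mid = (lo + hi) / 2.0
        feas = feasible(mid, cols)
        lo = np.where(feas, mid, lo)
        hi = np.where(feas, hi, mid)
    theta_star[cols] = (lo + hi) / 2.0
    frac = theta_star / np.pi
    return float(frac.mean()), float(frac.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def omega_solid_angle(sys: GLVSystem, n_directions: int = 10_000, seed: int | None = None) -> FeasibilityEstimate:
    """Omega as the fraction of isotropic growth-rate directions in the cone."""
    dirs = sample_directions(sys.size, n_directions, seed)
    omega, se = _omega_solid_angle_from_dirs(sys.B, dirs)
    return FeasibilityEstimate(omega, "solid_angle", n_directions, seed, se)


def omega_center_deviation(
    sys: GLVSystem, n_directions: int = 10_000, seed: int | None = None
) -> FeasibilityEstimate:
    """Omega as the mean tolerated arc deviation from the cone center / pi.

    For each random great-circle direction, bisection (tolerance 1e-4 rad)
    finds the critical angle at which the rotated growth-rate vector leaves
    the cone; theta* = pi if feasibility is never lost along the arc.
    """
    dirs = sample_directions(sys.size, n_directions, seed)
    omega, se = _omega_center_deviation_from_dirs(sys.B, dirs)
    return FeasibilityEstimate(omega, "center_deviation", n_directions, seed, se)


def _omega_from_dirs(B: np.ndarray, dirs: np.ndarray, estimator: str) -> float:
    if estimator == "solid_angle":
        return _omega_solid_angle_from_dirs(B, dirs)[0]
    if estimator == "center_deviation":
        return _omega_center_deviation_from_dirs(B, dirs)[0]
    raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")


# ---------------------------------------------------------------------------
# per-link feasibility contribution


class LinkExclusion(Exception):
    """Removal of this link would isolate a species; contribution undefined."""


def _removed_adjacency(adjacency: np.ndarray, plant_idx: int, animal_idx: int) -> np.ndarray:
    removed = adjacency.astype(float).copy()
    if removed[plant_idx, animal_idx] == 0:
        raise ValueError("focal link not present")
    removed[plant_idx, animal_idx] = 0.0
    if removed[plant_idx, :].sum() == 0 or removed[:, animal_idx].sum() == 0:
        raise LinkExclusion(f"removing link ({plant_idx}, {animal_idx}) isolates a species")
    return removed


def feasibility_contribution(
    net: WeightedBipartiteNetwork,
    plant_idx: int,
    animal_idx: int,
    params: GLVParameterSet,
    estimator: str = "center_deviation",
    n_directions: int = 10_000,
    seed: int | None = None,
) -> float:
    """Percent change in Omega when the focal link is removed.

    I = 100 * Omega_O / Omega_R - 100, with Omega_O (original) and Omega_R
    (removed, degrees recomputed at the same gamma0/delta/rho) estimated on
    the SAME direction sample so the ratio is low-variance.  Positive values
    mean removal shrinks the feasibility domain.  Raises
    :class:`LinkExclusion` if removal would isolate a species.
    """
    dirs = sample_directions(net.n_plants + net.n_animals, n_directions, seed)
    omega_o = _omega_from_dirs(build_system(net, params).B, dirs, estimator)
    removed = _removed_adjacency(params.adjacency, plant_idx, animal_idx)
    params_r = GLVParameterSet(
        rho=params.rho, delta=params.delta, gamma0=params.gamma0, adjacency=removed
    )
    omega_r = _omega_from_dirs(build_system(net, params_r).B, dirs, estimator)
    if omega_r == 0:
        raise ZeroDivisionError("Omega_R estimated as 0; contribution ratio undefined")
    return 100.0 * omega_o / omega_r - 100.0


def network_feasibility_run(
    net: WeightedBipartiteNetwork,
    rho: float,
    delta: float,
    estimator: str = "center_deviation",
    n_directions: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-link feasibility contributions for one network.

    gamma0 is calibrated once on the original topology (half the stability
    threshold) and held fixed across removals; Omega_O is estimated once and
    shares its direction sample with every Omega_R.  Links whose removal
    would isolate a species are flagged ``excluded`` with missing I.

    Returns a frame aligned with the network's row-major link order and a
    diagnostics dict (gamma0, threshold, Omega_O, inclusion counts).
    """
    gamma0_max = stability_threshold(net, delta, rho)
    gamma0 = gamma0_max / 2.0
    params = GLVParameterSet(rho=rho, delta=delta, gamma0=gamma0, adjacency=net.adjacency)
    dirs = sample_directions(net.n_plants + net.n_animals, n_directions, seed)
    omega_o = _omega_from_dirs(build_system(net, params).B, dirs, estimator)

    dp = net.plant_degrees()
    da = net.animal_degrees()
    rows = []
    for i, j in net.link_indices():
        if dp[i] == 1 or da[j] == 1:
            rows.append({"I_percent": np.nan, "excluded": True})
            continue
        removed = _removed_adjacency(params.adjacency, i, j)
        params_r = GLVParameterSet(rho=rho, delta=delta, gamma0=gamma0, adjacency=removed)
        omega_r = _omega_from_dirs(build_system(net, params_r).B, dirs, estimator)
        if omega_r == 0:
            raise ZeroDivisionError(
                f"{net.network_id}: Omega_R = 0 for link ({i}, {j}); "
                "increase n_directions or use the center_deviation estimator"
            )
        rows.append({"I_percent": 100.0 * omega_o / omega_r - 100.0, "excluded": False})
    result = pd.DataFrame(rows, columns=["I_percent", "excluded"])
    diagnostics = {
        "network_id": net.network_id,
        "gamma0_max": gamma0_max,
        "gamma0": gamma0,
        "omega_original": omega_o,
        "estimator": estimator,
        "n_directions": n_directions,
        "seed": seed,
        "n_links": int(len(result)),
        "n_excluded": int(result["excluded"].sum()),
        "n_included": int((~result["excluded"]).sum()),
    }
    logger.info(
        "%s: %d links, %d excluded (isolation rule), gamma0=%.4g",
        net.network_id, diagnostics["n_links"], diagnostics["n_excluded"], gamma0,
    )
    return result, diagnostics
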