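"""Resource budget model dynamics: single tree, coupled population, reduced map.

The single-tree map accumulates a surplus ``P_S`` each year; once the
reserve exceeds the threshold ``L_T`` the excess ``C_f`` is spent on
flowering and a proportional amount ``C_a = R_C * C_f`` on pollination
and fruiting.  In the coupled population the fruiting cost is modulated
by the pollen-availability term ``Y``, a power ``beta`` of the mean
flowering effort of the *other* trees, so an out-of-phase tree sets no
seed.  Seed production is ``C_S = C_f * Y`` and is the model analogue of
the crop level scored in field surveys.

When every tree is synchronised the population collapses onto a
one-dimensional piecewise-smooth map (`reduced_map`), whose
border-collision structure organises the period-adding bifurcations
studied in :mod:`mastsync.bifurcation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .params import ModelParams

__all__ = [
    "EnsembleTrajectory",
    "step_uncoupled",
    "step_coupled",
    "reduced_map",
    "simulate",
]


@dataclass
class EnsembleTrajectory:
    """Recorded state and fluxes of a GCM-RBM run, all shaped (N, T).

    ``S`` is the reserve at the start of each recorded year; ``C_f``,
    ``C_a``, ``C_S`` and ``Y`` are the flowering cost, fruiting cost,
    seed production and pollen term realised in that year.
    """

    S: NDArray[np.float64]
    C_f: NDArray[np.float64]
    C_a: NDArray[np.float64]
    C_S: NDArray[np.float64]
    Y: NDArray[np.float64]
    params: ModelParams

    @property
    def n_trees(self) -> int:
        return self.S.shape[0]

    @property
    def n_years(self) -> int:
        return self.S.shape[1]


def step_uncoupled(S: ArrayLike, params: ModelParams) -> tuple[NDArray, NDArray]:
    """One deterministic year of the uncoupled RBM (``P_S = P_0``).

    Returns ``(S_next, C_f)``.  Below threshold the surplus is hoarded;
    above it the whole excess is flowered and the reserve drops to
    ``L_T - R_C * C_f``, which may be negative after a heavy year (no
    floor is applied).
    """
    S = np.asarray(S, dtype=float)
    acc = S + params.P_0
    C_f = np.maximum(acc - params.L_T, 0.0)
    S_next = np.where(acc <= params.L_T, acc, params.L_T - params.R_C * C_f)
    return S_next, C_f


def _pollen_term(C_f: NDArray, params: ModelParams) -> NDArray:
    """Per-tree pollen availability Y_i, self term excluded.

    Y_i = [sum_{j != i} C_f_j / ((N-1) P_0)]^beta.  With beta = 0 the
    coupling vanishes (Y = 1 identically, including when nobody
    flowers).
    """
    if params.beta == 0:
        return np.ones_like(C_f)
    others = C_f.sum() - C_f
    base = others / ((params.N - 1) * params.P_0)
    return np.power(base, params.beta)


def step_coupled(
    S_vec: ArrayLike,
    params: ModelParams,
    sigma: float,
    delta_vec: ArrayLike,
) -> tuple[NDArray, NDArray, NDArray, NDArray, NDArray]:
    """One year of the globally coupled RBM with injected noise draws.

    Parameters
    ----------
    S_vec:
        Reserves of the N trees at the start of the year.
    sigma:
        Common (population-wide) standard-normal draw for the year.
    delta_vec:
        Individual standard-normal draws, one per tree.

    Returns
    -------
    (S_next, C_f, C_a, C_S, Y), each of shape (N,).

    Notes
    -----
    The noisy surplus is ``P_S_i = P_0 (1 + e_C sigma)(1 + e_I delta_i)``
    and is *not* clamped: a rare large negative draw may make it
    negative, which the model tolerates (the flowering cost itself is
    clamped at zero through the threshold branch).
    """
    S_vec = np.asarray(S_vec, dtype=float)
    if S_vec.ndim != 1 or S_vec.shape[0] != params.N:
        raise ValueError(f"S_vec must have shape ({params.N},), got {S_vec.shape}")
    if params.beta > 0 and params.N < 2:
        raise ValueError("pollen coupling requires N >= 2")
    delta_vec = np.asarray(delta_vec, dtype=float)
    if delta_vec.shape != S_vec.shape:
        raise ValueError("delta_vec must match S_vec in shape")

    P_S = params.P_0 * (1.0 + params.e_C * sigma) * (1.0 + params.e_I * delta_vec)
    acc = S_vec + P_S
    C_f = np.maximum(acc - params.L_T, 0.0)
    Y = _pollen_term(C_f, params)
    C_a = params.R_C * C_f * Y
    C_S = C_f * Y
    S_next = np.where(acc <= params.L_T, acc, acc - C_f - C_a)
    return S_next, C_f, C_a, C_S, Y


def reduced_map(
    S: ArrayLike,
    R_C: float,
    beta: float,
    P_0: float = 10.0,
    L_T: float = 100.0,
) -> NDArray | float:
    """Fully synchronised limit of the coupled map, as a scalar 1-D map.

    f(S) = S + P_0                                    if S + P_0 <= L_T
         = L_T - R_C (S + P_0 - L_T)^(beta+1) / P_0^beta   otherwise

    For beta = 0 this is exactly the uncoupled tent-like map.  The map
    is continuous but has a kink at the flowering border
    ``S = L_T - P_0``: the left derivative is 1 for every beta, the
    right derivative is ``-R_C`` for beta = 0 and 0 for beta > 0, which
    is what makes the bifurcations border-collision rather than smooth.
    """
    S = np.asarray(S, dtype=float)
    acc = S + P_0
    excess = np.maximum(acc - L_T, 0.0)
    flower = L_T - R_C * np.power(excess, beta + 1) / P_0**beta
    out = np.where(acc <= L_T, acc, flower)
    return float(out) if out.ndim == 0 else out


def simulate(params: ModelParams) -> EnsembleTrajectory:
    """Run the GCM-RBM and return the post-transient trajectory.

    Initial reserves are drawn uniformly on [0, L_T], one draw per tree.
    Noise draws follow a fixed fill order per year (the common draw
    first, then the individual draws in tree-index order) from a single
    generator seeded with ``params.seed``, so equal seeds give bitwise
    identical trajectories.

    Raises
    ------
    FloatingPointError
        If the state leaves the finite range (possible at extreme
        ``R_C * beta`` combinations, where the flowering branch is
        steeply expanding).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    S = rng.uniform(0.0, p.L_T, p.N)

    shape = (p.N, p.T_record)
    rec_S = np.empty(shape)
    rec_Cf = np.empty(shape)
    rec_Ca = np.empty(shape)
    rec_CS = np.empty(shape)
    rec_Y = np.empty(shape)

    total = p.T_transient + p.T_record
    for t in range(total):
        sigma = rng.standard_normal()
        delta = rng.standard_normal(p.N)
        S_next, C_f, C_a, C_S, Y = step_coupled(S, p, sigma, delta)
        if not np.all(np.isfinite(S_next)):
            raise FloatingPointError(
                f"non-finite reserve at iteration {t} "
                f"(R_C={p.R_C}, beta={p.beta}); the flowering branch is "
                "expanding too strongly for this parameter combination"
            )
        k = t - p.T_transient
        if k >= 0:
            rec_S[:, k] = S
            rec_Cf[:, k] = C_f
            rec_Ca[:, k] = C_a
            rec_CS[:, k] = C_S
            rec_Y[:, k] = Y
        S = S_next

    return EnsembleTrajectory(
        S=rec_S, C_f=rec_Cf, C_a=rec_Ca, C_S=rec_CS, Y=rec_Y, params=p
    )
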