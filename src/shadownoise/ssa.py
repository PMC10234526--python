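"""Exact stochastic simulation (Gillespie direct method) of built networks.

Serves both as the pipeline's synthetic-data generator (sample mRNA traces of
the kind measured in live *Drosophila* embryos) and as a sampling-based oracle
for the moment-closure results. Trajectories start from the all-empty enhancer
state with zero TFs and mRNA, and are recorded on a regular time grid.

The inner event loop is compiled with numba when available; the pure-Python
fallback runs the same source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .model_core import ReactionNetwork
from .moments import MomentState


def _ssa_core_py(rates, i1, i2, stoich_t, x0, grid, seed):  # pragma: no cover - thin
    np.random.seed(seed)
    n_rxn = rates.shape[0]
    n_sp = x0.shape[0]
    n_grid = grid.shape[0]
    x = x0.copy()
    out = np.zeros((n_grid, n_sp), dtype=np.int64)
    props = np.zeros(n_rxn)
    t = 0.0
    g = 0
    t_end = grid[n_grid - 1]
    while g < n_grid:
        a0 = 0.0
        for r in range(n_rxn):
            a = rates[r]
            if i1[r] >= 0:
                a *= x[i1[r]]
            if i2[r] >= 0:
                a *= x[i2[r]]
            props[r] = a
            a0 += a
        if a0 <= 0.0:
            while g < n_grid:
                out[g] = x
                g += 1
            break
        t_next = t + np.random.exponential(1.0 / a0)
        while g < n_grid and grid[g] < t_next:
            out[g] = x
            g += 1
        if t_next > t_end:
            break
        t = t_next
        u = np.random.random() * a0
        acc = 0.0
        rxn = n_rxn - 1
        for r in range(n_rxn):
            acc += props[r]
            if u <= acc:
                rxn = r
                break
        for s in range(n_sp):
            x[s] += stoich_t[rxn, s]
    return out


try:  # compile the identical kernel when numba is present
    from numba import njit

    _ssa_core = njit(cache=False)(_ssa_core_py)
except Exception:  # pragma: no cover
    _ssa_core = _ssa_core_py


@dataclass
class Trajectory:
    """One SSA realization sampled on a regular grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species) integer copy numbers
    species: tuple[str, ...]
    seed: int
    network: ReactionNetwork

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        df["seed"] = self.seed
        return df


def gillespie_simulate(network: ReactionNetwork, t_end: float, seed: int,
                       grid_dt: float = 0.5) -> Trajectory:
    """Statistically exact sample path of the network's master equation.

    Identical (network, seed) pairs give bit-identical trajectories. If the
    total propensity reaches zero (possible only in networks without
    constant-rate reactions) the state is frozen for the remaining grid.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rates, i1, i2 = network.propensity_arrays()
    stoich_t = np.ascontiguousarray(network.stoichiometry().T)
    x0 = network.initial_vector()
    grid = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    states = _ssa_core(rates, i1, i2, stoich_t, x0, grid, int(seed) % 2**31)
    return Trajectory(times=grid, states=states,
                      species=tuple(network.species_names),
                      seed=int(seed), network=network)


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic per-trajectory seed ladder from a base seed."""
    return np.asarray(np.random.SeedSequence(int(base_seed)).generate_state(n)
                      % np.uint32(2**31), dtype=np.int64)


def ensemble_stats(network: ReactionNetwork, n_traj: int = 200,
                   t_end: float = 500.0, burn_in: float = 100.0,
                   base_seed: int = 0, grid_dt: float = 0.5) -> MomentState:
    """Stationary moments estimated by combined ensemble and time averaging.

    Each trajectory contributes its time average of first and second raw
    moments over the window [burn_in, t_end]; the pooled averages give means,
    variances and covariances. Monte Carlo standard errors (per-species means
    and the derived noise/fidelity/Fano metrics) are obtained by jackknife over
    trajectories, which treats each trajectory as one independent batch.
    """
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    if not 0 <= burn_in < t_end:
        raise ValueError("burn_in must lie in [0, t_end)")
    rates, i1, i2 = network.propensity_arrays()
    stoich_t = np.ascontiguousarray(network.stoichiometry().T)
    x0 = network.initial_vector()
    grid = np.arange(0.0, t_end + 0.5 * grid_dt, grid_dt)
    keep = grid >= burn_in
    seeds = derive_seeds(base_seed, n_traj)

    S = len(network.species)
    m1 = np.zeros((n_traj, S))
    m2 = np.zeros((n_traj, S, S))
    for k in range(n_traj):
        states = _ssa_core(rates, i1, i2, stoich_t, x0, grid, int(seeds[k]))
        w = states[keep].astype(float)
        m1[k] = w.mean(axis=0)
        m2[k] = w.T @ w / w.shape[0]

    mean = m1.mean(axis=0)
    raw2 = m2.mean(axis=0)
    cov = raw2 - np.outer(mean, mean)
    names = tuple(network.species_names)

    output = "R" if "R" in names else names[0]

    def metric_vec(mm1: np.ndarray, mm2: np.ndarray) -> dict:
        cc = mm2 - np.outer(mm1, mm1)
        st = MomentState(species=names, mean=mm1, cov=0.5 * (cc + cc.T),
                         method="ssa")
        st.pathological = False  # sampling estimates: do not gate on round-off
        return _metrics.metrics_row(st, species=output)

    # Jackknife standard errors over trajectories.
    full = metric_vec(mean, raw2)
    jack = {key: [] for key in full}
    jack_mean = np.zeros((n_traj, S))
    s1, s2 = m1.sum(axis=0), m2.sum(axis=0)
    for k in range(n_traj):
        mm1 = (s1 - m1[k]) / (n_traj - 1)
        mm2 = (s2 - m2[k]) / (n_traj - 1)
        jack_mean[k] = mm1
        for key, val in metric_vec(mm1, mm2).items():
            jack[key].append(val)
    fac = (n_traj - 1) / n_traj
    se = {f"se_{key}": float(np.sqrt(fac * np.sum((np.asarray(v) - np.nanmean(v)) ** 2)))
          if np.all(np.isfinite(v)) else float("nan")
          for key, v in jack.items()}
    se["mean"] = np.sqrt(fac * ((jack_mean - jack_mean.mean(axis=0)) ** 2).sum(axis=0))

    state = MomentState(species=names, mean=mean, cov=0.5 * (cov + cov.T),
                        se=se, method="ssa")
    state.pathological = bool(np.any(np.diag(state.cov) < -1e-9))
    return state
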