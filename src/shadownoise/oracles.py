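"""Benchmark networks with independently known answers.

These fixtures make every other module testable without external data: simple
birth-death and bursty birth-death processes and the two-state telegraph
promoter have closed-form stationary moments, while small enhancer systems can
be solved exactly by brute force on a truncated copy-number box
(:func:`solve_cme_truncated`). Together they form a consistency triangle —
closed form, truncated master equation, and SSA ensemble — that brackets the
moment-closure error.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model_core import (EnhancerSpec, ModelError, RateParameters, Reaction,
                         ReactionNetwork, Species, SystemConfig, build_network,
                         make_kruppel_config)
from .moments import MomentState

FIXTURES = ("birth_death", "bursty_birth_death", "telegraph",
            "single_enhancer_T1", "kruppel")

MAX_TRUNCATED_STATES = 50_000


def make_fixture(name: str, **overrides) -> ReactionNetwork:
    """Build one of the named benchmark networks.

    ``birth_death(k, alpha)``: 0 -> R at k, R -> 0 at alpha (Poisson).
    ``bursty_birth_death(beta, n, delta)``: bursts of n molecules at rate beta,
    linear decay delta. ``telegraph(kon, koff, rho, alpha)``: two-state
    promoter driving mRNA. ``single_enhancer_T1``: one enhancer with one T1
    site at the default fitted rates. ``kruppel``: the full two-enhancer model.
    """
    if name == "birth_death":
        k = float(overrides.pop("k", 10.0))
        alpha = float(overrides.pop("alpha", 2.0))
        _no_extra(overrides)
        return ReactionNetwork(
            species=[Species(name="R", role="mrna")],
            reactions=[
                Reaction(name="birth", reactants=(), products=(("R", 1),),
                         rate=k, order="constant", propensity_species=()),
                Reaction(name="death", reactants=(("R", 1),), products=(),
                         rate=alpha, order="first", propensity_species=("R",)),
            ],
            conservation_groups=[], initial_state={})
    if name == "bursty_birth_death":
        beta = float(overrides.pop("beta", 0.33))
        n = int(overrides.pop("n", 4))
        delta = float(overrides.pop("delta", 2.7))
        _no_extra(overrides)
        if n < 1:
            raise ModelError("burst size must be >= 1")
        return ReactionNetwork(
            species=[Species(name="T1", role="free_tf", tf_type=0)],
            reactions=[
                Reaction(name="burst", reactants=(), products=(("T1", n),),
                         rate=beta, order="constant", propensity_species=()),
                Reaction(name="degrade", reactants=(("T1", 1),), products=(),
                         rate=delta, order="first", propensity_species=("T1",)),
            ],
            conservation_groups=[], initial_state={})
    if name == "telegraph":
        kon = float(overrides.pop("kon", 1.0))
        koff = float(overrides.pop("koff", 0.5))
        rho = float(overrides.pop("rho", 20.0))
        alpha = float(overrides.pop("alpha", 1.96))
        _no_extra(overrides)
        return ReactionNetwork(
            species=[Species(name="G0", role="enhancer_state", occupancy=(0,)),
                     Species(name="G1", role="enhancer_state", occupancy=(1,)),
                     Species(name="R", role="mrna")],
            reactions=[
                Reaction(name="on", reactants=(("G0", 1),), products=(("G1", 1),),
                         rate=kon, order="first", propensity_species=("G0",)),
                Reaction(name="off", reactants=(("G1", 1),), products=(("G0", 1),),
                         rate=koff, order="first", propensity_species=("G1",)),
                Reaction(name="transcribe", reactants=(("G1", 1),),
                         products=(("G1", 1), ("R", 1)), rate=rho, order="first",
                         propensity_species=("G1",)),
                Reaction(name="degrade", reactants=(("R", 1),), products=(),
                         rate=alpha, order="first", propensity_species=("R",)),
            ],
            conservation_groups=[["G0", "G1"]], initial_state={"G0": 1})
    if name == "single_enhancer_T1":
        params = overrides.pop("params", RateParameters())
        _no_extra(overrides)
        return build_network(SystemConfig(enhancers=(EnhancerSpec((1, 0)),),
                                          params=params))
    if name == "kruppel":
        _no_extra(overrides)
        return build_network(make_kruppel_config())
    raise ModelError(f"unknown fixture {name!r}; known: {FIXTURES}")


def _no_extra(overrides: dict) -> None:
    if overrides:
        raise ModelError(f"unknown fixture overrides: {sorted(overrides)}")


def closed_form_moments(name: str, **params) -> MomentState:
    """Exact stationary moments for fixtures that admit a closed form.

    birth_death: Poisson with mean = var = k/alpha. bursty_birth_death:
    mean n*beta/delta, Fano (n+1)/2. telegraph: the standard two-state promoter
    result, including cov(G1, R).
    """
    if name == "birth_death":
        k = float(params.get("k", 10.0))
        alpha = float(params.get("alpha", 2.0))
        m = k / alpha
        return MomentState(species=("R",), mean=np.array([m]),
                           cov=np.array([[m]]), method="closed_form")
    if name == "bursty_birth_death":
        beta = float(params.get("beta", 0.33))
        n = int(params.get("n", 4))
        delta = float(params.get("delta", 2.7))
        m = n * beta / delta
        v = m * (n + 1) / 2.0
        return MomentState(species=("T1",), mean=np.array([m]),
                           cov=np.array([[v]]), method="closed_form")
    if name == "telegraph":
        kon = float(params.get("kon", 1.0))
        koff = float(params.get("koff", 0.5))
        rho = float(params.get("rho", 20.0))
        alpha = float(params.get("alpha", 1.96))
        p = kon / (kon + koff)
        m = rho * p / alpha
        # E[G1*R] from the stationary cross-moment balance (G1^2 = G1).
        u = (kon * m + rho * p) / (kon + koff + alpha)
        c = u - p * m
        raw2_R = (2.0 * rho * u + rho * p + alpha * m) / (2.0 * alpha)
        v_r = raw2_R - m * m
        v_g = p * (1.0 - p)
        mean = np.array([1.0 - p, p, m])
        cov = np.array([[v_g, -v_g, -c],
                        [-v_g, v_g, c],
                        [-c, c, v_r]])
        return MomentState(species=("G0", "G1", "R"), mean=mean, cov=cov,
                           method="closed_form")
    raise ModelError(f"no closed form for fixture {name!r}")


# ---------------------------------------------------------------------------
# Brute-force truncated master equation
# ---------------------------------------------------------------------------

def default_copy_bounds(network: ReactionNetwork, sd_mult: float = 10.0,
                        pilot_seed: int = 12345) -> dict[str, int]:
    """Heuristic truncation bounds: mean + ``sd_mult`` standard deviations from
    a short pilot SSA ensemble, per unconserved species."""
    from .ssa import ensemble_stats

    pilot = ensemble_stats(network, n_traj=20, t_end=200.0, burn_in=50.0,
                           base_seed=pilot_seed)
    grouped = {n for g in network.conservation_groups for n in g}
    bounds = {}
    for i, name in enumerate(network.species_names):
        if name in grouped:
            continue
        sd = float(np.sqrt(max(pilot.cov[i, i], 0.0)))
        bounds[name] = max(10, int(np.ceil(pilot.mean[i] + sd_mult * sd)))
    return bounds


def solve_cme_truncated(network: ReactionNetwork,
                        copy_bounds: dict[str, int] | None = None,
                        max_states: int = MAX_TRUNCATED_STATES) -> MomentState:
    """Exact stationary distribution of the master equation on a finite box.

    Conserved enhancer-state groups are enumerated exactly (no truncation);
    every other species is capped at ``copy_bounds[name]`` with a reflecting
    boundary. The stationary law of the truncated generator is obtained by a
    sparse linear solve, and the probability mass sitting on the boundary is
    reported in ``state.se['truncation_error']`` as a truncation-quality proxy.
    """
    if copy_bounds is None:
        copy_bounds = default_copy_bounds(network)
    names = network.species_names
    index = {n: i for i, n in enumerate(names)}
    grouped = {n for g in network.conservation_groups for n in g}
    free_species = [n for n in names if n not in grouped]
    missing = [n for n in free_species if n not in copy_bounds]
    if missing:
        raise ModelError(f"copy_bounds missing for species {missing}")

    # Enumerate per-dimension values: one dimension per conservation group
    # (which member carries the single copy) and one per free species.
    dims: list[list[np.ndarray]] = []
    S = len(names)
    for g in network.conservation_groups:
        vals = []
        for member in g:
            v = np.zeros(S, dtype=np.int64)
            v[index[member]] = 1
            vals.append(v)
        dims.append(vals)
    for n in free_species:
        vals = []
        for c in range(copy_bounds[n] + 1):
            v = np.zeros(S, dtype=np.int64)
            v[index[n]] = c
            vals.append(v)
        dims.append(vals)

    n_states = int(np.prod([len(d) for d in dims]))
    if n_states > max_states:
        raise ModelError(
            f"truncated state space has {n_states} states (> {max_states}); "
            "use the SSA ensemble instead")
    if n_states < 2:
        counts = sum(d[0] for d in dims) if dims else np.zeros(S, dtype=np.int64)
        state = MomentState(species=tuple(names), mean=counts.astype(float),
                            cov=np.zeros((S, S)), method="cme",
                            se={"truncation_error": 1.0})
        return state

    # Full copy-number table for all states, shape (n_states, S).
    combos = list(itertools.product(*[range(len(d)) for d in dims]))
    counts = np.zeros((n_states, S), dtype=np.int64)
    for row, combo in enumerate(combos):
        for d, choice in enumerate(combo):
            counts[row] += dims[d][choice]
    lookup = {tuple(counts[row]): row for row in range(n_states)}

    rates, i1, i2 = network.propensity_arrays()
    stoich_t = network.stoichiometry().T  # (n_rxn, S)
    bound_vec = np.array([copy_bounds.get(n, np.iinfo(np.int64).max)
                          for n in names], dtype=np.int64)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_states)
    for row in range(n_states):
        x = counts[row]
        for r in range(len(rates)):
            a = float(rates[r])
            if i1[r] >= 0:
                a *= x[i1[r]]
            if i2[r] >= 0:
                a *= x[i2[r]]
            if a <= 0.0:
                continue
            new = x + stoich_t[r]
            if np.any(new < 0) or np.any(new > bound_vec):
                continue  # reflecting boundary
            col = lookup[tuple(new)]
            rows.append(row)
            cols.append(col)
            vals.append(a)
            diag[row] -= a
    Q = sp.coo_matrix((vals + list(diag),
                       (rows + list(range(n_states)),
                        cols + list(range(n_states)))),
                      shape=(n_states, n_states)).tocsr()

    A = Q.T.tolil()
    A[-1, :] = 1.0
    b = np.zeros(n_states)
    b[-1] = 1.0
    p = spla.spsolve(A.tocsr(), b)
    p = np.maximum(p, 0.0)
    p /= p.sum()

    mean = p @ counts
    raw2 = counts.T @ (counts * p[:, None])
    cov = raw2 - np.outer(mean, mean)

    at_boundary = np.zeros(n_states, dtype=bool)
    for n in free_species:
        at_boundary |= counts[:, index[n]] == copy_bounds[n]
    state = MomentState(species=tuple(names), mean=mean.astype(float),
                        cov=0.5 * (cov + cov.T), method="cme",
                        se={"truncation_error": float(p[at_boundary].sum())})
    return state
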