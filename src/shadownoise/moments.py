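"""Raw-moment ODEs with zero-cumulant (Gaussian) closure for mass-action networks.

For a jump process with reactions ``r`` of stoichiometry ``s_r`` and propensity
``a_r(x)``, every raw moment E[x_J] (J a multiset of species) obeys

    d E[x_J] / dt = sum_r E[ a_r(x) * ( prod_p (x_{J_p} + s_r[J_p]) - prod_p x_{J_p} ) ]

Expanding the product turns the right-hand side into a linear combination of raw
moments; with propensities of order <= 2, moment equations of order N involve
raw moments up to order N + 2. Closure sets all cumulants above the truncation
order to zero and re-expresses the excess raw moments as polynomials in the
retained ones (for order 2 this is the Gaussian identity
E[xyz] = E[x]E[yz] + E[y]E[xz] + E[z]E[xy] - 2 E[x]E[y]E[z]).

The equations are assembled numerically from stoichiometry/propensity data into
flat coefficient tables (no symbolic math), evaluated with vectorized numpy,
and integrated to stationarity with a stiff-capable solver.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import LSODA
from scipy.optimize import root

from .model_core import ModelError, ReactionNetwork


class ClosureError(ModelError):
    pass


class NonConvergenceError(RuntimeError):
    """Stationary solve did not converge by t_max; carries the last state."""

    def __init__(self, message: str, state: "MomentState"):
        super().__init__(message)
        self.state = state


@dataclass
class MomentState:
    """Stationary first and second moments of all species.

    ``pathological`` marks negative closure variances (a known Gaussian-closure
    failure mode at low copy number); metrics refuse such states. ``se`` holds
    Monte Carlo standard errors when the state comes from an SSA ensemble.
    """

    species: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    converged: bool = True
    pathological: bool = False
    se: dict | None = None
    method: str = "mc2"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        self._index = {s: i for i, s in enumerate(self.species)}
        if self.cov.shape != (len(self.species),) * 2:
            raise ValueError("covariance must be square over the species")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8, rtol=1e-6):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        if np.any(np.diag(self.cov) < -1e-9):
            self.pathological = True

    def index(self, name: str) -> int:
        return self._index[name]

    def mean_of(self, name: str) -> float:
        return float(self.mean[self.index(name)])

    def var_of(self, name: str) -> float:
        i = self.index(name)
        return float(self.cov[i, i])

    def cov_of(self, a: str, b: str) -> float:
        return float(self.cov[self.index(a), self.index(b)])

    def permuted(self, order: Sequence[str]) -> "MomentState":
        idx = [self.index(s) for s in order]
        return MomentState(species=tuple(order), mean=self.mean[idx],
                           cov=self.cov[np.ix_(idx, idx)],
                           converged=self.converged,
                           pathological=self.pathological, method=self.method)


# ---------------------------------------------------------------------------
# Zero-cumulant closure algebra
# ---------------------------------------------------------------------------

def _set_partitions(items: tuple[int, ...]):
    """All partitions of a position tuple into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + (first,)] + part[i + 1:]
        yield part + [(first,)]


def _poly_mul(a: dict, b: dict) -> dict:
    out: dict = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            key = tuple(sorted(ka + kb))
            out[key] = out.get(key, 0.0) + va * vb
    return out


def _cumulant_poly(block: tuple[int, ...]) -> dict:
    """Joint cumulant of the species in `block` as a polynomial in raw moments.

    Moebius inversion over set partitions: kappa(A) = sum_pi (-1)^{k-1} (k-1)!
    prod_B m(B). Monomials are tuples of sorted raw-moment keys.
    """
    positions = tuple(range(len(block)))
    out: dict = {}
    for part in _set_partitions(positions):
        coef = (-1.0) ** (len(part) - 1) * math.factorial(len(part) - 1)
        key = tuple(sorted(tuple(sorted(block[p] for p in blk)) for blk in part))
        out[key] = out.get(key, 0.0) + coef
    return out


@lru_cache(maxsize=None)
def closed_moment_poly(idx: tuple[int, ...], order: int) -> tuple:
    """Raw moment E[x_idx] (degree > order) under zero cumulants above `order`.

    Returns ``((coef, (moment_key, ...)), ...)``: a polynomial whose variables
    are retained raw moments (sorted species-index tuples of degree <= order).
    """
    positions = tuple(range(len(idx)))
    total: dict = {}
    for part in _set_partitions(positions):
        if any(len(blk) > order for blk in part):
            continue
        poly = {(): 1.0}
        for blk in part:
            block_species = tuple(sorted(idx[p] for p in blk))
            poly = _poly_mul(poly, _cumulant_poly(block_species))
        for key, coef in poly.items():
            total[key] = total.get(key, 0.0) + coef
    return tuple((coef, key) for key, coef in sorted(total.items()) if coef != 0.0)


def close_third_moment(means: np.ndarray, second_raw: np.ndarray,
                       ijk: tuple[int, int, int]) -> float:
    """Gaussian-closure third raw moment
    E[x_i x_j x_k] = E[x_i]E[x_j x_k] + E[x_j]E[x_i x_k] + E[x_k]E[x_i x_j]
    - 2 E[x_i]E[x_j]E[x_k]; symmetric under permutation of (i, j, k)."""
    i, j, k = ijk
    m, M = np.asarray(means, float), np.asarray(second_raw, float)
    return float(m[i] * M[j, k] + m[j] * M[i, k] + m[k] * M[i, j]
                 - 2.0 * m[i] * m[j] * m[k])


# ---------------------------------------------------------------------------
# Moment system assembly
# ---------------------------------------------------------------------------

@dataclass
class MomentSystem:
    """Closed moment ODEs for one network: flat term tables grouped by the
    number of state factors in each term, for vectorized RHS evaluation."""

    network: ReactionNetwork
    order: int
    keys: list[tuple[int, ...]]
    key_index: dict = field(repr=False)
    term_groups: list = field(repr=False)  # [(out_idx, coef, factor_idx (n,f))]

    @property
    def n(self) -> int:
        return len(self.keys)

    def __post_init__(self) -> None:
        # Precompute scatter matrices (output x terms) per factor count:
        # much faster than np.add.at for repeated RHS evaluation.
        import scipy.sparse as _sp

        self._scatter = []
        for out_idx, coef, fidx in self.term_groups:
            m = _sp.csr_matrix(
                (np.ones(len(out_idx)), (out_idx, np.arange(len(out_idx)))),
                shape=(self.n, len(out_idx)))
            self._scatter.append((m, coef, fidx))

    def jac(self, y: np.ndarray) -> np.ndarray:
        """Analytic dense Jacobian of :meth:`rhs` (the RHS is polynomial)."""
        J = np.zeros((self.n, self.n))
        for out_idx, coef, fidx in self.term_groups:
            nf = fidx.shape[1]
            for c in range(nf):
                vals = coef.copy()
                for c2 in range(nf):
                    if c2 != c:
                        vals = vals * y[fidx[:, c2]]
                np.add.at(J, (out_idx, fidx[:, c]), vals)
        return J

    def rhs(self, y: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n)
        for m, coef, fidx in self._scatter:
            if fidx.shape[1] == 0:
                contrib = coef
            else:
                contrib = coef * y[fidx[:, 0]]
                for c in range(1, fidx.shape[1]):
                    contrib = contrib * y[fidx[:, c]]
            out += m @ contrib
        return out

    def initial_condition(self) -> np.ndarray:
        x0 = self.network.initial_vector().astype(float)
        y0 = np.empty(self.n)
        for pos, key in enumerate(self.keys):
            y0[pos] = float(np.prod(x0[list(key)]))
        return y0

    def unpack(self, y: np.ndarray, converged: bool = True,
               method: str | None = None) -> MomentState:
        S = len(self.network.species)
        mean = np.array([y[self.key_index[(i,)]] for i in range(S)])
        raw2 = np.empty((S, S))
        for i in range(S):
            for j in range(i, S):
                raw2[i, j] = raw2[j, i] = y[self.key_index[tuple(sorted((i, j)))]]
        cov = raw2 - np.outer(mean, mean)
        return MomentState(species=tuple(self.network.species_names), mean=mean,
                           cov=0.5 * (cov + cov.T), converged=converged,
                           method=method or f"mc{self.order}")


def derive_moment_odes(network: ReactionNetwork, order: int = 2,
                       closure: str = "zero_cumulant") -> MomentSystem:
    """Build the closed raw-moment ODE system of the given truncation order.

    Only mass-action propensities of order <= 2 are supported; higher-order
    propensities raise :class:`ClosureError`.
    """
    if closure != "zero_cumulant":
        raise ClosureError(f"unsupported closure {closure!r}")
    if order not in (2, 3):
        raise ClosureError("truncation order must be 2 or 3")

    S = len(network.species)
    keys: list[tuple[int, ...]] = []
    for deg in range(1, order + 1):
        keys.extend(itertools.combinations_with_replacement(range(S), deg))
    key_index = {k: i for i, k in enumerate(keys)}

    stoich = network.stoichiometry()
    rates, i1, i2 = network.propensity_arrays()
    for r in network.reactions:
        if r.order not in ("constant", "first", "second"):
            raise ClosureError("propensity order > 2 is unsupported")

    # terms[(out, factors)] -> coefficient
    terms: dict[tuple[int, tuple[int, ...]], float] = {}

    def add_term(out: int, coef: float, monomial: tuple[int, ...]) -> None:
        if coef == 0.0:
            return
        if len(monomial) <= order:
            factors = (key_index[monomial],) if monomial else ()
            key = (out, factors)
            terms[key] = terms.get(key, 0.0) + coef
        else:
            for c, mon_keys in closed_moment_poly(monomial, order):
                factors = tuple(sorted(key_index[mk] for mk in mon_keys))
                key = (out, factors)
                terms[key] = terms.get(key, 0.0) + coef * c

    for j in range(len(network.reactions)):
        k_rate = float(rates[j])
        if k_rate == 0.0:
            continue
        prop = tuple(int(v) for v in (i1[j], i2[j]) if v >= 0)
        s_col = stoich[:, j]
        for J in keys:
            q = len(J)
            svals = [int(s_col[sp]) for sp in J]
            if all(v == 0 for v in svals):
                continue
            for mask in range(1, 1 << q):
                coef = 1.0
                rest: list[int] = []
                for p in range(q):
                    if mask >> p & 1:
                        coef *= svals[p]
                    else:
                        rest.append(J[p])
                if coef == 0.0:
                    continue
                monomial = tuple(sorted(prop + tuple(rest)))
                add_term(key_index[J], k_rate * coef, monomial)

    # Group terms by factor count into flat arrays.
    by_f: dict[int, list] = {}
    for (out, factors), coef in terms.items():
        if coef == 0.0:
            continue
        by_f.setdefault(len(factors), []).append((out, coef, factors))
    groups = []
    for f, items in sorted(by_f.items()):
        out_idx = np.array([t[0] for t in items], dtype=np.int64)
        coef = np.array([t[1] for t in items], dtype=np.float64)
        fidx = np.array([t[2] for t in items], dtype=np.int64).reshape(len(items), f)
        groups.append((out_idx, coef, fidx))

    return MomentSystem(network=network, order=order, keys=keys,
                        key_index=key_index, term_groups=groups)


def _residual_norm(system: MomentSystem, y: np.ndarray) -> float:
    v = system.rhs(y)
    return float(np.max(np.abs(v)) / (1.0 + np.max(np.abs(y))))


def solve_stationary(system: MomentSystem, tol: float = 1e-8,
                     t_max: float = 1e4) -> MomentState:
    """Integrate the closed moment ODEs from the deterministic initial state
    (all enhancers empty, zero TFs and mRNA) until the relative RHS norm drops
    below ``tol``, with a Newton polish of the integration endpoint.

    Raises :class:`NonConvergenceError` (carrying the last state) if the
    criterion is not met by ``t_max``. Negative stationary variances only set
    the ``pathological`` flag; downstream metrics refuse such states.
    """
    if not (tol > 0 and np.isfinite(tol)):
        raise ValueError("tol must be finite and > 0")
    y = system.initial_condition()
    fun = lambda t, yy: system.rhs(yy)

    # Closed moment systems can blow up in finite time (a known zero-cumulant
    # instability at unfavourable parameters). Stepping the solver manually
    # bounds the cost: a hard step budget and a magnitude cap turn divergence
    # into a prompt NonConvergenceError instead of an integrator stall.
    blowup_cap = 1e14
    steps_left = 20_000
    n_means = len(system.network.species)

    def diverged(msg: str) -> NonConvergenceError:
        return NonConvergenceError(msg, system.unpack(y, converged=False))

    t0, t1 = 0.0, 50.0
    polish_attempts = 3
    while True:
        solver = LSODA(fun, t0, y, t_bound=min(t1, t_max),
                       rtol=1e-10, atol=1e-10,
                       jac=lambda t, yy: system.jac(yy))
        while solver.status == "running":
            if steps_left <= 0:
                raise diverged("step budget exhausted before stationarity "
                               "(likely closure instability)")
            solver.step()
            steps_left -= 1
            if not np.all(np.isfinite(solver.y)) or \
                    np.max(np.abs(solver.y)) > blowup_cap or \
                    np.min(solver.y[:n_means]) < -1e3:
                raise diverged("moment system diverged (closure instability "
                               "at these parameters)")
        if solver.status == "failed":
            raise diverged("stiff integration failed before stationarity")
        y = solver.y
        res = _residual_norm(system, y)
        if res < tol:
            return system.unpack(y)
        if res < tol * 1e6 and polish_attempts > 0:
            polish_attempts -= 1
            polished = _polish(system, y, tol)
            if polished is not None:
                return system.unpack(polished)
        if t1 >= t_max:
            raise NonConvergenceError(
                f"no stationary state by t_max={t_max:g} "
                f"(relative RHS norm {res:.3g} > tol {tol:g})",
                system.unpack(y, converged=False))
        t0, t1 = t1, t1 * 4.0


def _polish(system: MomentSystem, y: np.ndarray, tol: float) -> np.ndarray | None:
    try:
        sol = root(system.rhs, y, jac=system.jac, method="hybr",
                   options={"maxfev": 300})
    except Exception:
        return None
    if not sol.success:
        return None
    move = np.max(np.abs(sol.x - y)) / (1.0 + np.max(np.abs(y)))
    if move > 1e-2:  # refused: polish jumped to a different root
        return None
    if _residual_norm(system, sol.x) < tol:
        return sol.x
    return None


def stationary_moments(network: ReactionNetwork, order: int = 2,
                       tol: float = 1e-8, t_max: float = 1e4) -> MomentState:
    """Convenience wrapper: derive the closed moment ODEs and solve them."""
    return solve_stationary(derive_moment_odes(network, order=order), tol=tol,
                            t_max=t_max)
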