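"""Declarative enhancer-system configurations and their mass-action reaction networks.

An enhancer system is described by a :class:`SystemConfig`: a list of enhancers
(each a vector of TF binding-site counts), a set of kinetic rate parameters
(:class:`RateParameters`, defaulting to values fitted to *Kruppel* shadow-enhancer
expression data), an additivity regime, and linear kon/koff modulation
coefficients. :func:`build_network` translates a configuration into an explicit
chemical reaction network over free-TF, mRNA and enhancer-occupancy species in
which every propensity is mass action of order at most two.

Occupancy is represented with one species per occupancy state: a k-site enhancer
contributes 2**k species forming a conservation group that always sums to one
copy. For the ``saturation`` and ``synergy`` regimes — whose transcription rule
depends on the joint occupancy of *all* enhancers — the builder enumerates the
joint occupancy space instead, keeping propensities bimolecular at most.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

REGIMES = ("additive", "subadditive", "superadditive", "saturation", "synergy")

#: Default kon decrement / koff increment per enhancer for the subadditive regime,
#: one coefficient per TF type (T1, T2).
SUBADDITIVE_D1 = (0.04, 0.02)
SUBADDITIVE_D2 = (0.75, 0.75)
#: Default kon increment / koff decrement per enhancer for the superadditive regime.
SUPERADDITIVE_D1 = (0.01, 0.01)
SUPERADDITIVE_D2 = (0.4, 0.3)

#: Hard cap on occupancy-state explosion: 2**k species per k-site group.
MAX_SITES_PER_GROUP = 12


class ModelError(ValueError):
    """Invalid enhancer-system specification."""


class NegativeRateError(ModelError):
    """A linearly modulated kon/koff became negative (not clamped by design)."""


class ModulationError(ModelError):
    """Rate modulation applied more than once to the same parameter set."""


@dataclass(frozen=True)
class RateParameters:
    """Kinetic rates of the enhancer model, one entry per TF type.

    Defaults are the rates fitted to *Kruppel* expression data: TF bursts of size
    n_m arrive at rate ``burst_rate[m]`` (beta1, gamma1), free TFs degrade at
    ``tf_degradation[m]`` (beta_-1, gamma_-1), each bound site of TF type m
    drives transcription at ``transcription_rate[m]`` (r1, r2) under the additive
    rule, and mRNA degrades at ``mrna_degradation`` (alpha). All rates share one
    consistent arbitrary time unit.
    """

    kon: tuple[float, ...] = (0.36, 0.19)
    koff: tuple[float, ...] = (1.8, 1.5)
    burst_rate: tuple[float, ...] = (0.33, 0.29)
    burst_size: tuple[int, ...] = (4, 12)
    tf_degradation: tuple[float, ...] = (2.7, 3.9)
    transcription_rate: tuple[float, ...] = (120.0, 140.0)
    mrna_degradation: float = 1.96
    modulated: bool = False

    def __post_init__(self) -> None:
        n = len(self.kon)
        for name in ("koff", "burst_rate", "burst_size", "tf_degradation",
                     "transcription_rate"):
            if len(getattr(self, name)) != n:
                raise ModelError(f"per-TF field {name!r} must have length {n}")
        for name in ("kon", "koff", "burst_rate", "tf_degradation",
                     "transcription_rate"):
            if any(v < 0 for v in getattr(self, name)):
                raise NegativeRateError(f"negative rate in {name!r}")
        if self.mrna_degradation < 0:
            raise NegativeRateError("negative mRNA degradation rate")
        if any(int(s) != s or s < 1 for s in self.burst_size):
            raise ModelError("burst sizes must be integers >= 1")

    @property
    def n_tf_types(self) -> int:
        return len(self.kon)


@dataclass(frozen=True)
class EnhancerSpec:
    """One enhancer: number of binding sites per TF type."""

    site_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_counts", tuple(int(c) for c in self.site_counts))
        if any(c < 0 for c in self.site_counts):
            raise ModelError("site counts must be >= 0")
        if sum(self.site_counts) == 0:
            raise ModelError("enhancer must have at least one binding site")

    @property
    def total_sites(self) -> int:
        return sum(self.site_counts)

    @property
    def site_tf_types(self) -> tuple[int, ...]:
        """TF type of each site, sites ordered by TF type."""
        out: list[int] = []
        for tf, count in enumerate(self.site_counts):
            out.extend([tf] * count)
        return tuple(out)


def _default_d(regime: str, which: int, n_tf: int) -> tuple[float, ...]:
    if regime == "subadditive":
        base = SUBADDITIVE_D1 if which == 1 else SUBADDITIVE_D2
    elif regime == "superadditive":
        base = SUPERADDITIVE_D1 if which == 1 else SUPERADDITIVE_D2
    else:
        return (0.0,) * n_tf
    if n_tf <= len(base):
        return base[:n_tf]
    return base + (base[-1],) * (n_tf - len(base))


@dataclass(frozen=True)
class SystemConfig:
    """Declarative description of an enhancer system.

    ``d1``/``d2`` are the per-TF linear modulation coefficients (kon shift and
    koff shift per enhancer). When ``None`` they take the regime defaults.
    ``saturation_rate`` is the single transcription rate used by the saturation
    and synergy regimes; ``None`` means r1.
    """

    enhancers: tuple[EnhancerSpec, ...]
    params: RateParameters = field(default_factory=RateParameters)
    regime: str = "additive"
    d1: tuple[float, ...] | None = None
    d2: tuple[float, ...] | None = None
    saturation_rate: float | None = None

    def __post_init__(self) -> None:
        enh = tuple(e if isinstance(e, EnhancerSpec) else EnhancerSpec(tuple(e))
                    for e in self.enhancers)
        object.__setattr__(self, "enhancers", enh)
        if len(self.enhancers) < 1:
            raise ModelError("at least one enhancer is required")
        if self.regime not in REGIMES:
            raise ModelError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        n_tf = self.params.n_tf_types
        if any(len(e.site_counts) != n_tf for e in self.enhancers):
            raise ModelError("enhancer site-count vectors must match the number of TF types")
        for name in ("d1", "d2"):
            val = getattr(self, name)
            if val is not None:
                val = tuple(float(v) for v in val)
                if len(val) != n_tf or any(v < 0 for v in val):
                    raise ModelError(f"{name} must be {n_tf} coefficients >= 0")
                object.__setattr__(self, name, val)

    @property
    def n_enhancers(self) -> int:
        return len(self.enhancers)

    @property
    def total_site_counts(self) -> tuple[int, ...]:
        """(tau1, tau2, ...) — total sites per TF type over all enhancers."""
        n_tf = self.params.n_tf_types
        return tuple(sum(e.site_counts[t] for e in self.enhancers) for t in range(n_tf))

    def effective_d(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        n_tf = self.params.n_tf_types
        d1 = self.d1 if self.d1 is not None else _default_d(self.regime, 1, n_tf)
        d2 = self.d2 if self.d2 is not None else _default_d(self.regime, 2, n_tf)
        return d1, d2

    def canonical(self) -> "SystemConfig":
        """Enhancers sorted lexicographically by site-count vector."""
        return replace(self, enhancers=tuple(sorted(self.enhancers,
                                                    key=lambda e: e.site_counts)))

    def label(self) -> str:
        return "|".join(",".join(map(str, e.site_counts))
                        for e in self.canonical().enhancers)


@dataclass(frozen=True)
class Species:
    name: str
    role: str  # free_tf | mrna | enhancer_state
    enhancer_index: int | None = None
    occupancy: tuple[int, ...] | None = None
    tf_type: int | None = None


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction of order <= 2.

    ``order`` is one of ``constant``, ``first``, ``second``;
    ``propensity_species`` names the 0, 1 or 2 species whose copy numbers enter
    the propensity ``rate * prod(copies)``.
    """

    name: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: float
    order: str
    propensity_species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise NegativeRateError(f"reaction {self.name!r} has negative rate")
        n_prop = {"constant": 0, "first": 1, "second": 2}
        if self.order not in n_prop:
            raise ModelError(f"unsupported propensity order {self.order!r}")
        if len(self.propensity_species) != n_prop[self.order]:
            raise ModelError("propensity species inconsistent with order")


@dataclass
class ReactionNetwork:
    """Concrete mass-action network plus per-group conservation bookkeeping."""

    species: list[Species]
    reactions: list[Reaction]
    conservation_groups: list[list[str]]
    initial_state: dict[str, int]

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ModelError("duplicate species names")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self._index[name]

    def stoichiometry(self):
        """Net stoichiometry matrix, shape (n_species, n_reactions)."""
        import numpy as np

        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for name, c in r.reactants:
                S[self._index[name], j] -= c
            for name, c in r.products:
                S[self._index[name], j] += c
        return S

    def propensity_arrays(self):
        """(rates, i1, i2) with -1 for absent propensity factors."""
        import numpy as np

        rates = np.array([r.rate for r in self.reactions], dtype=np.float64)
        i1 = np.full(len(self.reactions), -1, dtype=np.int64)
        i2 = np.full(len(self.reactions), -1, dtype=np.int64)
        for j, r in enumerate(self.reactions):
            idx = [self._index[n] for n in r.propensity_species]
            if len(idx) > 0:
                i1[j] = idx[0]
            if len(idx) > 1:
                i2[j] = idx[1]
        return rates, i1, i2

    def initial_vector(self):
        import numpy as np

        x0 = np.zeros(len(self.species), dtype=np.int64)
        for name, c in self.initial_state.items():
            x0[self._index[name]] = c
        return x0

    def canonical_key(self):
        """Hashable form invariant to species/reaction listing order."""
        sp = tuple(sorted((s.name, s.role) for s in self.species))
        rx = tuple(sorted(
            (tuple(sorted(r.reactants)), tuple(sorted(r.products)), round(r.rate, 12),
             r.order, tuple(sorted(r.propensity_species)))
            for r in self.reactions))
        groups = tuple(sorted(tuple(sorted(g)) for g in self.conservation_groups))
        return sp, rx, groups


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def make_kruppel_config() -> SystemConfig:
    """The two-enhancer *Kruppel* system: enhancer A with one T1 site and
    enhancer B with one T2 site, additive regime, fitted default rates."""
    return SystemConfig(enhancers=(EnhancerSpec((1, 0)), EnhancerSpec((0, 1))))


def apply_rate_modulation(
    params: RateParameters,
    regime: str,
    n_enhancers: int,
    d1: Sequence[float] | None = None,
    d2: Sequence[float] | None = None,
) -> RateParameters:
    """Linearly shift kon/koff with the enhancer count n.

    Subadditive: kon -> kon - n*d1, koff -> koff + n*d2 (TFs bind less, leave
    faster). Superadditive flips both signs. Other regimes return ``params``
    unchanged. A resulting negative rate raises :class:`NegativeRateError`
    rather than being clamped.
    """
    if regime not in REGIMES:
        raise ModelError(f"unknown regime {regime!r}")
    if regime not in ("subadditive", "superadditive"):
        return params
    if params.modulated:
        raise ModulationError("rate modulation must be applied exactly once")
    if n_enhancers < 1:
        raise ModelError("n_enhancers must be >= 1")
    n_tf = params.n_tf_types
    d1 = tuple(d1) if d1 is not None else _default_d(regime, 1, n_tf)
    d2 = tuple(d2) if d2 is not None else _default_d(regime, 2, n_tf)
    if len(d1) != n_tf or len(d2) != n_tf or any(v < 0 for v in d1 + d2):
        raise ModelError("modulation coefficients must be per-TF and >= 0")
    sign = -1.0 if regime == "subadditive" else 1.0
    kon = tuple(k + sign * n_enhancers * d for k, d in zip(params.kon, d1))
    koff = tuple(k - sign * n_enhancers * d for k, d in zip(params.koff, d2))
    for name, vals in (("kon", kon), ("koff", koff)):
        if any(v < 0 for v in vals):
            raise NegativeRateError(
                f"{regime} modulation with n={n_enhancers} drives {name} negative: {vals}")
    return replace(params, kon=kon, koff=koff, modulated=True)


def transcription_rate(
    occupancy_by_enhancer: Sequence[Sequence[int]],
    enhancers: Sequence[EnhancerSpec],
    params: RateParameters,
    regime: str,
    saturation_rate: float | None = None,
) -> float:
    """Instantaneous mRNA production rate for a joint occupancy pattern.

    Additive family (additive/sub/superadditive): sum over enhancers of
    (bound T1 sites)*r1 + (bound T2 sites)*r2 + ... — sub/superadditivity acts
    only through the binding rates, never through this formula. Saturation:
    the single rate r whenever at least one enhancer has a bound TF. Synergy:
    r only when *every* enhancer has at least one bound TF.
    """
    if regime not in REGIMES:
        raise ModelError(f"unknown regime {regime!r}")
    if len(occupancy_by_enhancer) != len(enhancers):
        raise ModelError("one occupancy vector per enhancer required")
    for occ, enh in zip(occupancy_by_enhancer, enhancers):
        if len(occ) != enh.total_sites:
            raise ModelError("occupancy vector length must equal the site count")
    if regime in ("additive", "subadditive", "superadditive"):
        total = 0.0
        for occ, enh in zip(occupancy_by_enhancer, enhancers):
            for bit, tf in zip(occ, enh.site_tf_types):
                if bit:
                    total += params.transcription_rate[tf]
        return total
    r = saturation_rate if saturation_rate is not None else params.transcription_rate[0]
    bound = [any(occ) for occ in occupancy_by_enhancer]
    if regime == "saturation":
        return r if any(bound) else 0.0
    return r if all(bound) else 0.0


def _occupancy_states(n_sites: int) -> list[tuple[int, ...]]:
    return list(itertools.product((0, 1), repeat=n_sites))


def _enhancer_letter(i: int) -> str:
    # A, B, ..., Z, E26, E27, ...
    return chr(ord("A") + i) if i < 26 else f"E{i}"


def _state_name(enh_idx: int, occ: tuple[int, ...]) -> str:
    return f"{_enhancer_letter(enh_idx)}{''.join(map(str, occ))}"


def build_network(config: SystemConfig) -> ReactionNetwork:
    """Translate a :class:`SystemConfig` into a mass-action reaction network.

    Produces, per occupancy state and empty site, a bimolecular binding reaction
    (free TF + state -> state with the site filled, rate kon of the site's TF
    type); per filled site a first-order unbinding reaction (rate koff); a
    catalytic mRNA-production reaction for every occupancy state with positive
    regime-dependent transcription rate; per TF a constant-rate burst production
    (of ``burst_size`` molecules) and first-order degradation; and first-order
    mRNA degradation. kon/koff are the post-modulation effective rates.
    """
    cfg = config
    d1, d2 = cfg.effective_d()
    eff = apply_rate_modulation(cfg.params, cfg.regime, cfg.n_enhancers, d1, d2)
    joint = cfg.regime in ("saturation", "synergy")

    if joint:
        total = sum(e.total_sites for e in cfg.enhancers)
        if total > MAX_SITES_PER_GROUP:
            raise ModelError(
                f"{cfg.regime} systems enumerate the joint occupancy space; "
                f"{total} total sites exceeds the cap of {MAX_SITES_PER_GROUP}")
    else:
        for e in cfg.enhancers:
            if e.total_sites > MAX_SITES_PER_GROUP:
                raise ModelError(
                    f"enhancer with {e.total_sites} sites exceeds the per-enhancer "
                    f"cap of {MAX_SITES_PER_GROUP} (2**k occupancy species)")

    used_tfs = sorted({tf for e in cfg.enhancers for tf in e.site_tf_types})
    species: list[Species] = []
    for tf in used_tfs:
        species.append(Species(name=f"T{tf + 1}", role="free_tf", tf_type=tf))
    species.append(Species(name="R", role="mrna"))

    reactions: list[Reaction] = []
    groups: list[list[str]] = []
    initial: dict[str, int] = {}

    def add_binding_unbinding(name: str, other_name, occ: tuple[int, ...],
                              site_tfs: tuple[int, ...], enh_idx: int | None) -> None:
        """Register bind/unbind reactions from state `occ` (names via other_name)."""
        for j, (bit, tf) in enumerate(zip(occ, site_tfs)):
            tf_name = f"T{tf + 1}"
            if bit == 0:
                target = other_name(occ, j, 1)
                reactions.append(Reaction(
                    name=f"bind:{name}+{tf_name}->{target}",
                    reactants=((name, 1), (tf_name, 1)), products=((target, 1),),
                    rate=eff.kon[tf], order="second",
                    propensity_species=(name, tf_name)))
            else:
                target = other_name(occ, j, 0)
                reactions.append(Reaction(
                    name=f"unbind:{name}->{target}+{tf_name}",
                    reactants=((name, 1),), products=((target, 1), (tf_name, 1)),
                    rate=eff.koff[tf], order="first", propensity_species=(name,)))

    if not joint:
        for i, enh in enumerate(cfg.enhancers):
            site_tfs = enh.site_tf_types
            states = _occupancy_states(enh.total_sites)
            group = []
            for occ in states:
                nm = _state_name(i, occ)
                species.append(Species(name=nm, role="enhancer_state",
                                       enhancer_index=i, occupancy=occ))
                group.append(nm)
            groups.append(group)
            initial[_state_name(i, tuple([0] * enh.total_sites))] = 1

            def flip(occ, j, v, _i=i):
                lst = list(occ)
                lst[j] = v
                return _state_name(_i, tuple(lst))

            for occ in states:
                nm = _state_name(i, occ)
                add_binding_unbinding(nm, flip, occ, site_tfs, i)
                rate = transcription_rate([occ], cfg.enhancers[i:i + 1],
                                          eff, "additive")
                if rate > 0:
                    reactions.append(Reaction(
                        name=f"transcribe:{nm}", reactants=((nm, 1),),
                        products=((nm, 1), ("R", 1)), rate=rate,
                        order="first", propensity_species=(nm,)))
    else:
        # Joint occupancy: one conserved group over the product space.
        site_tfs = tuple(tf for e in cfg.enhancers for tf in e.site_tf_types)
        sizes = [e.total_sites for e in cfg.enhancers]
        offsets = [sum(sizes[:i]) for i in range(len(sizes))]

        def joint_name(occ: tuple[int, ...]) -> str:
            parts = [''.join(map(str, occ[offsets[i]:offsets[i] + sizes[i]]))
                     for i in range(len(sizes))]
            return "S" + ".".join(parts)

        def split_occ(occ: tuple[int, ...]) -> list[tuple[int, ...]]:
            return [tuple(occ[offsets[i]:offsets[i] + sizes[i]])
                    for i in range(len(sizes))]

        states = _occupancy_states(sum(sizes))
        group = []
        for occ in states:
            nm = joint_name(occ)
            species.append(Species(name=nm, role="enhancer_state", occupancy=occ))
            group.append(nm)
        groups.append(group)
        initial[joint_name(tuple([0] * sum(sizes)))] = 1

        def flip(occ, j, v):
            lst = list(occ)
            lst[j] = v
            return joint_name(tuple(lst))

        for occ in states:
            nm = joint_name(occ)
            add_binding_unbinding(nm, flip, occ, site_tfs, None)
            rate = transcription_rate(split_occ(occ), cfg.enhancers, eff,
                                      cfg.regime, cfg.saturation_rate)
            if rate > 0:
                reactions.append(Reaction(
                    name=f"transcribe:{nm}", reactants=((nm, 1),),
                    products=((nm, 1), ("R", 1)), rate=rate,
                    order="first", propensity_species=(nm,)))

    for tf in used_tfs:
        tf_name = f"T{tf + 1}"
        reactions.append(Reaction(
            name=f"burst:{tf_name}", reactants=(),
            products=((tf_name, int(eff.burst_size[tf])),),
            rate=eff.burst_rate[tf], order="constant", propensity_species=()))
        reactions.append(Reaction(
            name=f"degrade:{tf_name}", reactants=((tf_name, 1),), products=(),
            rate=eff.tf_degradation[tf], order="first",
            propensity_species=(tf_name,)))
    reactions.append(Reaction(
        name="degrade:R", reactants=(("R", 1),), products=(),
        rate=eff.mrna_degradation, order="first", propensity_species=("R",)))

    return ReactionNetwork(species=species, reactions=reactions,
                           conservation_groups=groups, initial_state=initial)


def enumerate_configurations(
    max_enhancers: int,
    max_total_sites: int,
    n_tf_types: int = 2,
    params: RateParameters | None = None,
    regime: str = "additive",
) -> list[SystemConfig]:
    """All systems with at most ``max_enhancers`` enhancers and
    ``max_total_sites`` binding sites in total, deduplicated as unordered
    multisets of per-enhancer site-count vectors and returned in a
    deterministic canonical order.
    """
    if max_enhancers < 1 or max_total_sites < 1 or n_tf_types < 1:
        raise ModelError("enumeration bounds must be >= 1")
    params = params if params is not None else _params_with_n_tf(n_tf_types)
    vectors = [v for v in itertools.product(range(max_total_sites + 1),
                                            repeat=n_tf_types)
               if 0 < sum(v) <= max_total_sites]
    vectors.sort()
    configs: list[SystemConfig] = []
    for n_enh in range(1, max_enhancers + 1):
        for combo in itertools.combinations_with_replacement(vectors, n_enh):
            if sum(sum(v) for v in combo) <= max_total_sites:
                configs.append(SystemConfig(
                    enhancers=tuple(EnhancerSpec(v) for v in combo),
                    params=params, regime=regime))
    configs.sort(key=lambda c: (sum(c.total_site_counts), c.n_enhancers,
                                tuple(e.site_counts for e in c.canonical().enhancers)))
    return configs


def _params_with_n_tf(n_tf: int) -> RateParameters:
    base = RateParameters()
    if n_tf == base.n_tf_types:
        return base
    if n_tf == 1:
        return RateParameters(
            kon=base.kon[:1], koff=base.koff[:1], burst_rate=base.burst_rate[:1],
            burst_size=base.burst_size[:1], tf_degradation=base.tf_degradation[:1],
            transcription_rate=base.transcription_rate[:1])

    def ext(t):
        return t + (t[-1],) * (n_tf - len(t))

    return RateParameters(
        kon=ext(base.kon), koff=ext(base.koff), burst_rate=ext(base.burst_rate),
        burst_size=ext(base.burst_size), tf_degradation=ext(base.tf_degradation),
        transcription_rate=ext(base.transcription_rate))


def duplicate_system(config: SystemConfig, copies: int) -> SystemConfig:
    """Exact duplication of a single-enhancer archetype: ``copies`` identical
    enhancers; total sites scale with ``copies``; modulation is re-evaluated at
    the new enhancer count when the network is built."""
    if copies < 1:
        raise ModelError("copies must be >= 1")
    archetypes = set(e.site_counts for e in config.enhancers)
    if len(archetypes) != 1:
        raise ModelError("duplication requires a single enhancer archetype")
    return replace(config, enhancers=config.enhancers * copies)


def split_system(
    total_sites_per_tf: Sequence[int],
    n_enhancers: int,
    params: RateParameters | None = None,
    regime: str = "additive",
    **kwargs,
) -> SystemConfig:
    """Distribute fixed per-TF site totals over ``n_enhancers`` as evenly as
    possible (sites dealt round-robin, TF types in order), preserving total
    counts exactly; every enhancer receives at least one site."""
    tau = [int(t) for t in total_sites_per_tf]
    if n_enhancers < 1:
        raise ModelError("n_enhancers must be >= 1")
    if any(t < 0 for t in tau) or sum(tau) < n_enhancers:
        raise ModelError(
            f"cannot split {sum(tau)} sites over {n_enhancers} enhancers")
    params = params if params is not None else _params_with_n_tf(len(tau))
    counts = [[0] * len(tau) for _ in range(n_enhancers)]
    i = 0
    for tf, t in enumerate(tau):
        for _ in range(t):
            counts[i % n_enhancers][tf] += 1
            i += 1
    cfg = SystemConfig(enhancers=tuple(EnhancerSpec(tuple(c)) for c in counts),
                       params=params, regime=regime, **kwargs)
    return cfg.canonical()


def canonical_site_multiset(config: SystemConfig):
    """Multiset of independent site descriptors — the factored canonical form
    of an additive-family system.

    In the additive regimes each binding site evolves independently given the
    TF pools, and transcription is a sum of per-site indicators, so two
    configurations are stochastically equivalent iff these multisets (plus the
    shared TF/mRNA kinetics) coincide, regardless of how sites are grouped
    into enhancers."""
    if config.regime in ("saturation", "synergy"):
        raise ModelError("factored canonical form exists only for additive-family regimes")
    d1, d2 = config.effective_d()
    eff = apply_rate_modulation(config.params, config.regime, config.n_enhancers, d1, d2)
    sites = []
    for e in config.enhancers:
        for tf in e.site_tf_types:
            sites.append((tf, eff.kon[tf], eff.koff[tf], eff.transcription_rate[tf]))
    return tuple(sorted(sites))


# ---------------------------------------------------------------------------
# Config file I/O
# ---------------------------------------------------------------------------

_PARAM_KEYS = {
    "beta1": ("burst_rate", 0), "gamma1": ("burst_rate", 1),
    "beta_m1": ("tf_degradation", 0), "gamma_m1": ("tf_degradation", 1),
    "kon1": ("kon", 0), "kon2": ("kon", 1),
    "koff1": ("koff", 0), "koff2": ("koff", 1),
    "r1": ("transcription_rate", 0), "r2": ("transcription_rate", 1),
    "n1": ("burst_size", 0), "n2": ("burst_size", 1),
    "alpha": ("mrna_degradation", None),
}


def params_from_dict(d: dict) -> RateParameters:
    base = RateParameters()
    fields = {name: list(getattr(base, name))
              for name in ("kon", "koff", "burst_rate", "burst_size",
                           "tf_degradation", "transcription_rate")}
    alpha = base.mrna_degradation
    for key, value in d.items():
        if key not in _PARAM_KEYS:
            raise ModelError(f"unknown parameter name {key!r}")
        fname, idx = _PARAM_KEYS[key]
        if idx is None:
            alpha = float(value)
        else:
            fields[fname][idx] = value
    fields["burst_size"] = [int(v) for v in fields["burst_size"]]
    return RateParameters(
        kon=tuple(fields["kon"]), koff=tuple(fields["koff"]),
        burst_rate=tuple(fields["burst_rate"]),
        burst_size=tuple(fields["burst_size"]),
        tf_degradation=tuple(fields["tf_degradation"]),
        transcription_rate=tuple(fields["transcription_rate"]),
        mrna_degradation=alpha)


def params_to_dict(p: RateParameters) -> dict:
    if p.n_tf_types != 2:
        raise ModelError("named-parameter serialization is defined for two TF types")
    return {
        "beta1": p.burst_rate[0], "beta_m1": p.tf_degradation[0],
        "gamma1": p.burst_rate[1], "gamma_m1": p.tf_degradation[1],
        "kon1": p.kon[0], "koff1": p.koff[0],
        "kon2": p.kon[1], "koff2": p.koff[1],
        "alpha": p.mrna_degradation,
        "r1": p.transcription_rate[0], "r2": p.transcription_rate[1],
        "n1": p.burst_size[0], "n2": p.burst_size[1],
    }


def config_to_dict(config: SystemConfig) -> dict:
    out = {
        "enhancers": [list(e.site_counts) for e in config.enhancers],
        "params": params_to_dict(config.params),
        "regime": config.regime,
    }
    if config.d1 is not None:
        out["d1"] = list(config.d1)
    if config.d2 is not None:
        out["d2"] = list(config.d2)
    if config.saturation_rate is not None:
        out["saturation_rate"] = config.saturation_rate
    return out


def config_from_dict(d: dict) -> SystemConfig:
    params = params_from_dict(d.get("params", {}))
    return SystemConfig(
        enhancers=tuple(EnhancerSpec(tuple(e)) for e in d["enhancers"]),
        params=params, regime=d.get("regime", "additive"),
        d1=tuple(d["d1"]) if "d1" in d else None,
        d2=tuple(d["d2"]) if "d2" in d else None,
        saturation_rate=d.get("saturation_rate"))


def load_config(path: str | Path) -> SystemConfig:
    """Read a system configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(data)


def save_config(config: SystemConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
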