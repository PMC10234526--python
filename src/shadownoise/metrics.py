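"""Transcriptional output statistics computed from stationary moments.

Noise is the coefficient of variation of mRNA, CV = sigma_R / E[R]. Fidelity is
the stationary Pearson correlation Corr(T_m, R) between a TF's *free* copy
number and mRNA (free rather than free+bound TF; see docs/methods.md). The
Fano factor is variance over mean.
"""

from __future__ import annotations

import math

from .moments import MomentState


class MetricError(ValueError):
    """Metric undefined for this state (zero mean/variance or pathological)."""


def _check(state: MomentState) -> None:
    if state.pathological:
        raise MetricError("state has negative closure variances; refusing metrics")


def coefficient_of_variation(state: MomentState, species: str = "R") -> float:
    """sigma / mean of the given species (default mRNA)."""
    _check(state)
    mean = state.mean_of(species)
    var = state.var_of(species)
    if mean <= 0:
        raise MetricError(f"CV undefined: E[{species}] = {mean}")
    if var < 0:
        raise MetricError(f"CV undefined: var[{species}] = {var} < 0")
    return math.sqrt(var) / mean


def fidelity(state: MomentState, tf: str = "T1", species: str = "R") -> float:
    """Pearson correlation between free TF and mRNA copy number, in [-1, 1]."""
    _check(state)
    v_tf, v_r = state.var_of(tf), state.var_of(species)
    if v_tf <= 0 or v_r <= 0:
        raise MetricError(f"fidelity undefined: var[{tf}]={v_tf}, var[{species}]={v_r}")
    rho = state.cov_of(tf, species) / math.sqrt(v_tf * v_r)
    return max(-1.0, min(1.0, rho))


def fano_factor(state: MomentState, species: str = "R") -> float:
    """Variance over mean of the given species."""
    _check(state)
    mean = state.mean_of(species)
    if mean <= 0:
        raise MetricError(f"Fano factor undefined: E[{species}] = {mean}")
    return state.var_of(species) / mean


def metrics_row(state: MomentState, species: str = "R") -> dict:
    """Standard result columns (for the given output species, default mRNA);
    metrics that are undefined come back as NaN."""
    row: dict = {}
    nan = float("nan")
    try:
        row[f"mean_{species}"] = state.mean_of(species)
        row[f"var_{species}"] = state.var_of(species)
    except KeyError:
        row[f"mean_{species}"] = row[f"var_{species}"] = nan
    for col, fn, args in (("cv", coefficient_of_variation, ()),
                          ("fidelity_T1", fidelity, ("T1", species)),
                          ("fidelity_T2", fidelity, ("T2", species)),
                          ("fano", fano_factor, ())):
        try:
            row[col] = fn(state, *args, **({"species": species}
                                           if not args else {}))
        except (MetricError, KeyError):
            row[col] = nan
    return row
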