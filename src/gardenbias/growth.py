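"""Crowding index and full/base growth predictions.

The growth of plant *i* in group *s* over one census interval is modeled
two ways:

* full model:  mu_F = alpha_s + beta_s * Size_i + gamma_s * phi_i + eps
* base model:  mu_B = alpha_s + beta_s * Size_i + eps

where phi_i is the neighborhood crowding index — a cumulative measure of
neighbor crown size weighted by a Gaussian-in-distance kernel:

    phi_i = sum_{j != i} c[s_j] * Size_j * exp(b * D_ij^2)

with c >= 0 a per-group kernel scale and b < 0 a shared decay rate
(per m^2). gamma_s is the group's crowding response: more negative means
less tolerant of neighbors. eps is N(0, sigma^2) residual noise, or zero
in deterministic mode.

The kernel scale is indexed by the *neighbor's* group by default (a
neighbor's competitive effect scales its own size); pass
``c_by_target=True`` to index by the target instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "PlantStateVector",
    "crowding_index",
    "predict_growth_full",
    "predict_growth_base",
    "kernel_weight",
    "read_params_json",
    "write_params_json",
]


@dataclass(frozen=True)
class GrowthParams:
    """One parameter set of the growth model.

    alpha, beta, gamma, c are arrays with one entry per group; b and
    sigma are shared scalars. Units: alpha in crown-volume units per
    census; beta per census; gamma in growth per unit crowding index;
    c dimensionless (>= 0); b per m^2 (< 0); sigma in growth units (>= 0).
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    c: np.ndarray
    b: float
    sigma: float

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("alpha", "beta", "gamma", "c"):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, a)
            arrays[name] = a
        lens = {a.shape for a in arrays.values()}
        if len(lens) != 1:
            raise ValueError("alpha, beta, gamma, c must have equal length")
        if any(not np.all(np.isfinite(a)) for a in arrays.values()):
            raise ValueError("parameters must be finite")
        if np.any(arrays["c"] < 0):
            raise ValueError("kernel scale c must be >= 0")
        if not self.b < 0:
            raise ValueError(f"kernel decay b must be negative, got {self.b}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def n_groups(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class PlantStateVector:
    """Per-plant state entering the growth equations."""

    size: np.ndarray   # initial crown volume, m^3, > 0
    group: np.ndarray  # group index per plant
    phi: np.ndarray    # crowding index, >= 0

    def __post_init__(self) -> None:
        for name in ("size", "group", "phi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.size) == len(self.group) == len(self.phi)):
            raise ValueError("size, group, phi must have equal length")
        if np.any(self.size <= 0):
            raise ValueError("sizes must be strictly positive")


def kernel_weight(d: np.ndarray | float, b: float) -> np.ndarray | float:
    """Distance-decay weight exp(b * d^2) of the competition kernel."""
    return np.exp(b * np.square(d))


def crowding_index(
    sizes: np.ndarray,
    groups: np.ndarray,
    dist: np.ndarray,
    params: GrowthParams,
    c_by_target: bool = False,
    cutoff: float | None = None,
) -> np.ndarray:
    """Neighborhood crowding index phi for every plant.

    phi_i = sum_{j != i} c[group_j] * size_j * exp(b * D_ij^2); the sum
    runs over all other (live) plants — no truncation radius unless
    ``cutoff`` (meters) is given, in which case more distant neighbors
    are dropped (a speed knob; with calibrated b the kernel is near zero
    beyond a few meters anyway).
    """
    sizes = np.asarray(sizes, dtype=float)
    groups = np.asarray(groups, dtype=int)
    dist = np.asarray(dist, dtype=float)
    n = len(sizes)
    if dist.shape != (n, n) or len(groups) != n:
        raise ValueError(
            f"shape mismatch: {n} sizes, {len(groups)} groups, dist {dist.shape}"
        )
    if np.any(groups < 0) or np.any(groups >= params.n_groups):
        raise IndexError("group index outside parameter range")
    w = np.exp(params.b * dist * dist)
    np.fill_diagonal(w, 0.0)
    if cutoff is not None:
        w[dist > cutoff] = 0.0
    if c_by_target:
        return params.c[groups] * (w @ sizes)
    return w @ (params.c[groups] * sizes)


def _check_state(state: PlantStateVector, params: GrowthParams) -> None:
    if np.any(state.group < 0) or np.any(state.group >= params.n_groups):
        raise IndexError("group index outside parameter range")


def predict_growth_full(
    state: PlantStateVector, params: GrowthParams, noise: np.ndarray | None = None
) -> np.ndarray:
    """Full-model predicted growth: alpha + beta*size + gamma*phi + noise."""
    _check_state(state, params)
    g = state.group
    mu = params.alpha[g] + params.beta[g] * state.size + params.gamma[g] * state.phi
    if noise is not None:
        mu = mu + np.asarray(noise, dtype=float)
    return mu


def predict_growth_base(
    state: PlantStateVector, params: GrowthParams, noise: np.ndarray | None = None
) -> np.ndarray:
    """Base-model predicted growth: alpha + beta*size + noise (no crowding)."""
    _check_state(state, params)
    g = state.group
    mu = params.alpha[g] + params.beta[g] * state.size
    if noise is not None:
        mu = mu + np.asarray(noise, dtype=float)
    return mu


def write_params_json(params: GrowthParams, path, group_names=None) -> None:
    doc = {
        "alpha": params.alpha.tolist(),
        "beta": params.beta.tolist(),
        "gamma": params.gamma.tolist(),
        "c": params.c.tolist(),
        "b": params.b,
        "sigma": params.sigma,
    }
    if group_names is not None:
        doc["group_names"] = list(group_names)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_params_json(path) -> GrowthParams:
    with open(path) as fh:
        doc = json.load(fh)
    return GrowthParams(
        alpha=np.asarray(doc["alpha"], float),
        beta=np.asarray(doc["beta"], float),
        gamma=np.asarray(doc["gamma"], float),
        c=np.asarray(doc["c"], float),
        b=float(doc["b"]),
        sigma=float(doc["sigma"]),
    )
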