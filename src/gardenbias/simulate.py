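"""Scenario sweep: distance grid x posterior draws -> growth predictions.

Each scenario rescales the fixed garden to a uniform planting distance,
recomputes the crowding index under one posterior parameter draw, and
evaluates the full and base growth models. The default grid spans 15
planting distances from 0.5 to 4.0 m; with 2000 posterior draws that is
30,000 simulation runs.

Noise modes
-----------
independent
    Full and base each receive their own sigma*z residual vector — the
    two models as written, each a draw from its predictive distribution.
common
    One shared residual vector, so mu_full - mu_base is exactly
    gamma*phi (useful for isolating the spatial term).
none
    sigma treated as 0; fully deterministic (used for the correlation
    analysis, which propagates uncertainty only through the mean).

Seeding: one top-level seed spawns an independent substream per
(distance index, draw index), so results do not depend on loop order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthParams, PlantStateVector, crowding_index, predict_growth_base, predict_growth_full
from .layout import GardenLayout, pairwise_distances, rescale_layout

__all__ = [
    "NOISE_MODES",
    "PosteriorDraws",
    "ScenarioResult",
    "SweepResult",
    "default_distance_grid",
    "run_sweep",
    "write_results_csv",
]

NOISE_MODES = ("independent", "common", "none")


class PosteriorDraws:
    """An ordered collection of growth-parameter sets.

    Stands in for posterior samples: iterating yields one
    :class:`GrowthParams` per draw. Internally stored as stacked arrays
    (``alpha``, ``beta``, ``gamma``, ``c`` of shape (n_draws, n_groups);
    ``b``, ``sigma`` of shape (n_draws,)).
    """

    def __init__(self, alpha, beta, gamma, c, b, sigma):
        self.alpha = np.atleast_2d(np.asarray(alpha, float))
        self.beta = np.atleast_2d(np.asarray(beta, float))
        self.gamma = np.atleast_2d(np.asarray(gamma, float))
        self.c = np.atleast_2d(np.asarray(c, float))
        self.b = np.atleast_1d(np.asarray(b, float))
        self.sigma = np.atleast_1d(np.asarray(sigma, float))
        if not (self.alpha.shape == self.beta.shape == self.gamma.shape == self.c.shape):
            raise ValueError("per-group parameter arrays must share a shape")
        if len(self.b) != self.n_draws or len(self.sigma) != self.n_draws:
            raise ValueError("b and sigma must have one entry per draw")
        if self.n_draws < 1:
            raise ValueError("need at least one draw")
        for k in range(self.n_draws):
            self[k]  # validates each draw via GrowthParams invariants

    @classmethod
    def from_list(cls, draws: Sequence[GrowthParams]) -> "PosteriorDraws":
        if not draws:
            raise ValueError("need at least one parameter set")
        return cls(
            alpha=np.stack([d.alpha for d in draws]),
            beta=np.stack([d.beta for d in draws]),
            gamma=np.stack([d.gamma for d in draws]),
            c=np.stack([d.c for d in draws]),
            b=np.array([d.b for d in draws]),
            sigma=np.array([d.sigma for d in draws]),
        )

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_groups(self) -> int:
        return self.alpha.shape[1]

    def __len__(self) -> int:
        return self.n_draws

    def __getitem__(self, k: int) -> GrowthParams:
        return GrowthParams(
            alpha=self.alpha[k], beta=self.beta[k], gamma=self.gamma[k],
            c=self.c[k], b=float(self.b[k]), sigma=float(self.sigma[k]),
        )

    def __iter__(self) -> Iterator[GrowthParams]:
        for k in range(self.n_draws):
            yield self[k]


@dataclass(frozen=True)
class ScenarioResult:
    """Predictions for one (planting distance, posterior draw) pair."""

    distance: float
    draw_index: int
    mu_full: np.ndarray
    mu_base: np.ndarray
    phi: np.ndarray
    noise_mode: str

    def __post_init__(self) -> None:
        if not (len(self.mu_full) == len(self.mu_base) == len(self.phi)):
            raise ValueError("per-plant vectors must share a length")


class SweepResult:
    """All scenario results of one sweep, stored densely.

    Arrays ``mu_full``, ``mu_base``, ``phi`` have shape
    (n_distances, n_draws, n_plants). Iterating yields one
    :class:`ScenarioResult` per (distance, draw) pair, distances outer.
    """

    def __init__(self, distances, mu_full, mu_base, phi, noise_mode,
                 groups, sizes):
        self.distances = np.asarray(distances, float)
        self.mu_full = mu_full
        self.mu_base = mu_base
        self.phi = phi
        self.noise_mode = noise_mode
        self.groups = np.asarray(groups)
        self.sizes = np.asarray(sizes)

    @property
    def n_distances(self) -> int:
        return len(self.distances)

    @property
    def n_draws(self) -> int:
        return self.mu_full.shape[1]

    @property
    def n_plants(self) -> int:
        return self.mu_full.shape[2]

    def __len__(self) -> int:
        return self.n_distances * self.n_draws

    def __iter__(self) -> Iterator[ScenarioResult]:
        for i in range(self.n_distances):
            for k in range(self.n_draws):
                yield self.result(i, k)

    def result(self, dist_index: int, draw_index: int) -> ScenarioResult:
        return ScenarioResult(
            distance=float(self.distances[dist_index]),
            draw_index=draw_index,
            mu_full=self.mu_full[dist_index, draw_index],
            mu_base=self.mu_base[dist_index, draw_index],
            phi=self.phi[dist_index, draw_index],
            noise_mode=self.noise_mode,
        )

    def at_distance(self, d: float) -> "SweepResult":
        """Sub-sweep restricted to the grid distance closest to ``d``."""
        i = int(np.argmin(np.abs(self.distances - d)))
        sl = slice(i, i + 1)
        return SweepResult(self.distances[sl], self.mu_full[sl],
                           self.mu_base[sl], self.phi[sl], self.noise_mode,
                           self.groups, self.sizes)

    def to_dataframe(self) -> pd.DataFrame:
        nd, nk, npl = self.mu_full.shape
        return pd.DataFrame(
            {
                "distance": np.repeat(self.distances, nk * npl),
                "draw": np.tile(np.repeat(np.arange(nk), npl), nd),
                "plant_id": np.tile(np.arange(npl), nd * nk),
                "mu_full": self.mu_full.ravel(),
                "mu_base": self.mu_base.ravel(),
                "phi": self.phi.ravel(),
            }
        )


def default_distance_grid() -> np.ndarray:
    """15 equally spaced planting distances from 0.5 to 4.0 m (0.25 m step)."""
    return np.linspace(0.5, 4.0, 15)


def run_sweep(
    layout: GardenLayout,
    sizes: np.ndarray,
    draws: PosteriorDraws,
    distances: Sequence[float] | None = None,
    noise_mode: str = "independent",
    seed: int = 0,
    c_by_target: bool = False,
) -> SweepResult:
    """Simulate every (distance, draw) scenario on one fixed garden.

    The layout's topology, occupancy, labels, and initial sizes are held
    fixed across scenarios; only the lattice spacing changes. ``sizes``
    has one entry per *live* plant.
    """
    if distances is None:
        distances = default_distance_grid()
    distances = np.asarray(distances, float)
    if distances.size == 0:
        raise ValueError("distance grid must be nonempty")
    if noise_mode not in NOISE_MODES:
        raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
    if len(draws) == 0:
        raise ValueError("no parameter draws supplied")

    live = layout.live_subset()
    sizes = np.asarray(sizes, float)
    if len(sizes) == layout.n_positions:
        sizes = sizes[layout.alive]  # per-position sizes: keep live only
    elif len(sizes) != live.n_positions:
        raise ValueError(
            f"{len(sizes)} sizes for {live.n_positions} live plants"
        )
    groups = live.group
    n = live.n_positions
    nd, nk = len(distances), len(draws)

    mu_full = np.empty((nd, nk, n))
    mu_base = np.empty((nd, nk, n))
    phi_all = np.empty((nd, nk, n))

    for i, d in enumerate(distances):
        d2 = np.square(pairwise_distances(rescale_layout(layout, float(d))))
        for k, params in enumerate(draws):
            phi = crowding_index_from_d2(sizes, groups, d2, params, c_by_target)
            state = PlantStateVector(size=sizes, group=groups, phi=phi)
            nf, nb = _draw_noise(noise_mode, params.sigma, n, seed, i, k)
            mu_full[i, k] = predict_growth_full(state, params, nf)
            mu_base[i, k] = predict_growth_base(state, params, nb)
            phi_all[i, k] = phi

    return SweepResult(distances, mu_full, mu_base, phi_all, noise_mode,
                       groups, sizes)


def crowding_index_from_d2(sizes, groups, d2, params, c_by_target=False):
    """Crowding index from a precomputed squared-distance matrix."""
    w = np.exp(params.b * d2)
    np.fill_diagonal(w, 0.0)
    if c_by_target:
        return params.c[groups] * (w @ sizes)
    return w @ (params.c[groups] * sizes)


def _draw_noise(noise_mode, sigma, n, seed, dist_index, draw_index):
    """Residual vectors for (full, base) under one scenario substream."""
    if noise_mode == "none":
        return None, None
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(dist_index, draw_index))
    rng = np.random.default_rng(ss)
    z_full = sigma * rng.standard_normal(n)
    if noise_mode == "common":
        return z_full, z_full
    return z_full, sigma * rng.standard_normal(n)


def write_results_csv(result: SweepResult, path) -> None:
    """Long-format CSV: distance, draw, plant_id, mu_full, mu_base, phi."""
    result.to_dataframe().to_csv(path, index=False)
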