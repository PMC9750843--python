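"""Grid garden layouts: generation, rescaling, perturbation, and distances.

A layout is a rectangular lattice of planting positions, filled row-major.
Each position carries an alive flag (mortality gaps are part of real
gardens), a source-population label, and a taxonomic group label.  All
coordinates are continuous meters with the origin at the first position;
there is no boundary wrapping, so edge plants simply have fewer close
neighbors, as in a real garden.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GardenLayout",
    "InvalidLayoutError",
    "default_population_roster",
    "make_grid_layout",
    "rescale_layout",
    "perturb_layout",
    "pairwise_distances",
    "read_layout_csv",
    "write_layout_csv",
]

#: Taxonomic groups: five Artemisia tridentata subspecies-cytotypes plus
#: A. arbuscula, in the order used for group indices 0..5.
DEFAULT_GROUP_NAMES = (
    "tridentata-2x",
    "tridentata-4x",
    "vaseyana-2x",
    "vaseyana-4x",
    "wyomingensis-4x",
    "arbuscula",
)


class InvalidLayoutError(ValueError):
    """Raised when layout construction arguments are inconsistent."""


@dataclass(frozen=True)
class GardenLayout:
    """A grid garden: positions, occupancy, and group structure.

    Attributes
    ----------
    x, y:
        Position coordinates in meters, one entry per planting position.
    alive:
        Boolean flag per position; dead plants contribute neither growth
        nor crowding.
    population:
        Integer source-population label per position (1-based).
    group:
        Integer taxonomic group index per position (0-based into
        ``group_names``).
    dx, dy:
        Lattice spacings along the two axes, meters.
    group_names:
        Names of the taxonomic groups indexed by ``group``.
    """

    x: np.ndarray
    y: np.ndarray
    alive: np.ndarray
    population: np.ndarray
    group: np.ndarray
    dx: float
    dy: float
    group_names: tuple[str, ...] = field(default=DEFAULT_GROUP_NAMES)

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "alive", "population", "group"):
            if len(getattr(self, name)) != n:
                raise InvalidLayoutError(f"field {name!r} length != {n}")
        if self.dx <= 0 or self.dy <= 0:
            raise InvalidLayoutError("lattice spacings must be positive")
        if self.group.size and (self.group.min() < 0 or self.group.max() >= len(self.group_names)):
            raise InvalidLayoutError("group index outside group_names range")
        # each population must map to exactly one group
        pairs = {(int(p), int(g)) for p, g in zip(self.population, self.group)}
        pops = [p for p, _ in pairs]
        if len(pops) != len(set(pops)):
            raise InvalidLayoutError("a population maps to more than one group")

    @property
    def n_positions(self) -> int:
        return len(self.x)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def plant_id(self) -> np.ndarray:
        return np.arange(self.n_positions)

    def live_subset(self) -> "GardenLayout":
        """Layout restricted to live positions (labels preserved)."""
        m = self.alive
        return GardenLayout(
            x=self.x[m], y=self.y[m], alive=self.alive[m],
            population=self.population[m], group=self.group[m],
            dx=self.dx, dy=self.dy, group_names=self.group_names,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant_id": self.plant_id,
                "x": self.x,
                "y": self.y,
                "alive": self.alive.astype(int),
                "population": self.population,
                "group": self.group,
            }
        )


def default_population_roster(
    n_populations: int = 56, group_names: tuple[str, ...] = DEFAULT_GROUP_NAMES
) -> dict[int, int]:
    """Map population labels (1-based) to group indices.

    The default emulates the empirical garden: 55 *A. tridentata* source
    populations spread as evenly as possible across the five
    subspecies-cytotype groups, plus a single *A. arbuscula* population
    assigned to the last group.
    """
    if n_populations < len(group_names):
        raise InvalidLayoutError("need at least one population per group")
    roster: dict[int, int] = {}
    n_main = n_populations - 1
    n_main_groups = len(group_names) - 1
    for p in range(1, n_main + 1):
        roster[p] = (p - 1) % n_main_groups
    roster[n_populations] = len(group_names) - 1
    return roster


def make_grid_layout(
    n_positions: int = 470,
    n_cols: int = 24,
    dx: float = 1.0,
    dy: float = 1.5,
    n_dead: int = 22,
    group_spec: dict[int, int] | None = None,
    seed: int = 0,
    group_names: tuple[str, ...] = DEFAULT_GROUP_NAMES,
) -> GardenLayout:
    """Generate a grid garden with random mortality and population labels.

    Positions fill a lattice row-major over ``n_cols`` columns. Exactly
    ``n_dead`` positions are marked dead, chosen uniformly at random.
    Populations from ``group_spec`` (a population -> group map) are
    allocated to positions as evenly as possible and then randomly
    permuted across the grid.

    Defaults mirror the empirical design: 470 positions at 1 x 1.5 m
    spacing with 22 mortalities, leaving 448 live plants.
    """
    if n_positions < 1 or n_cols < 1:
        raise InvalidLayoutError("n_positions and n_cols must be >= 1")
    if not (0 <= n_dead < n_positions):
        raise InvalidLayoutError(
            f"n_dead must satisfy 0 <= n_dead < n_positions, got {n_dead}"
        )
    if dx <= 0 or dy <= 0:
        raise InvalidLayoutError("spacings must be positive")
    if group_spec is None:
        group_spec = default_population_roster(group_names=group_names)
    if not group_spec:
        raise InvalidLayoutError("empty population roster")

    rng = np.random.default_rng(seed)
    idx = np.arange(n_positions)
    x = (idx % n_cols) * dx
    y = (idx // n_cols) * dy

    alive = np.ones(n_positions, dtype=bool)
    dead_idx = rng.choice(n_positions, size=n_dead, replace=False)
    alive[dead_idx] = False

    pops = np.fromiter(group_spec.keys(), dtype=int)
    reps = int(np.ceil(n_positions / len(pops)))
    population = rng.permutation(np.tile(pops, reps)[:n_positions])
    gmap = np.zeros(int(pops.max()) + 1, dtype=int)
    for p, g in group_spec.items():
        gmap[p] = g
    group = gmap[population]

    return GardenLayout(
        x=x.astype(float), y=y.astype(float), alive=alive,
        population=population, group=group, dx=float(dx), dy=float(dy),
        group_names=group_names,
    )


def rescale_layout(layout: GardenLayout, d: float) -> GardenLayout:
    """Set both lattice spacings to ``d`` (uniform square lattice).

    Topology, occupancy, and labels are unchanged; only inter-plant
    distances move. This is how distance scenarios are generated: the
    same garden composition at a different planting density.
    """
    if d <= 0:
        raise InvalidLayoutError(f"planting distance must be positive, got {d}")
    return replace(
        layout,
        x=layout.x / layout.dx * d,
        y=layout.y / layout.dy * d,
        dx=float(d),
        dy=float(d),
    )


def perturb_layout(
    layout: GardenLayout, seed: int, sizes: np.ndarray | None = None
) -> GardenLayout | tuple[GardenLayout, np.ndarray]:
    """Randomly permute plant identities across fixed positions.

    The lattice positions stay put; the (alive, population, group) tuples
    — and attached per-position sizes, if given — are shuffled jointly.
    This is the spatial-perturbation check: if a pre-existing spatial
    pattern mattered, a permuted garden would give different downstream
    statistics.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(layout.n_positions)
    out = replace(
        layout,
        alive=layout.alive[perm],
        population=layout.population[perm],
        group=layout.group[perm],
    )
    if sizes is None:
        return out
    return out, np.asarray(sizes)[perm]


def pairwise_distances(layout: GardenLayout, live_only: bool = True) -> np.ndarray:
    """Symmetric Euclidean distance matrix among plants, meters.

    By default only live plants enter (dead positions exert no crowding).
    """
    lay = layout.live_subset() if live_only else layout
    pts = np.column_stack([lay.x, lay.y])
    if len(pts) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


def write_layout_csv(layout: GardenLayout, path) -> None:
    layout.to_dataframe().to_csv(path, index=False)


def read_layout_csv(path, dx: float | None = None, dy: float | None = None,
                    group_names: tuple[str, ...] = DEFAULT_GROUP_NAMES) -> GardenLayout:
    """Read a layout CSV (columns plant_id, x, y, alive, population, group).

    Spacings are inferred from unique coordinate gaps unless given.
    """
    df = pd.read_csv(path)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)

    def _infer(v: np.ndarray) -> float:
        u = np.unique(v)
        return float(np.diff(u).min()) if len(u) > 1 else 1.0

    return GardenLayout(
        x=x, y=y,
        alive=df["alive"].to_numpy().astype(bool),
        population=df["population"].to_numpy(int),
        group=df["group"].to_numpy(int),
        dx=dx if dx is not None else _infer(x),
        dy=dy if dy is not None else _infer(y),
        group_names=group_names,
    )
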