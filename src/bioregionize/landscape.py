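"""Synthetic lattice landscapes with riverine barriers, environmental gradients,
and spreading-dye species ranges.

The generator emulates the statistical structure that gridded bioregionalization
analyses assume: a rectangular lattice of equal-area cells partitioned into
blocks by river polylines, smooth climate/topography gradients with seeded
noise, and contiguous species ranges grown by a spreading-dye process with a
river-crossing penalty and (optional) climatic niche filtering.  Every landscape
carries its ground truth (the planted region of each cell), so downstream
clustering and driver-attribution methods can be validated against a known
answer.

Rivers are polylines over lattice *corner* coordinates: a lattice of ``n_rows ×
n_cols`` cells has corners ``(r, c)`` with ``0 ≤ r ≤ n_rows`` and ``0 ≤ c ≤
n_cols``.  Each unit segment of a polyline lies on the grid line separating two
4-adjacent cells; those adjacencies are severed, and blocks are the connected
components of what remains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

Corner = tuple[int, int]
Polyline = Sequence[Corner]

#: vegetation types used by the default environment (moist forest dominant,
#: mirroring the strong vegetation homogeneity of large tropical lowland biomes)
DEFAULT_VEG_TYPES = ("moist_forest", "dry_forest", "varzea", "savanna", "montane")


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Lattice:
    """A rectangular grid of cells cut into blocks by river polylines.

    ``block_label`` is the connected-component id of each cell in the
    4-adjacency graph with river-crossed edges removed; labels are canonical
    (numbered by first occurrence in row-major order).  ``river_bank_category``
    is the categorical riverine-barrier predictor, by default one category per
    block.
    """

    n_rows: int
    n_cols: int
    cell_ids: tuple[str, ...]
    coords: np.ndarray            # (n_cells, 2) int (row, col), row-major order
    block_label: np.ndarray       # (n_cells,) int
    river_bank_category: np.ndarray  # (n_cells,) str
    crossed_edges: frozenset = field(repr=False, default=frozenset())

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_blocks(self) -> int:
        return int(self.block_label.max()) + 1

    def cell_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def neighbors(self, idx: int) -> list[int]:
        """4-neighbors of a cell (river crossings included)."""
        r, c = divmod(idx, self.n_cols)
        out = []
        if r > 0:
            out.append(idx - self.n_cols)
        if r < self.n_rows - 1:
            out.append(idx + self.n_cols)
        if c > 0:
            out.append(idx - 1)
        if c < self.n_cols - 1:
            out.append(idx + 1)
        return out

    def edge_crosses_river(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.crossed_edges

    def to_frame(self) -> pd.DataFrame:
        """Cell table: cell_id, row, col, block_label, river_bank_category."""
        return pd.DataFrame(
            {
                "cell_id": list(self.cell_ids),
                "row": self.coords[:, 0],
                "col": self.coords[:, 1],
                "block_label": self.block_label,
                "river_bank_category": self.river_bank_category,
            }
        )


def full_horizontal_river(row_boundary: int, n_cols: int) -> list[Corner]:
    """Polyline spanning the lattice along corner-row ``row_boundary``."""
    return [(row_boundary, c) for c in range(n_cols + 1)]


def full_vertical_river(col_boundary: int, n_rows: int) -> list[Corner]:
    """Polyline spanning the lattice along corner-col ``col_boundary``."""
    return [(r, col_boundary) for r in range(n_rows + 1)]


def _segment_cut(a: Corner, b: Corner, n_rows: int, n_cols: int) -> tuple[int, int] | None:
    """Cell-index pair severed by the unit corner segment a—b (None on boundary)."""
    (r1, c1), (r2, c2) = a, b
    if r1 == r2:  # horizontal segment: separates cell above from cell below
        r = r1
        c = min(c1, c2)
        if r == 0 or r == n_rows:
            return None
        return (r - 1) * n_cols + c, r * n_cols + c
    else:         # vertical segment: separates cell left from cell right
        c = c1
        r = min(r1, r2)
        if c == 0 or c == n_cols:
            return None
        return r * n_cols + (c - 1), r * n_cols + c


def _validate_polyline(line: Polyline, n_rows: int, n_cols: int) -> None:
    if len(line) < 2:
        raise ValueError("river polyline needs at least two corner points")
    for r, c in line:
        if not (0 <= r <= n_rows and 0 <= c <= n_cols):
            raise ValueError(
                f"river corner ({r}, {c}) lies off the corner grid "
                f"[0..{n_rows}] x [0..{n_cols}]"
            )
    for (r1, c1), (r2, c2) in zip(line, line[1:]):
        if abs(r1 - r2) + abs(c1 - c2) != 1:
            raise ValueError(
                f"river corners ({r1},{c1}) and ({r2},{c2}) are not adjacent "
                "on the edge grid"
            )
    for r, c in (line[0], line[-1]):
        if r not in (0, n_rows) and c not in (0, n_cols):
            raise ValueError(
                f"river endpoint ({r}, {c}) must terminate on the lattice boundary"
            )


def make_lattice(
    n_rows: int,
    n_cols: int,
    rivers: Sequence[Polyline] = (),
    bank_categories: Sequence[str] | None = None,
) -> Lattice:
    """Build a lattice and derive blocks as river-delimited connected components.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (cells), both >= 1.
    rivers
        Polylines over lattice corner coordinates; each must consist of unit
        steps along grid lines and terminate on the lattice boundary (so every
        river cleanly spans or exits the grid).
    bank_categories
        Optional per-cell override of the riverine-barrier category; defaults
        to one category per block (``bank<label>``).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    n = n_rows * n_cols
    for line in rivers:
        _validate_polyline(line, n_rows, n_cols)

    crossed: set[tuple[int, int]] = set()
    for line in rivers:
        for a, b in zip(line, line[1:]):
            cut = _segment_cut(a, b, n_rows, n_cols)
            if cut is not None:
                crossed.add((min(cut), max(cut)))

    rows_i, cols_j = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            if c + 1 < n_cols and (i, i + 1) not in crossed:
                rows_i.append(i)
                cols_j.append(i + 1)
            if r + 1 < n_rows and (i, i + n_cols) not in crossed:
                rows_i.append(i)
                cols_j.append(i + n_cols)
    adj = coo_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_j)), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)

    # canonicalize block labels by first occurrence in row-major order
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(comp):
        if c not in remap:
            remap[c] = len(remap)
        labels[i] = remap[c]

    coords = np.array([(r, c) for r in range(n_rows) for c in range(n_cols)])
    cell_ids = tuple(f"c{r}_{c}" for r in range(n_rows) for c in range(n_cols))
    if bank_categories is not None:
        if len(bank_categories) != n:
            raise ValueError("bank_categories must have one entry per cell")
        banks = np.asarray(bank_categories, dtype=object)
    else:
        banks = np.array([f"bank{l}" for l in labels], dtype=object)
    return Lattice(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_ids=cell_ids,
        coords=coords,
        block_label=labels,
        river_bank_category=banks,
        crossed_edges=frozenset(crossed),
    )


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientSpec:
    """A deterministic spatial gradient plus iid Gaussian noise.

    orientation: 'row' (varies down rows), 'col' (across columns) or 'radial'
    (distance from the lattice center, scaled to [0, 1]).
    low/high: field value at the gradient's start/end.
    noise_sd: standard deviation of the additive noise (>= 0).
    """

    orientation: str = "col"
    low: float = 0.0
    high: float = 1.0
    noise_sd: float = 0.0

    def evaluate(self, coords: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
        r = coords[:, 0].astype(float)
        c = coords[:, 1].astype(float)
        if self.orientation == "row":
            t = r / max(n_rows - 1, 1)
        elif self.orientation == "col":
            t = c / max(n_cols - 1, 1)
        elif self.orientation == "radial":
            rc, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
            dist = np.hypot(r - rc, c - cc)
            t = dist / max(dist.max(), 1e-12)
        else:
            raise ValueError(f"unknown gradient orientation {self.orientation!r}")
        return self.low + (self.high - self.low) * t


def default_gradients() -> dict[str, GradientSpec]:
    """Climate and topography gradients emulating a tropical lowland biome.

    Temperatures in deg C, precipitation in mm/yr, elevations in m.  Southeast
    (high row, high col) is warmer, drier and more seasonal; the northwest
    holds the highest relief — the broad gradient structure the regionalization
    predictors are meant to capture.
    """
    return {
        "AMAXTE": GradientSpec("row", 30.0, 34.0, 0.3),
        "AMINTE": GradientSpec("row", 18.0, 22.0, 0.3),
        "AMEANTE": GradientSpec("row", 24.0, 28.0, 0.3),
        "TESE": GradientSpec("col", 0.5, 2.5, 0.1),
        "APRE": GradientSpec("col", 3000.0, 1400.0, 60.0),
        "PRER": GradientSpec("col", 150.0, 320.0, 15.0),
        "PRSE": GradientSpec("col", 20.0, 80.0, 4.0),
        "TOPOMIN": GradientSpec("radial", 350.0, 40.0, 15.0),
        "TOPOSTD": GradientSpec("radial", 120.0, 15.0, 8.0),
        "SLOPERAN": GradientSpec("radial", 25.0, 4.0, 2.0),
        "SLOPESTD": GradientSpec("radial", 8.0, 1.0, 0.8),
        "ASPECTSTD": GradientSpec("radial", 100.0, 40.0, 6.0),
    }


#: columns belonging to each predictor family in the default environment
CLIMATE_VARS = ("AMAXTE", "AMINTE", "TESE", "APRE", "PRER", "PRSE")
TOPO_VARS = ("TOPOMAX", "TOPOMIN", "TOPOSTD", "SLOPERAN", "SLOPESTD", "ASPECTSTD")


@dataclass(frozen=True)
class EnvironmentFields:
    """Per-cell environmental predictor fields.

    ``table`` is indexed by cell_id.  The column-name tuples identify the
    variable families consumed downstream (group PCAs and the LGM historical
    differences).  Invariants: vegetation percentages are non-negative and sum
    to 100 per cell; TOPOMAX >= TOPOMIN everywhere.
    """

    table: pd.DataFrame
    climate_vars: tuple[str, ...] = CLIMATE_VARS
    topo_vars: tuple[str, ...] = TOPO_VARS
    veg_vars: tuple[str, ...] = tuple(f"veg_{v}" for v in DEFAULT_VEG_TYPES)
    lgm_temp_cols: tuple[str, ...] = ()
    lgm_prec_cols: tuple[str, ...] = ()
    current_temp_col: str = "AMEANTE"
    current_prec_col: str = "APRE"

    def __post_init__(self) -> None:
        t = self.table
        veg = t[list(self.veg_vars)].to_numpy()
        if (veg < -1e-9).any():
            raise ValueError("vegetation percentages must be non-negative")
        if not np.allclose(veg.sum(axis=1), 100.0, atol=1e-6):
            raise ValueError("vegetation percentages must sum to 100 per cell")
        if "TOPOMAX" in t and "TOPOMIN" in t:
            if (t["TOPOMAX"].to_numpy() < t["TOPOMIN"].to_numpy() - 1e-9).any():
                raise ValueError("TOPOMAX must be >= TOPOMIN in every cell")


def sample_environment(
    lattice: Lattice,
    gradients: dict[str, GradientSpec] | None = None,
    n_lgm_models: int = 3,
    seed: int = 0,
    lgm_temp_offset: float = 4.0,
    lgm_prec_offset: float = 500.0,
    lgm_noise_sd: float = 20.0,
    veg_types: Sequence[str] = DEFAULT_VEG_TYPES,
    veg_noise_sd: float = 0.4,
) -> EnvironmentFields:
    """Sample reproducible environmental fields over a lattice.

    Each scalar field is its gradient evaluated on (row, col) plus seeded
    Gaussian noise.  TOPOMAX is TOPOMIN plus a non-negative relief term so the
    max >= min invariant holds by construction.  LGM (Last Glacial Maximum)
    fields are the current annual mean temperature / annual precipitation
    shifted cooler/drier by the given offsets, one independently perturbed
    field per circulation model.  Vegetation percentages come from a softmax of
    noisy type propensities (moist forest dominant), normalized to 100.
    """
    if n_lgm_models < 1:
        raise ValueError("n_lgm_models must be >= 1")
    gradients = dict(default_gradients() if gradients is None else gradients)
    for name, g in gradients.items():
        if g.noise_sd < 0:
            raise ValueError(f"negative noise_sd for field {name}")

    rng = np.random.default_rng(seed)
    n = lattice.n_cells
    cols: dict[str, np.ndarray] = {}
    for name in sorted(gradients):  # sorted: field order never affects draws
        g = gradients[name]
        base = g.evaluate(lattice.coords, lattice.n_rows, lattice.n_cols)
        noise = rng.normal(0.0, g.noise_sd, size=n) if g.noise_sd > 0 else 0.0
        cols[name] = base + noise
    if "TOPOMIN" in cols and "TOPOMAX" not in cols:
        relief = np.abs(rng.normal(0.0, 1.0, size=n)) * np.maximum(
            cols.get("TOPOSTD", np.full(n, 50.0)), 0.0
        )
        cols["TOPOMAX"] = cols["TOPOMIN"] + relief

    temp = cols.get("AMEANTE")
    prec = cols.get("APRE")
    lgm_temp, lgm_prec = [], []
    for m in range(1, n_lgm_models + 1):
        if temp is not None:
            cols[f"LGM_TEMP_M{m}"] = temp - lgm_temp_offset + rng.normal(
                0.0, lgm_noise_sd * 0.05, size=n
            )
            lgm_temp.append(f"LGM_TEMP_M{m}")
        if prec is not None:
            cols[f"LGM_PREC_M{m}"] = prec - lgm_prec_offset + rng.normal(
                0.0, lgm_noise_sd, size=n
            )
            lgm_prec.append(f"LGM_PREC_M{m}")

    # vegetation: dominant moist forest, montane propensity follows relief
    propensity = {v: rng.normal(0.0, veg_noise_sd, size=n) for v in veg_types}
    if "moist_forest" in propensity:
        propensity["moist_forest"] += 2.0
    if "montane" in propensity and "TOPOMIN" in cols:
        topomin = cols["TOPOMIN"]
        rng_span = np.ptp(topomin) or 1.0
        propensity["montane"] += 2.0 * (topomin - topomin.min()) / rng_span - 1.0
    expo = np.column_stack([np.exp(propensity[v]) for v in veg_types])
    veg_pct = 100.0 * expo / expo.sum(axis=1, keepdims=True)
    for j, v in enumerate(veg_types):
        cols[f"veg_{v}"] = veg_pct[:, j]

    table = pd.DataFrame(cols, index=pd.Index(lattice.cell_ids, name="cell_id"))
    return EnvironmentFields(
        table=table,
        climate_vars=tuple(v for v in CLIMATE_VARS if v in table),
        topo_vars=tuple(v for v in TOPO_VARS if v in table),
        veg_vars=tuple(f"veg_{v}" for v in veg_types),
        lgm_temp_cols=tuple(lgm_temp),
        lgm_prec_cols=tuple(lgm_prec),
    )


# ---------------------------------------------------------------------------
# Species simulation (spreading dye)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of a simulated landscape (the test oracle).

    true_region: per-cell category (the river-delimited block of each cell).
    species_origin_block: block containing each species' seed cell.
    crossing_probability: per-step probability that a range expansion across a
    river is accepted.
    niche_breadth: half-width of the climatic niche on the niche field (may be
    infinite).
    """

    true_region: np.ndarray
    species_origin_block: np.ndarray
    crossing_probability: float
    niche_breadth: float


def _draw_range_size(spec, rng: np.random.Generator, n_cells: int) -> int:
    """Draw a target range size; spec is ('fixed', k) | ('uniform', lo, hi) |
    ('lognormal', mean_cells, sigma)."""
    kind = spec[0]
    if kind == "fixed":
        size = int(spec[1])
    elif kind == "uniform":
        lo, hi = int(spec[1]), int(spec[2])
        size = int(rng.integers(lo, hi + 1))
    elif kind == "lognormal":
        mean_cells, sigma = float(spec[1]), float(spec[2])
        mu = math.log(mean_cells) - 0.5 * sigma**2
        size = int(round(rng.lognormal(mu, sigma)))
    else:
        raise ValueError(f"unknown range-size distribution {kind!r}")
    size = max(size, 1)
    if size > n_cells:
        logger.warning(
            "requested range size %d exceeds lattice size %d; capped", size, n_cells
        )
        size = n_cells
    return size


def simulate_species(
    lattice: Lattice,
    env: EnvironmentFields | None = None,
    n_species: int = 577,
    range_size: tuple = ("lognormal", 25.0, 0.75),
    crossing_probability: float = 0.05,
    niche_field: str = "APRE",
    niche_breadth: float = math.inf,
    origin_blocks: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Grow species ranges by spreading dye and return the incidence table.

    Each species starts at a uniformly drawn seed cell (optionally restricted
    to a prescribed origin block) and repeatedly occupies a uniformly chosen
    unoccupied 4-neighbor of its current range until the drawn range size is
    reached.  A candidate reachable only across a river is accepted with
    probability ``crossing_probability`` (one Bernoulli trial per draw; a
    rejected candidate is excluded until the range next grows).  A candidate
    whose niche-field value lies further than ``niche_breadth`` from the
    species' niche center (the value at its seed cell) is never admissible.
    Growth stops early when no admissible neighbor remains, so no species ends
    with an empty range.

    Returns the cells × species 0/1 incidence DataFrame (index cell_id) and
    the planted :class:`GroundTruth`.

    Randomness: one integer master seed; species s draws from the independent
    substream ``default_rng([seed, s])``, so output is byte-identical across
    runs and insensitive to execution order.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0.0 <= crossing_probability <= 1.0:
        raise ValueError("crossing_probability must lie in [0, 1]")
    n = lattice.n_cells
    climate = None
    if env is not None and niche_field in env.table and math.isfinite(niche_breadth):
        climate = env.table[niche_field].to_numpy()

    block_cells: dict[int, np.ndarray] = {
        b: np.flatnonzero(lattice.block_label == b) for b in range(lattice.n_blocks)
    }
    if origin_blocks is not None and len(origin_blocks) != n_species:
        raise ValueError("origin_blocks must supply one block per species")

    occupancy = np.zeros((n, n_species), dtype=np.int8)
    origins = np.empty(n_species, dtype=int)
    neighbor_cache = [lattice.neighbors(i) for i in range(n)]

    for s in range(n_species):
        rng = np.random.default_rng([seed, s])
        if origin_blocks is not None:
            pool = block_cells[int(origin_blocks[s])]
            start = int(pool[rng.integers(len(pool))])
        else:
            start = int(rng.integers(n))
        origins[s] = lattice.block_label[start]
        target = _draw_range_size(range_size, rng, n)

        center = climate[start] if climate is not None else None
        occupied = {start}
        frontier: set[int] = set()
        blocked: set[int] = set()

        def admissible(cell: int) -> bool:
            if center is not None and abs(climate[cell] - center) > niche_breadth:
                return False
            return True

        for nb in neighbor_cache[start]:
            if admissible(nb):
                frontier.add(nb)
        while len(occupied) < target:
            open_candidates = frontier - blocked
            if not open_candidates:
                break
            cand_list = sorted(open_candidates)
            cand = cand_list[rng.integers(len(cand_list))]
            crossing_only = all(
                lattice.edge_crosses_river(cand, nb)
                for nb in neighbor_cache[cand]
                if nb in occupied
            )
            if crossing_only and rng.random() >= crossing_probability:
                blocked.add(cand)
                continue
            occupied.add(cand)
            frontier.discard(cand)
            blocked.clear()  # range changed: previously blocked cells may now
            for nb in neighbor_cache[cand]:  # adjoin via a non-crossing edge
                if nb not in occupied and admissible(nb):
                    frontier.add(nb)
        occupancy[sorted(occupied), s] = 1

    species_ids = [f"sp{s:04d}" for s in range(n_species)]
    incidence = pd.DataFrame(
        occupancy,
        index=pd.Index(lattice.cell_ids, name="cell_id"),
        columns=species_ids,
    )
    truth = GroundTruth(
        true_region=lattice.block_label.copy(),
        species_origin_block=origins,
        crossing_probability=crossing_probability,
        niche_breadth=niche_breadth,
    )
    return incidence, truth
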