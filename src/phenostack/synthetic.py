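"""Synthetic riparian landscape and population generator.

Builds everything the analysis needs when no field data are supplied: a
stack of four continuous climate layers on a latitudinal gradient, a
dendritic stream network carrying Strahler orders, future-scenario stacks as
additive layer shifts, and ~400 genotypes in three latitudinal populations
whose leaf-out day is a linear function of the local environment plus a
population offset and noise.

Seeding: one master seed spawns independent named substreams (environment,
stream, populations, ...) so regenerating one stage never perturbs another.
Future scenarios reuse the baseline noise field and only add deterministic
shifts, which keeps the planted-niche truth analytically computable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .geodata_io import (
    EnvStack,
    GridSpec,
    OccurrenceTable,
    ScenarioSpec,
    ValidationError,
    cell_center,
)

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "CapacityError",
    "substream",
    "default_scenarios",
    "simulate_environment",
    "simulate_populations",
    "plant_decile_niches",
    "population_band_masks",
    "recovery_config",
    "coherent_shift",
    "decile_agreement",
]

GCM_LABELS = ("inm-cm4", "mpi-esm-lr", "gfdl-cm3")


class CapacityError(ValidationError):
    """The stream network cannot hold the requested number of genotypes."""


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (master seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic landscape.

    Defaults emulate the study conditions: 400 genotypes split 57/157/186
    across southern/central/northern populations, leaf-out spanning Julian
    day 71-125, earlier leaf-out associated with higher moisture index and
    winter precipitation and with lower relative humidity and continentality.
    Layer units are arbitrary but consistent: each climate layer ranges over
    roughly [2, 8] along the latitudinal gradient.
    """

    n_rows: int = 160
    n_cols: int = 100
    origin_lon: float = -112.0
    origin_lat: float = 48.0
    cell_size: float = 0.05

    #: genotypes per population (southern, central, northern)
    pop_sizes: tuple[int, int, int] = (57, 157, 186)
    #: hard clip range of the trait, Julian days
    trait_min: int = 71
    trait_max: int = 125
    trait_baseline: float = 98.0
    #: additive per-population day offsets (southern, central, northern)
    pop_offsets: tuple[float, float, float] = (-6.0, 0.0, 6.0)
    #: days per unit of each (unstandardised) layer; signs fix the
    #: trait-environment correlations
    trait_coefs: dict = field(
        default_factory=lambda: {"cmi": -1.8, "ppt_wt": -0.6, "rh": 0.8, "td": 1.0}
    )
    trait_noise_sd: float = 8.0

    #: per-layer (value at south edge, value at north edge)
    gradients: dict = field(
        default_factory=lambda: {
            "cmi": (8.0, 2.0),
            "ppt_wt": (7.0, 3.0),
            "rh": (3.0, 7.0),
            "td": (3.0, 7.0),
        }
    )
    #: sd of the smooth spatial noise added to every climate layer
    env_noise_sd: float = 0.6
    #: gaussian smoothing radius of the noise field, in cells
    env_noise_smooth: float = 3.0

    #: coarse-lattice spacing (cells) of the stream spanning tree; 3 gives a
    #: dense network whose decile models evaluate near the reference AUC band
    stream_spacing: int = 3

    #: additive layer shift per scenario = base * rcp * period * gcm factor.
    #: Signs push every layer beyond its present southern-edge values
    #: (trailing-edge conditions intensify), which is what drives the
    #: south-heavy loss of suitable bands under projection.
    base_shifts: dict = field(
        default_factory=lambda: {"cmi": 0.9, "ppt_wt": 0.5, "rh": -0.6, "td": -0.7}
    )
    rcp_factors: dict = field(default_factory=lambda: {"4.5": 1.0, "8.5": 1.6})
    period_factors: dict = field(default_factory=lambda: {"2050s": 1.0, "2080s": 1.5})
    gcm_factors: dict = field(
        default_factory=lambda: {"inm-cm4": 0.7, "mpi-esm-lr": 1.0, "gfdl-cm3": 1.3}
    )

    #: fraction of rows (north to south) the three populations occupy;
    #: a span narrower than (0, 1) leaves unoccupied climatic margins at
    #: both range edges, as in a species whose envelope is narrower than
    #: the modeled landscape
    pop_row_range: tuple[float, float] = (0.0, 1.0)

    #: planted-niche truth: driver layer and band overlap (in band widths)
    niche_driver: str = "cmi"
    niche_overlap: float = 0.5

    seed: int = 20220

    def __post_init__(self) -> None:
        if min(self.pop_sizes) < 0 or max(self.pop_sizes) == 0:
            raise ValidationError("population sizes must be >= 0 with at least one > 0")
        if self.trait_min >= self.trait_max:
            raise ValidationError("trait range endpoints must be ordered")
        if self.trait_noise_sd < 0:
            raise ValidationError("trait noise sd must be >= 0")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
        )

    @property
    def n_total(self) -> int:
        return sum(self.pop_sizes)

    def scenario_shifts(self, scenario: ScenarioSpec) -> dict[str, float]:
        """Additive per-layer shift of a scenario relative to baseline."""
        if scenario.is_current:
            return {name: 0.0 for name in self.base_shifts}
        f = (
            self.rcp_factors[scenario.rcp]
            * self.period_factors[scenario.period]
            * self.gcm_factors.get(scenario.gcm, 1.0)
        )
        return {name: base * f for name, base in self.base_shifts.items()}


def default_scenarios() -> list[ScenarioSpec]:
    """Baseline plus the 3 GCM x 2 RCP x 2 period future grid (13 total)."""
    out = [ScenarioSpec.current()]
    for gcm in GCM_LABELS:
        for rcp in ("4.5", "8.5"):
            for period in ("2050s", "2080s"):
                out.append(ScenarioSpec(gcm=gcm, rcp=rcp, period=period))
    return out


# ---------------------------------------------------------------------------
# environment


def _latitude_gradient(n_rows: int, n_cols: int, south: float, north: float) -> np.ndarray:
    # row 0 is the north edge
    col = np.linspace(north, south, n_rows)[:, None]
    return np.repeat(col, n_cols, axis=1)


def _smooth_noise(rng: np.random.Generator, shape, sd: float, sigma: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    # periodic boundaries keep the field stationary (no corner artifacts)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def _stream_layer(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Rasterised random spanning tree with Strahler orders (0 = non-stream)."""
    sp = cfg.stream_spacing
    ni = max(2, cfg.n_rows // sp)
    nj = max(2, cfg.n_cols // sp)
    g = nx.grid_2d_graph(ni, nj)
    for u, v in g.edges:
        g.edges[u, v]["w"] = rng.random()
    tree = nx.minimum_spanning_tree(g, weight="w")
    # outlet at the southernmost lattice row (random column)
    root = (ni - 1, int(rng.integers(nj)))

    order: dict = {}
    for node in nx.dfs_postorder_nodes(tree, source=root):
        child_orders = [order[n] for n in tree.neighbors(node) if n in order]
        if not child_orders:
            order[node] = 1
        else:
            m = max(child_orders)
            order[node] = m + 1 if child_orders.count(m) >= 2 else m

    def to_cell(node):
        i, j = node
        return (min(i * sp + sp // 2, cfg.n_rows - 1), min(j * sp + sp // 2, cfg.n_cols - 1))

    layer = np.zeros((cfg.n_rows, cfg.n_cols))
    for parent, child in nx.dfs_edges(tree, source=root):
        # edge carries the order of its upstream (child) node
        o = order[child]
        (r0, c0), (r1, c1) = to_cell(parent), to_cell(child)
        n_steps = max(abs(r1 - r0), abs(c1 - c0))
        for t in range(n_steps + 1):
            r = r0 + round(t * (r1 - r0) / max(n_steps, 1))
            c = c0 + round(t * (c1 - c0) / max(n_steps, 1))
            layer[r, c] = max(layer[r, c], o)
    layer[to_cell(root)] = max(layer[to_cell(root)], order[root])
    return layer


def simulate_environment(cfg: SyntheticConfig, scenario: ScenarioSpec | None = None) -> EnvStack:
    """Build the five-layer stack for one scenario.

    Climate layers are a latitudinal gradient plus smooth spatial noise;
    future scenarios add the configured deterministic shift to the identical
    baseline field (noise is not resimulated).  The stream layer is shared
    across scenarios.
    """
    scenario = scenario or ScenarioSpec.current()
    rng = substream(cfg.seed, "environment")
    layers: dict[str, np.ndarray] = {}
    for name, (south, north) in cfg.gradients.items():
        base = _latitude_gradient(cfg.n_rows, cfg.n_cols, south, north)
        noise = _smooth_noise(rng, base.shape, cfg.env_noise_sd, cfg.env_noise_smooth)
        layers[name] = base + noise
    layers["stream_order"] = _stream_layer(cfg, substream(cfg.seed, "stream"))
    shifts = cfg.scenario_shifts(scenario)
    for name, delta in shifts.items():
        if delta:
            layers[name] = layers[name] + delta
    return EnvStack(cfg.grid, layers)


# ---------------------------------------------------------------------------
# populations

_POP_ORDER = ("southern", "central", "northern")


def population_band_masks(
    grid: GridSpec, row_range: tuple[float, float] = (0.0, 1.0)
) -> dict[str, np.ndarray]:
    """Latitudinal thirds standing in for the three watershed extents.

    Row 0 is north, so the northern population occupies the top third.
    ``row_range`` restricts the occupied span (fractions of n_rows).
    """
    r0 = int(round(row_range[0] * grid.n_rows))
    r1 = int(round(row_range[1] * grid.n_rows))
    thirds = np.array_split(np.arange(r0, r1), 3)
    masks = {}
    for name, rows in zip(("northern", "central", "southern"), thirds):
        m = np.zeros(grid.shape, dtype=bool)
        m[rows, :] = True
        masks[name] = m
    return masks


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def trait_from_environment(
    env: EnvStack, cfg: SyntheticConfig, cells: np.ndarray, pop_offset: float,
    noise: np.ndarray,
) -> np.ndarray:
    """Deterministic trait rule: baseline + sum(coef * layer) + offset + noise."""
    names = list(cfg.trait_coefs)
    vals = env.values_at(cells, names)
    coefs = np.array([cfg.trait_coefs[n] for n in names])
    day = cfg.trait_baseline + vals @ coefs + pop_offset + noise
    day = _round_half_away(day)
    return np.clip(day, cfg.trait_min, cfg.trait_max).astype(int)


def simulate_populations(env: EnvStack, cfg: SyntheticConfig) -> OccurrenceTable:
    """Place genotypes on stream cells and assign genetically based leaf-out.

    Each population samples cells without replacement from the stream cells
    of its latitude band; raises :class:`CapacityError` when a band has fewer
    stream cells than genotypes.
    """
    rng = substream(cfg.seed, "populations")
    stream = env.layers["stream_order"] > 0
    bands = population_band_masks(env.grid, cfg.pop_row_range)
    records = []
    prefix = {"southern": "S", "central": "C", "northern": "N"}
    for pop, size, offset in zip(_POP_ORDER, cfg.pop_sizes, cfg.pop_offsets):
        if size == 0:
            continue
        candidates = np.argwhere(stream & bands[pop] & env.valid_mask)
        if len(candidates) < size:
            raise CapacityError(
                f"population {pop!r} needs {size} stream cells, band has {len(candidates)}"
            )
        idx = rng.choice(len(candidates), size=size, replace=False)
        cells = candidates[np.sort(idx)]
        noise = rng.normal(0.0, cfg.trait_noise_sd, size=size) if cfg.trait_noise_sd else np.zeros(size)
        days = trait_from_environment(env, cfg, cells, offset, noise)
        for k, ((r, c), day) in enumerate(zip(cells, days), start=1):
            lon, lat = cell_center(env.grid, r, c)
            records.append(
                {
                    "genotype_id": f"{prefix[pop]}{k:03d}",
                    "lon": lon,
                    "lat": lat,
                    "population": pop,
                    "leafout_day": int(day),
                }
            )
    return OccurrenceTable(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# planted-niche truth


@dataclass
class TruthRecord:
    """Analytic per-decile suitability rule used as a recovery oracle.

    The driver layer's value range over stream cells is split into ten
    equal-width contiguous bands; decile ``d`` is truly suitable on a stream
    cell when the driver falls inside band ``d`` widened by ``overlap`` band
    widths on each side.  Because scenarios are additive shifts of the same
    field, the truth under any scenario is exact band arithmetic.
    """

    driver: str
    #: ascending quantile edges of the driver over occupied stream cells;
    #: equal-count bands align with the equal-count trait deciles (and
    #: coincide with equal-width bands for a uniform driver)
    band_edges: np.ndarray  # shape (11,)
    overlap: float
    grid: GridSpec
    #: decile 1 is the earliest leaf-out; when the trait decreases with the
    #: driver, decile 1 occupies the TOP driver band
    descending: bool = False

    @property
    def band_width(self) -> float:
        """Mean band width (exact width of every band for a uniform driver)."""
        return float(self.band_edges[-1] - self.band_edges[0]) / 10.0

    def band_of_decile(self, d: int) -> tuple[float, float]:
        b = (11 - d) if self.descending else d
        return float(self.band_edges[b - 1]), float(self.band_edges[b])

    def true_mask_bits(self, env: EnvStack) -> np.ndarray:
        """uint16 bitmask of truly suitable deciles per cell (0 off-stream)."""
        vals = env.layers[self.driver]
        stream = env.layers["stream_order"] > 0
        top = float(self.band_edges[-1])
        bits = np.zeros(self.grid.shape, dtype=np.uint16)
        for d in range(1, 11):
            b_lo, b_hi = self.band_of_decile(d)
            w = b_hi - b_lo
            lo = b_lo - self.overlap * w
            hi = b_hi + self.overlap * w
            # the topmost band is closed above
            inside = (vals >= lo) & ((vals <= hi) if b_hi >= top else (vals < hi))
            bits |= np.where(inside & stream & env.valid_mask, np.uint16(1 << (d - 1)), np.uint16(0))
        return bits

    def true_richness(self, env: EnvStack) -> np.ndarray:
        return np.bitwise_count(self.true_mask_bits(env)).astype(int)


def plant_decile_niches(env: EnvStack, cfg: SyntheticConfig) -> TruthRecord:
    """Derive the banded truth rule from the baseline driver layer."""
    driver = cfg.niche_driver
    stream = (env.layers["stream_order"] > 0) & env.valid_mask
    occupied = np.zeros(env.grid.shape, dtype=bool)
    for m in population_band_masks(env.grid, cfg.pop_row_range).values():
        occupied |= m
    vals = env.layers[driver][stream & occupied]
    if float(vals.max()) <= float(vals.min()):
        raise ValidationError(f"driver layer {driver!r} is constant; cannot plant niches")
    edges = np.quantile(vals, np.linspace(0.0, 1.0, 11))
    return TruthRecord(
        driver=driver,
        band_edges=edges,
        overlap=cfg.niche_overlap,
        grid=env.grid,
        descending=cfg.trait_coefs.get(driver, 0.0) < 0,
    )


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of the config with a different master seed."""
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# planted-niche recovery experiment


def recovery_config(seed: int = 42) -> SyntheticConfig:
    """Study conditions for the parameter-recovery experiment.

    One dominant driver (cmi) determines the trait with little noise, the
    three populations occupy an interior latitude span so both range edges
    carry unoccupied (background-only) climates, and spatial noise is small
    enough that the planted quantile bands are sharp.  400 genotypes as in
    the default conditions.
    """
    return SyntheticConfig(
        seed=seed,
        gradients={"cmi": (10.0, 0.0), "ppt_wt": (7.0, 3.0), "rh": (3.0, 7.0), "td": (3.0, 7.0)},
        trait_coefs={"cmi": -5.0, "ppt_wt": 0.0, "rh": 0.0, "td": 0.0},
        trait_baseline=122.0,
        trait_noise_sd=1.0,
        pop_offsets=(0.0, 0.0, 0.0),
        pop_row_range=(0.18, 0.82),
        env_noise_sd=0.2,
        niche_overlap=0.5,
    )


def coherent_shift(env: EnvStack, cfg: SyntheticConfig, n_bands: float) -> dict[str, float]:
    """Uniform climate displacement of ``n_bands`` driver band widths.

    Every gradient layer shifts by the same number of tenths of its own
    occupied value span, signed by its gradient's alignment with latitude,
    so the whole climate field translates coherently and the planted truth
    moves by exactly ``n_bands`` bands.
    """
    stream = (env.layers["stream_order"] > 0) & env.valid_mask
    occupied = np.zeros(env.grid.shape, dtype=bool)
    for m in population_band_masks(env.grid, cfg.pop_row_range).values():
        occupied |= m
    shifts = {}
    for name, (south, north) in cfg.gradients.items():
        vals = env.layers[name][stream & occupied]
        span = (float(vals.max()) - float(vals.min())) / 10.0
        shifts[name] = n_bands * span * (1.0 if south > north else -1.0)
    return shifts


def decile_agreement(binaries, truth_bits: np.ndarray, mask: np.ndarray) -> float:
    """Mean per-(cell, decile) match of fitted binary maps vs the truth bits."""
    mask = np.asarray(mask, dtype=bool)
    vals = []
    for b in binaries:
        t = (truth_bits >> (b.decile - 1)) & 1
        vals.append(np.mean((b.values[mask] == 1) == (t[mask] == 1)))
    return float(np.mean(vals))
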