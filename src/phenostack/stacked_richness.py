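"""Stacking binary decile maps into richness, change and loss summaries.

Decile richness at a cell is the number of trait-decile models predicting
it suitable (0-10): a proxy for how much genetically based leaf-out
variation the local climate supports.  Scenario change is the cell-wise
difference future - current; cells with zero baseline richness are tracked
separately because a zero change there means "unsuitable throughout", not
"stable".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .geodata_io import GridSpec, ScenarioSpec, GridMismatchError, ValidationError
from .sdm_engine import BinaryMap

__all__ = [
    "RichnessMap",
    "ChangeMap",
    "ChangeSummary",
    "stack",
    "richness_change",
    "summarize_change",
    "percent_area",
    "tail_frequency",
]


@dataclass
class RichnessMap:
    grid: GridSpec
    values: np.ndarray  # int, 0..n_deciles at valid cells
    valid_mask: np.ndarray
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec.current)


@dataclass
class ChangeMap:
    grid: GridSpec
    delta: np.ndarray  # int, -n..n at valid cells
    valid_mask: np.ndarray
    unsuitable_baseline_mask: np.ndarray  # current richness == 0
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec.current)


@dataclass
class ChangeSummary:
    """Loss/gain percentages over one extent for one scenario.

    ``percent_loss``/``percent_gain`` count changed cells regardless of
    magnitude; the magnitude lives in ``histogram`` (delta value -> cell
    count over nonzero deltas).
    """

    extent: str
    scenario: ScenarioSpec
    denominator: int
    percent_loss: float
    percent_gain: float
    net_loss: float
    histogram: dict[int, int]
    denominator_rule: str = "all-valid"


def stack(binaries: list[BinaryMap], expected_n: int = 10) -> RichnessMap:
    """Cell-wise sum of binary maps; nodata propagates from any input."""
    if len(binaries) != expected_n:
        raise ValidationError(f"expected {expected_n} binary maps, got {len(binaries)}")
    grid = binaries[0].grid
    for b in binaries[1:]:
        if not grid.approx_equal(b.grid):
            raise GridMismatchError(f"decile {b.decile} map is on a different grid")
    valid = np.logical_and.reduce([b.valid_mask for b in binaries])
    values = np.sum([b.values for b in binaries], axis=0).astype(np.int16)
    values[~valid] = 0
    return RichnessMap(grid=grid, values=values, valid_mask=valid, scenario=binaries[0].scenario)


def richness_change(current: RichnessMap, future: RichnessMap) -> ChangeMap:
    """future - current richness with the zero-baseline disambiguation mask."""
    if not current.grid.approx_equal(future.grid):
        raise GridMismatchError("richness maps are on different grids")
    if not current.scenario.is_current:
        raise ValidationError("first argument must be the current-scenario map")
    valid = current.valid_mask & future.valid_mask
    delta = (future.values.astype(int) - current.values.astype(int)).astype(np.int16)
    delta[~valid] = 0
    unsuitable = (current.values == 0) & valid
    return ChangeMap(
        grid=current.grid,
        delta=delta,
        valid_mask=valid,
        unsuitable_baseline_mask=unsuitable,
        scenario=future.scenario,
    )


def summarize_change(
    chg: ChangeMap,
    extent_mask: np.ndarray,
    denominator_rule: str = "all-valid",
    extent_label: str = "extent",
) -> ChangeSummary:
    """Percent of an extent losing/gaining richness, and the net loss.

    ``all-valid`` divides by every valid cell in the extent ("percent of the
    landscape modeled"); ``suitable-only`` divides by cells suitable for at
    least one decile at baseline.
    """
    if denominator_rule not in ("all-valid", "suitable-only"):
        raise ValidationError(f"unknown denominator rule {denominator_rule!r}")
    in_extent = chg.valid_mask & extent_mask.astype(bool)
    if denominator_rule == "suitable-only":
        in_extent = in_extent & ~chg.unsuitable_baseline_mask
    denom = int(in_extent.sum())
    if denom == 0:
        raise ValidationError(f"extent {extent_label!r} has no cells under rule {denominator_rule}")
    d = chg.delta[in_extent]
    n_loss = int((d < 0).sum())
    n_gain = int((d > 0).sum())
    pct_loss = 100.0 * n_loss / denom
    pct_gain = 100.0 * n_gain / denom
    vals, counts = np.unique(d[d != 0], return_counts=True)
    hist = {int(v): int(c) for v, c in zip(vals, counts)}
    return ChangeSummary(
        extent=extent_label,
        scenario=chg.scenario,
        denominator=denom,
        percent_loss=pct_loss,
        percent_gain=pct_gain,
        net_loss=pct_loss - pct_gain,
        histogram=hist,
        denominator_rule=denominator_rule,
    )


def percent_area(count_suitable: int, count_total: int) -> float:
    """100 * suitable/total, rounded half-up to one decimal."""
    if count_total <= 0:
        raise ValidationError("total cell count must be positive")
    if count_suitable > count_total or count_suitable < 0:
        raise ValidationError("suitable count must lie in [0, total]")
    pct = Decimal(100 * count_suitable) / Decimal(count_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tail_frequency(
    binaries: list[BinaryMap],
    richness: RichnessMap,
    extent_mask: np.ndarray,
    deciles: tuple[int, ...] = (1, 10),
) -> dict[int, float | None]:
    """Frequency of the tail deciles over the richness >= 1 landscape.

    frequency(d) = (# extent cells where decile d is predicted present) /
    (# extent cells with richness >= 1).  ``None`` (missing) when no cell in
    the extent is suitable for any decile.
    """
    by_decile = {b.decile: b for b in binaries}
    in_extent = richness.valid_mask & extent_mask.astype(bool)
    denom = int(((richness.values >= 1) & in_extent).sum())
    out: dict[int, float | None] = {}
    for d in deciles:
        if d not in by_decile:
            raise ValidationError(f"no binary map for decile {d}")
        if denom == 0:
            out[d] = None
        else:
            b = by_decile[d]
            if not richness.grid.approx_equal(b.grid):
                raise GridMismatchError("binary and richness maps differ in grid")
            out[d] = float(((b.values == 1) & in_extent).sum() / denom)
    return out
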