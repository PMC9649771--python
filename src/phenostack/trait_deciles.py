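"""Trait-decile binning and spatial thinning of genotype occurrences.

Genotypes are sorted by leaf-out day and cut into ten equal-count bins.
Because several genotypes can share a day, a tie group that straddles an
ideal cut is moved wholly into the earlier (lower) decile, so no trait
value ever spans two deciles.  Within each decile, spatial thinning keeps
at most one presence per grid cell; the same cell may still carry presences
of different deciles.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geodata_io import GridSpec, OccurrenceTable, ValidationError, point_to_cell

__all__ = [
    "DecileAssignment",
    "PresenceSet",
    "DegenerateInputError",
    "assign_deciles",
    "thin_presences",
    "presences_to_frame",
]


class DegenerateInputError(ValidationError):
    """Too few distinct trait values to fill every decile."""


@dataclass
class DecileAssignment:
    """Partition of genotypes into ordered trait deciles (1 = earliest)."""

    decile_of: dict[str, int]
    members: dict[int, list[str]]  # decile -> genotype ids in (day, id) order
    trait_ranges: dict[int, tuple[int, int]]  # decile -> (min day, max day)
    n_bins: int = 10


@dataclass
class PresenceSet:
    """Spatially thinned presences of one decile."""

    decile: int
    cells: list[tuple[int, int]]
    genotype_ids: list[str]

    @property
    def n_occ(self) -> int:
        return len(self.cells)


def assign_deciles(occ: OccurrenceTable, n_bins: int = 10) -> DecileAssignment:
    """Cut the sorted trait distribution at ideal boundaries i*n/n_bins.

    A group of genotypes sharing a day never splits: if it straddles a
    boundary the whole group lands in the lower (earlier) bin.  Fewer than
    ``n_bins`` distinct trait values raise :class:`DegenerateInputError`
    listing the empty bins; with enough distinct values, large tie groups
    can still leave a bin empty, which is reported in the assignment rather
    than raised (real decile sizes simply vary with ties).
    """
    n = len(occ)
    if n < n_bins:
        raise DegenerateInputError(f"need at least {n_bins} genotypes, got {n}")
    df = occ.df.sort_values(["leafout_day", "genotype_id"]).reset_index(drop=True)
    decile_of: dict[str, int] = {}
    members: dict[int, list[str]] = {d: [] for d in range(1, n_bins + 1)}
    start = 0
    for _, group in df.groupby("leafout_day", sort=True):
        d = int(start * n_bins // n) + 1
        for gid in group["genotype_id"]:
            decile_of[gid] = d
            members[d].append(gid)
        start += len(group)
    empty = [d for d in members if not members[d]]
    n_distinct = df["leafout_day"].nunique()
    if empty and n_distinct < n_bins:
        raise DegenerateInputError(
            f"{n_distinct} distinct trait values leave deciles {empty} empty"
        )
    day_of = dict(zip(df["genotype_id"], df["leafout_day"]))
    trait_ranges = {
        d: (min(day_of[g] for g in ids), max(day_of[g] for g in ids))
        for d, ids in members.items()
        if ids
    }
    return DecileAssignment(decile_of, members, trait_ranges, n_bins)


def thin_presences(
    assign: DecileAssignment, occ: OccurrenceTable, grid: GridSpec
) -> list[PresenceSet]:
    """One presence per cell per decile, keeping the first in (day, id) order."""
    df = occ.df.set_index("genotype_id")
    out: list[PresenceSet] = []
    for d in range(1, assign.n_bins + 1):
        seen: set[tuple[int, int]] = set()
        cells: list[tuple[int, int]] = []
        ids: list[str] = []
        for gid in assign.members.get(d, []):
            row = df.loc[gid]
            cell = point_to_cell(grid, float(row["lon"]), float(row["lat"]))
            if cell is None:
                raise ValidationError(f"genotype {gid!r} lies outside the grid extent")
            if cell in seen:
                continue
            seen.add(cell)
            cells.append(cell)
            ids.append(gid)
        out.append(PresenceSet(decile=d, cells=cells, genotype_ids=ids))
    return out


def presences_to_frame(
    presences: list[PresenceSet], occ: OccurrenceTable, grid: GridSpec
) -> pd.DataFrame:
    """Audit table (decile, genotype_id, lon, lat, row, col) of retained points."""
    df = occ.df.set_index("genotype_id")
    rows = []
    for ps in presences:
        for gid, (r, c) in zip(ps.genotype_ids, ps.cells):
            rec = df.loc[gid]
            rows.append(
                {
                    "decile": ps.decile,
                    "genotype_id": gid,
                    "lon": float(rec["lon"]),
                    "lat": float(rec["lat"]),
                    "row": r,
                    "col": c,
                }
            )
    return pd.DataFrame(rows, columns=["decile", "genotype_id", "lon", "lat", "row", "col"])
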