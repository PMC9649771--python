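"""Decile-combination communities, similarity scores and constrained ordination.

Each suitable cell carries a non-empty subset of the ten trait deciles,
encoded as a 10-bit mask (bit d-1 <=> decile d present; 1..1023).  Tallying
cells by mask per (population, scenario) yields a community matrix exactly
analogous to a sites x species abundance table, which is then summarized by
a per-cell similarity score and analysed with redundancy analysis (RDA)
under permutation tests.

Similarity of a cell's decile set is 1 - dbar/9, where dbar is the mean
pairwise |i-j| over present deciles (0 for singletons), so 1 means a narrow
trait range and 0 is reached only by the {1,10} pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata_io import ScenarioSpec, GridMismatchError, ValidationError
from .sdm_engine import BinaryMap

__all__ = [
    "CommunityMatrix",
    "SimilarityScore",
    "OrdinationResult",
    "encode_combination",
    "decode_combination",
    "combination_bits",
    "cell_similarity",
    "build_community_matrix",
    "scenario_similarity",
    "rda",
    "select_constraints",
]

N_DECILES = 10
N_COMBINATIONS = (1 << N_DECILES) - 1  # 1023 non-empty subsets


def encode_combination(present) -> int:
    """Bitmask of a non-empty set of decile indices (bit d-1 per decile d)."""
    present = set(present)
    if not present:
        raise ValidationError("richness-0 cells are excluded, not encoded")
    if not present <= set(range(1, N_DECILES + 1)):
        raise ValidationError(f"decile indices must lie in 1..{N_DECILES}: {sorted(present)}")
    mask = 0
    for d in present:
        mask |= 1 << (d - 1)
    return mask


def decode_combination(mask: int) -> frozenset:
    if not 1 <= mask <= N_COMBINATIONS:
        raise ValidationError(f"mask must lie in 1..{N_COMBINATIONS}, got {mask}")
    return frozenset(d for d in range(1, N_DECILES + 1) if mask & (1 << (d - 1)))


def cell_similarity(present) -> float:
    """1 - (mean pairwise |i-j| of present deciles)/9; singletons score 1."""
    deciles = sorted(set(present))
    if not deciles:
        raise ValidationError("similarity of an empty decile set is undefined")
    if len(deciles) == 1:
        return 1.0
    dists = [
        abs(deciles[i] - deciles[j])
        for i in range(len(deciles))
        for j in range(i + 1, len(deciles))
    ]
    return 1.0 - float(np.mean(dists)) / (N_DECILES - 1)


def _similarity_lookup() -> np.ndarray:
    """similarity[mask] for all 1..1023 (index 0 unused, NaN)."""
    out = np.full(N_COMBINATIONS + 1, np.nan)
    for mask in range(1, N_COMBINATIONS + 1):
        out[mask] = cell_similarity(decode_combination(mask))
    return out


_SIMILARITY = _similarity_lookup()


def combination_bits(binaries: list[BinaryMap]) -> np.ndarray:
    """Per-cell uint16 decile bitmask from the ten binary maps."""
    grid = binaries[0].grid
    bits = np.zeros(grid.shape, dtype=np.uint16)
    for b in binaries:
        if not grid.approx_equal(b.grid):
            raise GridMismatchError(f"decile {b.decile} map is on a different grid")
        bits |= (b.values.astype(np.uint16) & 1) << (b.decile - 1)
    valid = np.logical_and.reduce([b.valid_mask for b in binaries])
    bits[~valid] = 0
    return bits


@dataclass
class CommunityMatrix:
    """Rows (population, scenario) x 1023 combination-mask columns of cell counts."""

    counts: pd.DataFrame  # index: MultiIndex (population, scenario label); columns 1..1023
    scenarios: dict[str, ScenarioSpec] = field(default_factory=dict)

    def row(self, population: str, scenario_label: str) -> np.ndarray:
        return self.counts.loc[(population, scenario_label)].to_numpy()

    def to_long(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_2": "mask"})
        )
        return long[long["count"] > 0].reset_index(drop=True)


def build_community_matrix(
    binaries_by_scenario: dict[str, list[BinaryMap]],
    extents: dict[str, np.ndarray],
    scenarios: dict[str, ScenarioSpec] | None = None,
) -> CommunityMatrix:
    """Tally suitable cells by decile combination per population x scenario.

    Richness-0 cells are excluded, so each row sums to the number of cells
    suitable for at least one decile in that population's extent.
    """
    index = []
    rows = []
    for scen_label, binaries in binaries_by_scenario.items():
        bits = combination_bits(binaries)
        for pop, mask in extents.items():
            sel = bits[mask.astype(bool)]
            sel = sel[sel > 0]
            counts = np.bincount(sel, minlength=N_COMBINATIONS + 1)[1:]
            index.append((pop, scen_label))
            rows.append(counts)
    df = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["population", "scenario"]),
        columns=range(1, N_COMBINATIONS + 1),
    )
    return CommunityMatrix(counts=df, scenarios=dict(scenarios or {}))


@dataclass
class SimilarityScore:
    population: str
    scenario: str
    value: float
    baseline_delta: float | None = None  # positive = trait values converging


def scenario_similarity(matrix: CommunityMatrix) -> list[SimilarityScore]:
    """Count-weighted mean cell similarity per row, with baseline deltas.

    The delta compares each future row with the same population's ``current``
    row; positive values mean the trait distribution is narrowing
    (converging).  Rows with zero suitable cells yield a missing value.
    """
    values: dict[tuple[str, str], float | None] = {}
    for (pop, scen) in matrix.counts.index:
        counts = matrix.counts.loc[(pop, scen)].to_numpy(dtype=float)
        total = counts.sum()
        values[(pop, scen)] = (
            float((counts * _SIMILARITY[1:]).sum() / total) if total > 0 else None
        )
    out = []
    for (pop, scen), val in values.items():
        base = values.get((pop, "current"))
        delta = None
        if val is not None and base is not None:
            delta = val - base
        out.append(
            SimilarityScore(
                population=pop,
                scenario=scen,
                value=float("nan") if val is None else val,
                baseline_delta=delta,
            )
        )
    return out


# ---------------------------------------------------------------------------
# constrained ordination


@dataclass
class OrdinationResult:
    constrained_fraction: float
    p_value: float
    constraints: list[str]
    marginal_fractions: dict[str, float] = field(default_factory=dict)


def _dummy_code(constraints: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Column-centered dummy coding (first level dropped per factor)."""
    parts = []
    for col in columns:
        d = pd.get_dummies(constraints[col].astype(str), prefix=col, drop_first=True)
        parts.append(d.to_numpy(dtype=float))
    if not parts:
        return np.zeros((len(constraints), 0))
    X = np.column_stack(parts)
    return X - X.mean(axis=0)


def _constrained_fraction(Y: np.ndarray, X: np.ndarray) -> float:
    """SS(fitted)/SS(total) of column-centered Y regressed on X."""
    Yc = Y - Y.mean(axis=0)
    tot = float((Yc**2).sum())
    if tot == 0:
        raise ValidationError("response matrix has no variance")
    if X.shape[1] == 0 or not np.any(X):
        return 0.0
    beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
    fitted = X @ beta
    return float((fitted**2).sum() / tot)


def rda(
    matrix,
    constraints: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    check_rank: bool = True,
) -> OrdinationResult:
    """Redundancy analysis of a count matrix on dummy-coded factors.

    The count matrix is column-centered; the constrained variance fraction
    is SS(fitted)/SS(total), and the p-value comes from ``n_perm`` seeded
    row permutations of the constraint table.
    """
    Y = matrix.counts.to_numpy(dtype=float) if isinstance(matrix, CommunityMatrix) else np.asarray(matrix, dtype=float)
    if Y.shape[0] < 2:
        raise ValidationError("RDA needs at least 2 rows")
    if len(constraints) != Y.shape[0]:
        raise ValidationError("constraint table does not align with matrix rows")
    cols = list(constraints.columns)
    X = _dummy_code(constraints, cols)
    if check_rank and X.shape[1] > 0:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            aliased = _aliased_columns(constraints, cols)
            raise ValidationError(f"rank-deficient constraints; aliased levels: {aliased}")
    obs = _constrained_fraction(Y, X)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(Y.shape[0])
        if _constrained_fraction(Y, X[perm]) >= obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    marginals = {
        c: _constrained_fraction(Y, _dummy_code(constraints, [c])) for c in cols
    }
    return OrdinationResult(
        constrained_fraction=obs, p_value=p, constraints=cols, marginal_fractions=marginals
    )


def _aliased_columns(constraints: pd.DataFrame, cols: list[str]) -> list[str]:
    X = _dummy_code(constraints, cols)
    names: list[str] = []
    for col in cols:
        d = pd.get_dummies(constraints[col].astype(str), prefix=col, drop_first=True)
        names += list(d.columns)
    keep: list[int] = []
    aliased = []
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def _term_pvalue(
    Y: np.ndarray,
    constraints: pd.DataFrame,
    base: list[str],
    term: str,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p of the added fraction of `term` given `base` terms."""
    X_base = _dummy_code(constraints, base)
    f_base = _constrained_fraction(Y, X_base) if base else 0.0
    obs = _constrained_fraction(Y, _dummy_code(constraints, base + [term])) - f_base
    n_ge = 0
    shuffled = constraints.copy()
    for _ in range(n_perm):
        shuffled[term] = constraints[term].to_numpy()[rng.permutation(len(constraints))]
        f = _constrained_fraction(Y, _dummy_code(shuffled, base + [term])) - f_base
        if f >= obs - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (1 + n_perm)


def select_constraints(
    matrix,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
    max_rounds: int = 20,
) -> list[str]:
    """Stepwise forward/backward constraint selection by permutation tests.

    Forward: add the candidate with the smallest permutation p below alpha.
    Backward: drop any selected term whose marginal contribution is no
    longer significant.  Iterates to a fixed point; an empty selection is a
    valid outcome.
    """
    Y = matrix.counts.to_numpy(dtype=float) if isinstance(matrix, CommunityMatrix) else np.asarray(matrix, dtype=float)
    if candidates.shape[1] < 1:
        raise ValidationError("need at least one candidate factor")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for _ in range(max_rounds):
        changed = False
        # forward step
        remaining = [c for c in candidates.columns if c not in selected]
        best, best_p = None, alpha
        for term in remaining:
            Xf = _dummy_code(candidates, selected + [term])
            if np.linalg.matrix_rank(Xf) <= np.linalg.matrix_rank(_dummy_code(candidates, selected)):
                continue  # term adds nothing (aliased/saturated)
            p = _term_pvalue(Y, candidates, selected, term, n_perm, rng)
            if p < best_p or (best is not None and p == best_p and term < best):
                best, best_p = term, p
        if best is not None:
            selected.append(best)
            changed = True
        # backward step
        for term in list(selected):
            others = [t for t in selected if t != term]
            p = _term_pvalue(Y, candidates, others, term, n_perm, rng)
            if p >= alpha:
                selected.remove(term)
                changed = True
        if not changed:
            break
    return selected
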