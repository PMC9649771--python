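"""Presence-background distribution model per trait decile.

The model is the weighted-logistic formulation of maximum entropy: presences
(total weight 1) are contrasted against a large background sample (total
weight ``bg_weight``), with an L2 penalty on standardized feature
coefficients.  Suitability is the logistic output at an assumed prevalence
of 0.5, obtained by removing the class-imbalance term from the fitted
intercept, so an uninformative model scores 0.5 everywhere.

Features default to linear + quadratic terms of each layer (adequate for
band-shaped niches at ~40 presences per model); product and hinge classes
are available behind :class:`FeatureSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .geodata_io import EnvStack, GridSpec, ScenarioSpec, ValidationError
from .trait_deciles import PresenceSet

__all__ = [
    "FeatureSpec",
    "SDMModel",
    "EvalReport",
    "BinaryMap",
    "ConvergenceError",
    "sample_background",
    "fit_sdm",
    "predict_suitability",
    "compute_auc",
    "crossvalidate",
    "threshold_10pct",
    "variable_contribution",
]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")


class ConvergenceError(RuntimeError):
    """Optimizer hit the iteration cap; carries diagnostics."""


@dataclass
class FeatureSpec:
    """Feature expansion recipe with frozen normalization constants.

    Normalization (mean/sd and min/max per layer) is computed once from the
    training stack's valid cells and reused verbatim for every projection,
    so a model projected onto a future stack is never re-normalized.
    """

    layer_names: list[str]
    classes: tuple[str, ...] = ("linear", "quadratic")
    means: np.ndarray = None  # type: ignore[assignment]
    sds: np.ndarray = None  # type: ignore[assignment]
    mins: np.ndarray = None  # type: ignore[assignment]
    maxs: np.ndarray = None  # type: ignore[assignment]
    hinge_knots: int = 4
    categorical: frozenset = frozenset()
    categorical_levels: dict = field(default_factory=dict)

    @classmethod
    def from_env(
        cls,
        env: EnvStack,
        layer_names: list[str] | None = None,
        classes: tuple[str, ...] = ("linear", "quadratic"),
        hinge_knots: int = 4,
        categorical: frozenset = frozenset(),
    ) -> "FeatureSpec":
        names = list(layer_names) if layer_names is not None else env.layer_names
        unknown = set(classes) - set(FEATURE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown feature classes: {sorted(unknown)}")
        if "linear" not in classes:
            raise ValidationError("feature classes must include 'linear'")
        vals = np.column_stack([env.layers[n][env.valid_mask] for n in names])
        means, sds = vals.mean(axis=0), vals.std(axis=0)
        if np.any(sds == 0):
            bad = [n for n, s in zip(names, sds) if s == 0]
            raise ValidationError(f"constant layer(s) {bad} give degenerate normalization")
        levels = {
            n: np.unique(env.layers[n][env.valid_mask]) for n in names if n in categorical
        }
        return cls(
            layer_names=names,
            classes=tuple(classes),
            means=means,
            sds=sds,
            mins=vals.min(axis=0),
            maxs=vals.max(axis=0),
            hinge_knots=hinge_knots,
            categorical=frozenset(categorical),
            categorical_levels=levels,
        )

    def feature_names(self) -> list[str]:
        names = []
        cont = [n for n in self.layer_names if n not in self.categorical]
        names += [f"lin:{n}" for n in cont]
        if "quadratic" in self.classes:
            names += [f"quad:{n}" for n in cont]
        if "product" in self.classes:
            names += [
                f"prod:{a}*{b}"
                for i, a in enumerate(cont)
                for b in cont[i + 1 :]
            ]
        if "hinge" in self.classes:
            for n in cont:
                names += [f"hinge:{n}:{k}" for k in range(self.hinge_knots)]
        for n in self.layer_names:
            if n in self.categorical:
                names += [f"cat:{n}={lv}" for lv in self.categorical_levels[n]]
        return names

    def expand(self, raw: np.ndarray) -> np.ndarray:
        """Expand raw layer values (n, n_layers) into the feature matrix."""
        raw = np.asarray(raw, dtype=float)
        cols = []
        cont_idx = [i for i, n in enumerate(self.layer_names) if n not in self.categorical]
        z = (raw - self.means) / self.sds
        zc = z[:, cont_idx]
        cols.append(zc)
        if "quadratic" in self.classes:
            cols.append(zc**2)
        if "product" in self.classes:
            prods = [
                zc[:, i] * zc[:, j]
                for i in range(zc.shape[1])
                for j in range(i + 1, zc.shape[1])
            ]
            if prods:
                cols.append(np.column_stack(prods))
        if "hinge" in self.classes:
            for i in cont_idx:
                lo, hi = self.mins[i], self.maxs[i]
                knots = np.linspace(lo, hi, self.hinge_knots + 2)[1:-1]
                h = np.maximum(0.0, (raw[:, i][:, None] - knots) / (hi - lo))
                cols.append(h)
        for i, n in enumerate(self.layer_names):
            if n in self.categorical:
                levels = self.categorical_levels[n]
                cols.append((raw[:, i][:, None] == levels).astype(float))
        return np.column_stack(cols)


@dataclass
class SDMModel:
    """Fitted presence-background model for one trait decile."""

    decile: int
    spec: FeatureSpec
    coef: np.ndarray
    intercept: float  # prevalence-adjusted: 0 coefficients -> suitability 0.5
    lam: float
    presence_cells: np.ndarray  # (n, 2) row/col
    background_cells: np.ndarray
    tau10: float | None = None
    train_omission: float | None = None
    n_iter: int = 0


@dataclass
class BinaryMap:
    """Thresholded presence/absence raster for one decile and scenario."""

    grid: GridSpec
    values: np.ndarray  # int {0,1}; invalid cells hold 0 but are masked
    valid_mask: np.ndarray
    decile: int
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec.current)


@dataclass
class EvalReport:
    """Cross-validation summary for one decile model."""

    decile: int
    test_auc_mean: float
    test_auc_sd: float
    train_auc: float
    omission_rate: float
    tau10: float
    n_presence: int
    n_background: int


def sample_background(env: EnvStack, n: int = 10000, seed: int = 0) -> np.ndarray:
    """Uniform sample of valid cells without replacement (all if fewer than n).

    Presence cells are deliberately not excluded (standard presence-background
    convention).
    """
    valid = np.argwhere(env.valid_mask)
    if len(valid) == 0:
        raise ValidationError("environment stack has no valid cells")
    if len(valid) <= n:
        return valid
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(valid), size=n, replace=False)
    return valid[np.sort(idx)]


def _design(env: EnvStack, spec: FeatureSpec, cells: np.ndarray) -> np.ndarray:
    missing = [n for n in spec.layer_names if n not in env.layers]
    if missing:
        raise ValidationError(f"stack is missing model layer(s): {missing}")
    return spec.expand(env.values_at(cells, spec.layer_names))


def fit_sdm(
    presences: PresenceSet,
    background: np.ndarray,
    env: EnvStack,
    spec: FeatureSpec | None = None,
    lam: float = 1.0,
    bg_weight: float = 100.0,
    max_iter: int = 500,
) -> SDMModel:
    """Penalized weighted logistic fit of presences against background.

    Presence weights sum to 1 and background weights to ``bg_weight``
    regardless of sample counts, so duplicating presence rows leaves the fit
    unchanged and the solution approaches the maximum-entropy one as
    ``bg_weight`` grows.
    """
    if presences.n_occ < 2:
        raise ValidationError("need at least 2 presences to fit")
    background = np.asarray(background)
    if len(background) == 0:
        raise ValidationError("background sample is empty")
    spec = spec or FeatureSpec.from_env(env)
    pres_cells = np.asarray(presences.cells)
    X = np.vstack([_design(env, spec, pres_cells), _design(env, spec, background)])
    y = np.r_[np.ones(len(pres_cells)), np.zeros(len(background))]
    w = np.r_[
        np.full(len(pres_cells), 1.0 / len(pres_cells)),
        np.full(len(background), bg_weight / len(background)),
    ]
    clf = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=max_iter, tol=1e-8)
    clf.fit(X, y, sample_weight=w)
    n_iter = int(clf.n_iter_[0])
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"decile {presences.decile}: no convergence in {max_iter} iterations "
            f"(lambda={lam}, n_presence={presences.n_occ}, n_features={X.shape[1]})"
        )
    # remove the class-imbalance term so that zero coefficients -> 0.5
    offset = np.log(1.0 / bg_weight)
    return SDMModel(
        decile=presences.decile,
        spec=spec,
        coef=clf.coef_.ravel(),
        intercept=float(clf.intercept_[0]) - offset,
        lam=lam,
        presence_cells=pres_cells,
        background_cells=background,
        n_iter=n_iter,
    )


def _score_cells(model: SDMModel, env: EnvStack, cells: np.ndarray) -> np.ndarray:
    X = _design(env, model.spec, np.asarray(cells))
    return expit(X @ model.coef + model.intercept)


def predict_suitability(model: SDMModel, env: EnvStack) -> np.ndarray:
    """Suitability raster in (0,1); masked cells are NaN.

    Projection onto a future stack reuses the training normalizers stored in
    the model's :class:`FeatureSpec`, so the output depends only on layer
    values.
    """
    out = np.full(env.grid.shape, np.nan)
    cells = np.argwhere(env.valid_mask)
    out[cells[:, 0], cells[:, 1]] = _score_cells(model, env, cells)
    return out


def compute_auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC with half credit for ties."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValidationError("AUC needs non-empty score lists")
    ranks = rankdata(np.r_[p, b])
    r1 = ranks[: len(p)].sum()
    return float((r1 - len(p) * (len(p) + 1) / 2) / (len(p) * len(b)))


def threshold_10pct(
    model: SDMModel,
    suitability: np.ndarray,
    env: EnvStack,
    percentile: float = 10.0,
    scenario: ScenarioSpec | None = None,
) -> tuple[BinaryMap, float, float]:
    """Binary map under the 10% training-presence threshold rule.

    tau is the largest training-presence suitability whose strictly-below
    fraction of training presences is <= percentile/100, so the training
    omission rate never exceeds that fraction.  Cells with suitability >= tau
    become 1.

    tau is a training-time constant: the first call (on the training stack)
    computes and stores it on the model; later calls — projections onto
    future stacks — reuse the stored threshold and omission rate.
    """
    if len(model.presence_cells) < 1:
        raise ValidationError("model has no training presences")
    if model.tau10 is None:
        scores = _score_cells(model, env, model.presence_cells)
        frac = percentile / 100.0
        tau = None
        for v in np.unique(scores):  # ascending
            if np.mean(scores < v) <= frac:
                tau = float(v)
        assert tau is not None  # the minimum always qualifies
        model.tau10 = tau
        model.train_omission = float(np.mean(scores < tau))
    tau = model.tau10
    omission = model.train_omission
    values = np.where(np.isfinite(suitability) & (suitability >= tau), 1, 0).astype(np.int16)
    bmap = BinaryMap(
        grid=env.grid,
        values=values,
        valid_mask=np.isfinite(suitability),
        decile=model.decile,
        scenario=scenario or ScenarioSpec.current(),
    )
    return bmap, tau, omission


def crossvalidate(
    presences: PresenceSet,
    background: np.ndarray,
    env: EnvStack,
    spec: FeatureSpec | None = None,
    lam: float = 1.0,
    k: int = 5,
    seed: int = 0,
    bg_weight: float = 100.0,
    threshold_percentile: float = 10.0,
) -> tuple[EvalReport, SDMModel]:
    """k-fold CV on presences against the full background, then a final fit.

    Each held-out fold's presences are scored against the entire background
    sample (presence-background test AUC).  The report carries the final
    model's training AUC, threshold and omission rate.
    """
    n = presences.n_occ
    if k > n:
        raise ValidationError(f"k={k} exceeds n_presence={n}")
    spec = spec or FeatureSpec.from_env(env)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    cells = np.asarray(presences.cells)
    ids = list(presences.genotype_ids)
    aucs = []
    for fold in folds:
        train_idx = np.setdiff1d(order, fold)
        train = PresenceSet(
            decile=presences.decile,
            cells=[tuple(c) for c in cells[train_idx]],
            genotype_ids=[ids[i] for i in train_idx],
        )
        m = fit_sdm(train, background, env, spec=spec, lam=lam, bg_weight=bg_weight)
        p_scores = _score_cells(m, env, cells[fold])
        b_scores = _score_cells(m, env, background)
        aucs.append(compute_auc(p_scores, b_scores))
    final = fit_sdm(presences, background, env, spec=spec, lam=lam, bg_weight=bg_weight)
    p_scores = _score_cells(final, env, cells)
    b_scores = _score_cells(final, env, background)
    train_auc = compute_auc(p_scores, b_scores)
    suit = predict_suitability(final, env)
    _, tau, omission = threshold_10pct(final, suit, env, percentile=threshold_percentile)
    report = EvalReport(
        decile=presences.decile,
        test_auc_mean=float(np.mean(aucs)),
        test_auc_sd=float(np.std(aucs, ddof=1)) if k > 1 else 0.0,
        train_auc=train_auc,
        omission_rate=omission,
        tau10=tau,
        n_presence=n,
        n_background=len(background),
    )
    return report, final


def variable_contribution(
    model: SDMModel,
    presences: PresenceSet,
    background: np.ndarray,
    env: EnvStack,
    seed: int = 0,
    n_rep: int = 5,
) -> dict[str, float]:
    """Permutation importance as percent contribution per layer.

    Each layer's raw values are shuffled across the evaluation points
    (presences + background), the training AUC drop is averaged over
    ``n_rep`` shuffles, floored at 0 and normalized to sum to 100.
    """
    rng = np.random.default_rng(seed)
    pres_cells = np.asarray(presences.cells)
    bg = np.asarray(background)
    names = model.spec.layer_names
    raw = np.vstack(
        [env.values_at(pres_cells, names), env.values_at(bg, names)]
    )
    n_p = len(pres_cells)

    def auc_of(raw_matrix: np.ndarray) -> float:
        X = model.spec.expand(raw_matrix)
        s = expit(X @ model.coef + model.intercept)
        return compute_auc(s[:n_p], s[n_p:])

    base = auc_of(raw)
    drops = {}
    for j, name in enumerate(names):
        vals = []
        for _ in range(n_rep):
            perm = raw.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            vals.append(base - auc_of(perm))
        drops[name] = max(0.0, float(np.mean(vals)))
    total = sum(drops.values())
    if total == 0:
        return {name: 0.0 for name in names}
    return {name: 100.0 * v / total for name, v in drops.items()}
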