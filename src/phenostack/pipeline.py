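"""End-to-end orchestration: simulate/load -> deciles -> SDMs -> stacks -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML/JSON)
plus its mandatory master seed; rerunning with the same config reproduces
every output byte-for-byte.  Each stage logs its counts, and every file the
run writes is listed in ``manifest.json`` together with a hash of the
config that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .geodata_io import (
    EnvStack,
    OccurrenceTable,
    ScenarioSpec,
    ValidationError,
    read_env_stack,
    read_occurrences,
    write_raster,
)
from .reporting import change_summary_table, evaluation_table, gcm_mean_ci
from .sdm_engine import (
    BinaryMap,
    FeatureSpec,
    crossvalidate,
    predict_suitability,
    sample_background,
    threshold_10pct,
    variable_contribution,
)
from .stacked_richness import (
    RichnessMap,
    richness_change,
    stack,
    summarize_change,
    tail_frequency,
)
from .synthetic import SyntheticConfig, default_scenarios, substream
from .trait_communities import (
    build_community_matrix,
    rda,
    scenario_similarity,
    select_constraints,
)
from .trait_deciles import assign_deciles, presences_to_frame, thin_presences

__all__ = ["RunConfig", "PipelineResult", "validate_config", "load_config", "run_pipeline"]

log = logging.getLogger("phenostack")

_CSV_FLOAT = "%.6f"


@dataclass
class RunConfig:
    seed: int
    mode: str = "synthetic"
    synthetic: SyntheticConfig | None = None
    #: user-data mode: raster paths per scenario label and occurrence CSV
    env_paths: dict = field(default_factory=dict)
    layer_names: list = field(default_factory=lambda: list(synthetic.SyntheticConfig().gradients) + ["stream_order"])
    occurrences_path: str | None = None
    decile_count: int = 10
    background_n: int = 10000
    lam: float = 1.0
    feature_classes: tuple = ("linear", "quadratic")
    k_folds: int = 5
    threshold_percentile: float = 10.0
    scenarios: list = field(default_factory=default_scenarios)
    denominator_rule: str = "all-valid"
    n_permutations: int = 999
    selection_permutations: int = 199
    outdir: str = "phenostack_out"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.decile_count < 2:
            raise ValidationError("decile count must be >= 2")
        if not 0 < self.threshold_percentile < 50:
            raise ValidationError("threshold percentile must lie in (0, 50)")
        if not any(s.is_current for s in self.scenarios):
            raise ValidationError("scenario list must include the current baseline")
        if self.mode == "synthetic" and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_SYN_KEYS = {f.name for f in dataclasses.fields(SyntheticConfig)}


def validate_config(raw: dict) -> RunConfig:
    """Build a RunConfig from a parsed config mapping.

    Unknown keys are rejected with their paths; the master seed is mandatory.
    """
    raw = dict(raw)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ValidationError("config must set 'seed' (runs must be reproducible)")
    if "synthetic" in raw and isinstance(raw["synthetic"], dict):
        syn = dict(raw["synthetic"])
        unknown = set(syn) - _SYN_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {[f'synthetic.{k}' for k in sorted(unknown)]}")
        syn.setdefault("seed", raw["seed"])
        for key in ("pop_sizes", "pop_offsets"):
            if key in syn:
                syn[key] = tuple(syn[key])
        raw["synthetic"] = SyntheticConfig(**syn)
    if "scenarios" in raw:
        raw["scenarios"] = [
            s if isinstance(s, ScenarioSpec) else ScenarioSpec(**{k: str(v) for k, v in s.items()})
            for s in raw["scenarios"]
        ]
    if "feature_classes" in raw:
        raw["feature_classes"] = tuple(raw["feature_classes"])
    return RunConfig(**raw)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    return validate_config(raw)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["scenarios"] = [dataclasses.asdict(s) for s in cfg.scenarios]
    return d


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(_config_dict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to everything a run computed."""

    config: RunConfig
    occurrences: OccurrenceTable
    presences: list
    reports: list
    models: list
    binaries: dict  # scenario label -> list[BinaryMap]
    richness: dict  # scenario label -> RichnessMap
    summaries: list
    community: object
    similarity: list
    ordination: object
    selected_constraints: list
    contributions: dict
    tail: pd.DataFrame
    extents: dict
    env_current: EnvStack
    manifest: dict


def _load_user_env(cfg: RunConfig, label: str) -> EnvStack:
    paths = cfg.env_paths[label]
    return read_env_stack([paths[n] for n in cfg.layer_names], cfg.layer_names)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to cfg.outdir."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    (outdir / "rasters").mkdir(parents=True, exist_ok=True)
    (outdir / "tables").mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save_raster(arr, grid, name):
        path = outdir / "rasters" / f"{name}.asc"
        write_raster(arr, grid, path)
        written.append(str(path.relative_to(outdir)))

    def save_table(df: pd.DataFrame, name):
        path = outdir / "tables" / f"{name}.csv"
        df.to_csv(path, index=False, float_format=_CSV_FLOAT)
        written.append(str(path.relative_to(outdir)))

    # --- stage 1: environment + occurrences -------------------------------
    scen_by_label = {s.label: s for s in cfg.scenarios}
    if cfg.mode == "synthetic":
        syn = cfg.synthetic
        env = {lbl: synthetic.simulate_environment(syn, s) for lbl, s in scen_by_label.items()}
        occ = synthetic.simulate_populations(env["current"], syn)
    else:
        env = {lbl: _load_user_env(cfg, lbl) for lbl in scen_by_label}
        occ = read_occurrences(cfg.occurrences_path)
    env_cur = env["current"]
    grid = env_cur.grid
    log.info("stage=environment scenarios=%d valid_cells=%d", len(env), int(env_cur.valid_mask.sum()))
    log.info("stage=occurrences n=%d", len(occ))
    occ.to_csv(outdir / "tables" / "occurrences.csv")
    written.append("tables/occurrences.csv")

    # --- stage 2: deciles + thinning --------------------------------------
    assign = assign_deciles(occ, n_bins=cfg.decile_count)
    presences = thin_presences(assign, occ, grid)
    n_dropped = len(occ) - sum(p.n_occ for p in presences)
    log.info("stage=thinning kept=%d dropped_same_cell=%d", sum(p.n_occ for p in presences), n_dropped)
    save_table(presences_to_frame(presences, occ, grid), "presences")

    # --- stage 3: fit + cross-validate per decile --------------------------
    bg_seed = int(substream(cfg.seed, "background").integers(2**31))
    background = sample_background(env_cur, n=cfg.background_n, seed=bg_seed)
    spec = FeatureSpec.from_env(env_cur, classes=cfg.feature_classes)
    reports, models = [], []
    for ps in presences:
        cv_seed = int(substream(cfg.seed, f"cv-{ps.decile}").integers(2**31))
        rep, model = crossvalidate(
            ps, background, env_cur, spec=spec, lam=cfg.lam, k=cfg.k_folds,
            seed=cv_seed, threshold_percentile=cfg.threshold_percentile,
        )
        reports.append(rep)
        models.append(model)
        log.info(
            "stage=fit decile=%d n_occ=%d test_auc=%.3f train_auc=%.3f omission=%.3f",
            ps.decile, ps.n_occ, rep.test_auc_mean, rep.train_auc, rep.omission_rate,
        )

    contributions = {}
    for ps, model in zip(presences, models):
        vc_seed = int(substream(cfg.seed, f"contrib-{ps.decile}").integers(2**31))
        contributions[ps.decile] = variable_contribution(
            model, ps, background, env_cur, seed=vc_seed
        )
    save_table(
        pd.DataFrame(
            [{"decile": d, **c} for d, c in sorted(contributions.items())]
        ),
        "variable_contribution",
    )

    # --- stage 4: project + threshold + stack every scenario ---------------
    binaries: dict[str, list[BinaryMap]] = {}
    richness: dict[str, RichnessMap] = {}
    for lbl, scen in scen_by_label.items():
        maps = []
        for model in models:
            suit = predict_suitability(model, env[lbl])
            if lbl == "current":
                save_raster(suit, grid, f"suitability_current_D{model.decile}")
            bmap, _, _ = threshold_10pct(
                model, suit, env[lbl], percentile=cfg.threshold_percentile, scenario=scen
            )
            maps.append(bmap)
            save_raster(bmap.values, grid, f"binary_{lbl}_D{model.decile}")
        binaries[lbl] = maps
        richness[lbl] = stack(maps, expected_n=cfg.decile_count)
        save_raster(richness[lbl].values, grid, f"richness_{lbl}")
    log.info("stage=stacking maps=%d", sum(len(v) for v in binaries.values()))

    # --- stage 5: change summaries per extent ------------------------------
    extents = {"species_range": env_cur.valid_mask.copy()}
    row_range = cfg.synthetic.pop_row_range if cfg.synthetic else (0.0, 1.0)
    extents.update(synthetic.population_band_masks(grid, row_range))
    summaries = []
    for lbl, scen in scen_by_label.items():
        if scen.is_current:
            continue
        chg = richness_change(richness["current"], richness[lbl])
        save_raster(chg.delta, grid, f"change_{lbl}")
        for extent_label, mask in extents.items():
            for rule in ("all-valid", "suitable-only"):
                summaries.append(
                    summarize_change(chg, mask, denominator_rule=rule, extent_label=extent_label)
                )
    save_table(change_summary_table(summaries), "change_summary")

    # --- stage 6: tail frequencies -----------------------------------------
    tail_rows = []
    for lbl in scen_by_label:
        for extent_label, mask in extents.items():
            freqs = tail_frequency(binaries[lbl], richness[lbl], mask)
            tail_rows.append(
                {"scenario": lbl, "extent": extent_label,
                 "decile1": freqs[1], "decile10": freqs[10]}
            )
    tail = pd.DataFrame(tail_rows)
    save_table(tail, "tail_frequency")

    # --- stage 7: communities, similarity, ordination ----------------------
    pop_extents = {p: extents[p] for p in ("southern", "central", "northern")}
    community = build_community_matrix(binaries, pop_extents, scenarios=scen_by_label)
    save_table(community.to_long(), "community_matrix")
    similarity = scenario_similarity(community)
    save_table(
        pd.DataFrame(
            [
                {"population": s.population, "scenario": s.scenario,
                 "similarity": s.value, "baseline_delta": s.baseline_delta}
                for s in similarity
            ]
        ),
        "similarity",
    )

    meta = community.counts.index.to_frame(index=False)
    scen_meta = meta["scenario"].map(scen_by_label)
    constraints = pd.DataFrame(
        {
            "population": meta["population"],
            "gcm": [s.gcm for s in scen_meta],
            "rcp": [s.rcp for s in scen_meta],
            "period": [s.period for s in scen_meta],
        }
    )
    rda_seed = int(substream(cfg.seed, "rda").integers(2**31))
    ordination = rda(
        community, constraints[["population"]], n_perm=cfg.n_permutations, seed=rda_seed
    )
    sel_seed = int(substream(cfg.seed, "selection").integers(2**31))
    selected = select_constraints(
        community, constraints, n_perm=cfg.selection_permutations, seed=sel_seed
    )
    full = rda(community, constraints[selected], n_perm=cfg.n_permutations, seed=rda_seed) if selected else None
    log.info(
        "stage=ordination population_fraction=%.3f p=%.4f selected=%s",
        ordination.constrained_fraction, ordination.p_value, selected,
    )
    ord_report = {
        "population_fraction": ordination.constrained_fraction,
        "population_p": ordination.p_value,
        "marginal_fractions": ordination.marginal_fractions,
        "selected_constraints": selected,
        "selected_fraction": full.constrained_fraction if full else None,
        "selected_p": full.p_value if full else None,
    }
    with open(outdir / "ordination.json", "w") as fh:
        json.dump(ord_report, fh, indent=2, sort_keys=True)
    written.append("ordination.json")

    # evaluation table last: includes current-scenario pixel counts
    save_table(evaluation_table(reports, binaries["current"]), "evaluation")

    manifest = {
        "config": _config_dict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "outputs": {name: _config_hash(cfg) for name in sorted(written)},
        "n_distribution_maps": sum(len(v) for v in binaries.values()),
    }
    log.info("stage=done runtime_s=%.1f", time.time() - t0)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return PipelineResult(
        config=cfg,
        occurrences=occ,
        presences=presences,
        reports=reports,
        models=models,
        binaries=binaries,
        richness=richness,
        summaries=summaries,
        community=community,
        similarity=similarity,
        ordination=ordination,
        selected_constraints=selected,
        contributions=contributions,
        tail=tail,
        extents=extents,
        env_current=env_cur,
        manifest=manifest,
    )


def gcm_average_net_loss(summaries, extent: str, rcp: str, period: str,
                         denominator_rule: str = "all-valid") -> tuple[float, float, float]:
    """Mean net loss (+/- CI) across GCMs for one extent x RCP x period."""
    vals = [
        s.net_loss
        for s in summaries
        if s.extent == extent
        and s.scenario.rcp == rcp
        and s.scenario.period == period
        and s.denominator_rule == denominator_rule
    ]
    if not vals:
        raise ValidationError(f"no summaries for {extent}/{rcp}/{period}")
    return gcm_mean_ci(vals)
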