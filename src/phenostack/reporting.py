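"""Tabular reporting: evaluation tables, AUC summaries, GCM means.

These are the arithmetic layers behind the published-style summary tables:
per-decile evaluation rows (occurrences, suitable pixels, % area, AUCs,
omission), the mean test AUC across the ten decile models, and the
mean +/- normal-theory 95% CI across the three GCMs of a scenario.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .sdm_engine import BinaryMap, EvalReport
from .stacked_richness import ChangeSummary, percent_area

__all__ = [
    "mean_test_auc",
    "evaluation_table",
    "change_summary_table",
    "gcm_mean_ci",
]


def mean_test_auc(test_aucs, decimals: int = 2) -> float:
    """Mean of per-decile test AUCs, rounded half-up."""
    m = Decimal(repr(float(np.mean(np.asarray(test_aucs, dtype=float)))))
    return float(m.quantize(Decimal(10) ** -decimals, rounding=ROUND_HALF_UP))


def evaluation_table(
    reports: list[EvalReport],
    binaries: list[BinaryMap] | None = None,
    total_pixels: int | None = None,
) -> pd.DataFrame:
    """Per-decile evaluation summary (one row per decile, plus % area).

    When binary maps are supplied, "pixels" counts suitable cells and
    "percent_area" relates them to ``total_pixels`` (default: valid cells).
    """
    by_decile = {b.decile: b for b in (binaries or [])}
    rows = []
    for rep in sorted(reports, key=lambda r: r.decile):
        row = {
            "decile": rep.decile,
            "n_occ": rep.n_presence,
            "test_auc": rep.test_auc_mean,
            "test_auc_sd": rep.test_auc_sd,
            "train_auc": rep.train_auc,
            "omission_rate": rep.omission_rate,
            "tau10": rep.tau10,
        }
        b = by_decile.get(rep.decile)
        if b is not None:
            pixels = int((b.values == 1).sum())
            total = total_pixels if total_pixels is not None else int(b.valid_mask.sum())
            row["pixels"] = pixels
            row["percent_area"] = percent_area(pixels, total)
        rows.append(row)
    return pd.DataFrame(rows)


def change_summary_table(summaries: list[ChangeSummary]) -> pd.DataFrame:
    """Flatten change summaries into a CSV-ready table with delta columns."""
    rows = []
    for s in summaries:
        row = {
            "extent": s.extent,
            "gcm": s.scenario.gcm,
            "rcp": s.scenario.rcp,
            "period": s.scenario.period,
            "denominator_rule": s.denominator_rule,
            "denominator": s.denominator,
            "percent_loss": s.percent_loss,
            "percent_gain": s.percent_gain,
            "net_loss": s.net_loss,
        }
        for d in range(-10, 11):
            if d == 0:
                continue
            row[f"delta_{d}"] = s.histogram.get(d, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def gcm_mean_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and normal-theory CI of per-GCM values (approximate by design).

    Returns (mean, lower, upper).  With the usual three GCMs the interval is
    mean +/- z * sd/sqrt(n); it summarizes between-GCM spread only.
    """
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if len(v) < 2:
        return m, m, m
    z = stats.norm.ppf(0.5 + confidence / 2)
    half = z * v.std(ddof=1) / np.sqrt(len(v))
    return m, m - half, m + half
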