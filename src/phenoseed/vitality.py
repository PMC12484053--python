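"""Dual-index growth-vitality evaluation.

Static vitality is the mean seedling length of a treatment group (accumulated
growth); dynamic vitality is the slope of the length-versus-time linear fit
(elongation rate). Both are max-normalised "under equivalent conditions" and
combined with equal 0.5 weights into a comprehensive score, which is then
averaged per nano-iron level and expressed as a percentage share of the sum
across levels.

Two normalisation strategies are provided because the aggregation is a
genuine modelling choice: ``per-salt`` (each salt level has its own maxima;
the default) and ``global`` (one set of maxima pooled over all cells).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import TreatmentDesign

__all__ = [
    "fit_growth_rate",
    "static_vitality",
    "comprehensive_scores",
    "vitality_report",
]


def fit_growth_rate(t_min, length_cm) -> tuple[float, float]:
    """OLS line of length on time; slope in cm/h, intercept in cm."""
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(length_cm, dtype=float)
    if t.size != y.size or t.size < 2:
        raise ValueError("need at least 2 time points")
    if np.ptp(t) == 0:
        raise ValueError("all time points identical; slope undefined")
    slope_per_min, intercept = np.polyfit(t, y, 1)
    return float(slope_per_min * 60.0), float(intercept)


def static_vitality(length_cm) -> float:
    """Arithmetic mean seedling length in cm."""
    y = np.asarray(length_cm, dtype=float)
    if y.size == 0:
        raise ValueError("empty series")
    return float(y.mean())


def _cell_table(series: pd.DataFrame, design: TreatmentDesign) -> pd.DataFrame:
    """Per-(salt, fe) static and dynamic vitality from a long series table."""
    rows = []
    for salt in design.salt_levels_mmolL:
        for fe in design.fe_levels_mgL:
            cell = series[(series["salt_mmolL"] == salt) & (series["fe_mgL"] == fe)]
            if cell.empty:
                raise ValueError(f"missing series for cell (salt={salt}, fe={fe})")
            slope, _ = fit_growth_rate(cell["t_min"], cell["length_cm"])
            rows.append(
                {
                    "salt_mmolL": salt,
                    "fe_mgL": fe,
                    "static_cm": static_vitality(cell["length_cm"]),
                    "dynamic_cm_per_h": slope,
                }
            )
    return pd.DataFrame(rows)


def comprehensive_scores(
    cells: pd.DataFrame,
    strategy: str = "per-salt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise, weight and aggregate vitality scores.

    ``cells`` needs one row per (salt, fe) cell with columns ``salt_mmolL``,
    ``fe_mgL``, ``static_cm`` and ``dynamic_cm_per_h``. Negative slopes are
    floored at zero before normalisation (shrinking groups carry no dynamic
    vitality rather than negative vitality). Within each normalisation block
    both indicators are divided by their block maximum, combined with equal
    0.5 weights, averaged per fe level, and converted to percentage shares.

    Returns ``(cell_scores, fe_scores)``.
    """
    if strategy not in ("per-salt", "global"):
        raise ValueError("strategy must be 'per-salt' or 'global'")
    df = cells.copy()
    dup = df.duplicated(subset=["salt_mmolL", "fe_mgL"])
    if dup.any():
        raise ValueError("duplicate (salt, fe) cells")
    df["dynamic_floored"] = df["dynamic_cm_per_h"].clip(lower=0.0)

    blocks = df.groupby("salt_mmolL") if strategy == "per-salt" else [(None, df)]
    scored = []
    for salt, block in blocks:
        max_static = block["static_cm"].max()
        max_dynamic = block["dynamic_floored"].max()
        if max_static <= 0 or max_dynamic <= 0:
            warnings.warn(
                f"salt level {salt} has a zero indicator maximum; excluded",
                stacklevel=2,
            )
            continue
        b = block.copy()
        b["norm_static"] = b["static_cm"] / max_static
        b["norm_dynamic"] = b["dynamic_floored"] / max_dynamic
        b["comprehensive"] = 0.5 * b["norm_static"] + 0.5 * b["norm_dynamic"]
        scored.append(b)
    if not scored:
        raise ValueError("no salt level with positive indicator maxima")
    cell_scores = pd.concat(scored, ignore_index=True).drop(columns="dynamic_floored")
    cell_scores = cell_scores.sort_values(["salt_mmolL", "fe_mgL"]).reset_index(drop=True)

    fe_scores = (
        cell_scores.groupby("fe_mgL", as_index=False)["comprehensive"]
        .mean()
        .rename(columns={"comprehensive": "score"})
    )
    fe_scores["share_pct"] = 100.0 * fe_scores["score"] / fe_scores["score"].sum()
    fe_scores["rank"] = (
        fe_scores["share_pct"].rank(ascending=False, method="min").astype(int)
    )
    fe_scores = fe_scores.sort_values("rank").reset_index(drop=True)
    return cell_scores, fe_scores


def vitality_report(
    series: pd.DataFrame,
    design: TreatmentDesign,
    strategy: str = "per-salt",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-cell and per-fe-level vitality tables from a series table.

    ``series`` is long-format with columns ``salt_mmolL, fe_mgL, t_min,
    length_cm`` (replicates, if present, are pooled into the cell fit).
    Deterministic given its input: rows are sorted, never order-dependent.
    """
    cells = _cell_table(series, design)
    return comprehensive_scores(cells, strategy=strategy)
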