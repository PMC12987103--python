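"""Pearson correlation screening and feature-group assembly.

The pipeline's variable filtering works on the per-stage sample table
(48 samples): vegetation indices with |r| > 0.5 against plant nitrogen
content, keeping at most the top three; one texture index per family
(NDTI/RTI/RDTI) with |r| > 0.5 and maximal |r|; and the fused group is
the concatenation of both.  Significance tiers follow the usual
0.05 / 0.01 / 0.001 convention (* / ** / ***).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def pearson_r(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p and n over pairwise-complete observations.

    r follows the product-moment definition
    ``Σ(xi−x̄)(yi−ȳ) / √(Σ(xi−x̄)² Σ(yi−ȳ)²)``; the p-value uses the
    exact t transform ``t = r √((n−2)/(1−r²))`` with n−2 degrees of
    freedom.  A constant series yields NaN r with a logged warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    den = np.sqrt((dx @ dx) * (dy @ dy))
    if den == 0.0:
        log.warning("constant series: Pearson r undefined")
        return float("nan"), float("nan"), n
    r = float(np.clip((dx @ dy) / den, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(t, n - 2))
    return r, p, n


def significance_tier(p: float) -> str:
    """Stars for p < 0.05 (*), < 0.01 (**), < 0.001 (***)."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate_features(
    table: pd.DataFrame,
    feature_columns: Sequence[str],
    target: str = "PNC",
) -> pd.DataFrame:
    """Per-feature correlation report: feature, r, p, n, tier."""
    rows = []
    y = table[target]
    for col in feature_columns:
        try:
            r, p, n = pearson_r(table[col], y)
        except ValueError:
            r, p, n = float("nan"), float("nan"), 0
        rows.append({
            "feature": col, "r": r, "p": p, "n": n,
            "tier": significance_tier(p),
        })
    return pd.DataFrame(rows)


def select_vis(
    vi_correlations: pd.DataFrame,
    threshold: float = 0.5,
    top: int = 3,
) -> list[str]:
    """Vegetation indices with |r| > threshold, top ``top`` by |r|.

    Deterministic tie-break by feature name.  May return fewer than
    ``top`` names (logged) when few indices clear the threshold.
    """
    sub = vi_correlations[vi_correlations["r"].notna()].copy()
    sub["abs_r"] = sub["r"].abs()
    sub = sub[sub["abs_r"] > threshold]
    sub = sub.sort_values(
        by=["abs_r", "feature"], ascending=[False, True], kind="mergesort"
    )
    chosen = sub["feature"].head(top).tolist()
    if len(chosen) < top:
        log.info("only %d vegetation indices passed |r| > %g", len(chosen), threshold)
    return chosen


def select_tis(
    catalog: pd.DataFrame,
    threshold: float = 0.5,
) -> list[tuple[str, str, str]]:
    """Best (family, t1, t2) per texture-index family with |r| > threshold."""
    from .tindex import FAMILIES, best_per_family

    best = best_per_family(catalog, threshold=threshold)
    out = []
    for family in FAMILIES:
        row = best[family]
        if row is not None:
            out.append((family, str(row["t1"]), str(row["t2"])))
    return out


def assemble_feature_sets(
    selected_vis: Sequence[str],
    selected_tis: Sequence[str],
) -> dict[str, list[str]]:
    """The three model input groups: VIs, TIs and their concatenation."""
    vis = list(selected_vis)
    tis = list(selected_tis)
    fused = vis + tis
    if len(set(fused)) != len(fused):
        raise ValueError("duplicate feature names across groups")
    return {"VIs": vis, "TIs": tis, "VIs+TIs": fused}


def relative_improvement(new: float, base: float) -> float:
    """(new − base)/base × 100; the pipeline's standard comparison."""
    if base == 0:
        raise ZeroDivisionError("relative improvement undefined for zero base")
    return (new - base) / base * 100.0


def summarize_tfv_vs_ti(
    tfv_correlations: pd.DataFrame,
    best_tis: pd.DataFrame | Sequence[Mapping],
) -> dict[str, float]:
    """Mean |r| of raw texture features vs. the selected texture indices.

    Quantifies how much pairwise index construction strengthens the
    texture–nitrogen relationship, as the percentage gain of the mean
    |r| of the best per-family indices over the mean |r| of all raw
    texture features.
    """
    tfv_abs = tfv_correlations["r"].abs().dropna()
    if tfv_abs.empty:
        raise ValueError("no raw texture-feature correlations given")
    ti_frame = pd.DataFrame(best_tis)
    ti_abs = ti_frame["r"].abs().dropna()
    if ti_abs.empty:
        raise ValueError("no selected texture indices given")
    mean_tfv = float(tfv_abs.mean())
    mean_ti = float(ti_abs.mean())
    if mean_tfv == 0:
        log.warning("mean raw-texture |r| is zero; improvement undefined")
        return {"mean_tfv_abs_r": 0.0, "mean_ti_abs_r": mean_ti,
                "relative_improvement_pct": float("nan")}
    return {
        "mean_tfv_abs_r": mean_tfv,
        "mean_ti_abs_r": mean_ti,
        "relative_improvement_pct": relative_improvement(mean_ti, mean_tfv),
    }
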