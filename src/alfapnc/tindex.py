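"""Texture indices: pairwise combinations of texture features.

Three index families combine any two of the 48 texture feature values
(T1, T2):

* NDTI — normalized difference, (T1 − T2)/(T1 + T2)
* RTI  — ratio, T1/T2
* RDTI — renormalized difference, (T1 − T2)/√(T1 + T2)

All ordered pairs (including self-pairs) are enumerated, giving 48² =
2304 candidates per family; self-pairs produce constant series (NDTI =
0, RTI = 1) and are therefore excluded from ranking.  Screening ranks
candidates by the absolute Pearson correlation of the index with plant
nitrogen content across samples.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

FAMILIES: tuple[str, ...] = ("NDTI", "RTI", "RDTI")

_EPS = 1e-9


def ndti(t1, t2):
    """Normalized difference texture index; NaN on |T1+T2| ≈ 0."""
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    den = t1 + t2
    bad = np.abs(den) < _EPS
    out = np.where(bad, np.nan, (t1 - t2) / np.where(bad, 1.0, den))
    return out if out.ndim else float(out)


def rti(t1, t2):
    """Ratio texture index; NaN on |T2| ≈ 0."""
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    bad = np.abs(t2) < _EPS
    out = np.where(bad, np.nan, t1 / np.where(bad, 1.0, t2))
    return out if out.ndim else float(out)


def rdti(t1, t2):
    """Renormalized difference texture index; NaN when T1+T2 ≤ 0."""
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    den = t1 + t2
    bad = den < _EPS
    out = np.where(bad, np.nan, (t1 - t2) / np.sqrt(np.where(bad, 1.0, den)))
    return out if out.ndim else float(out)


TI_FUNCTIONS = {"NDTI": ndti, "RTI": rti, "RDTI": rdti}


def compute_ti(family: str, t1, t2):
    return TI_FUNCTIONS[family](t1, t2)


def enumerate_pairs(tfv_names: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered (T1, T2) pairs, self-pairs included: n² combinations."""
    if len(tfv_names) < 2:
        raise ValueError("need at least two texture-feature names")
    return list(itertools.product(tfv_names, repeat=2))


def _pairwise_corr_with(y: np.ndarray, ti: np.ndarray):
    """Pearson r/p/n of each candidate series in ``ti`` (n, k, k) with y."""
    valid = np.isfinite(ti) & np.isfinite(y)[:, None, None]
    n = valid.sum(axis=0).astype(np.float64)
    tv = np.where(valid, ti, 0.0)
    yv = np.where(valid, y[:, None, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_n = np.where(n > 0, n, 1.0)
        mt = tv.sum(axis=0) / safe_n
        my = yv.sum(axis=0) / safe_n
        dt = np.where(valid, ti - mt[None], 0.0)
        dy = np.where(valid, y[:, None, None] - my[None], 0.0)
        sxx = (dt * dt).sum(axis=0)
        syy = (dy * dy).sum(axis=0)
        sxy = (dt * dy).sum(axis=0)
        den = np.sqrt(sxx * syy)
        r = np.where(den > 0, sxy / np.where(den > 0, den, 1.0), np.nan)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        t = np.abs(r) * np.sqrt(np.where(df > 0, df, 1.0) / np.maximum(1.0 - r * r, 1e-300))
        p = np.where(
            (df > 0) & np.isfinite(r),
            2.0 * stats.t.sf(t, np.where(df > 0, df, 1.0)),
            np.nan,
        )
    r = np.where(n >= 3, r, np.nan)
    return r, p, n.astype(int)


def screen_tis(
    tfv_table: pd.DataFrame,
    pnc_column: str = "PNC",
    tfv_columns: Sequence[str] | None = None,
    families: Sequence[str] = FAMILIES,
    min_n: int = 10,
) -> pd.DataFrame:
    """Correlation catalog of every texture-index candidate against PNC.

    Returns a DataFrame with columns family, t1, t2, r, p, n, one row
    per ordered pair per family.  Correlations are pairwise-complete;
    constant candidates (e.g. self-pairs) have NaN r.  Ranking helpers
    drop NaN r and candidates with fewer than ``min_n`` complete rows.
    """
    if tfv_columns is None:
        from .glcm import tfv_names

        tfv_columns = [c for c in tfv_names() if c in tfv_table.columns]
    if len(tfv_columns) < 2:
        raise ValueError("need at least two TFV columns to screen")
    X = tfv_table[list(tfv_columns)].to_numpy(dtype=np.float64)
    y = tfv_table[pnc_column].to_numpy(dtype=np.float64)
    k = X.shape[1]
    t1 = X[:, :, None]
    t2 = X[:, None, :]
    frames = []
    names = np.array(tfv_columns)
    for family in families:
        ti = TI_FUNCTIONS[family](t1, t2)
        r, p, n = _pairwise_corr_with(y, ti)
        idx1, idx2 = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        frames.append(pd.DataFrame({
            "family": family,
            "t1": names[idx1.ravel()],
            "t2": names[idx2.ravel()],
            "r": r.ravel(),
            "p": p.ravel(),
            "n": n.ravel(),
        }))
    catalog = pd.concat(frames, ignore_index=True)
    catalog.loc[catalog["n"] < min_n, "r"] = np.nan
    if catalog["r"].isna().all():
        log.warning("all texture-index candidates are constant or unusable")
    return catalog


def rank_family(catalog: pd.DataFrame, family: str) -> pd.DataFrame:
    """Usable candidates of one family sorted by |r| (desc), ties by name."""
    sub = catalog[(catalog["family"] == family) & catalog["r"].notna()].copy()
    sub["abs_r"] = sub["r"].abs()
    sub = sub.sort_values(
        by=["abs_r", "family", "t1", "t2"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return sub


def best_per_family(
    catalog: pd.DataFrame,
    threshold: float = 0.5,
    families: Sequence[str] = FAMILIES,
) -> dict[str, pd.Series | None]:
    """Highest-|r| candidate per family, subject to |r| > threshold."""
    out: dict[str, pd.Series | None] = {}
    for family in families:
        ranked = rank_family(catalog, family)
        ranked = ranked[ranked["abs_r"] > threshold]
        out[family] = None if ranked.empty else ranked.iloc[0]
        if out[family] is None:
            log.warning("family %s: no candidate with |r| > %g", family, threshold)
    return out


def ti_heatmap(catalog: pd.DataFrame, family: str) -> pd.DataFrame:
    """48×48 matrix of r indexed (t1 rows, t2 columns) in band-major order."""
    from .glcm import tfv_names

    sub = catalog[catalog["family"] == family]
    order = [c for c in tfv_names() if c in set(sub["t1"])]
    mat = sub.pivot(index="t1", columns="t2", values="r")
    return mat.reindex(index=order, columns=order)


def plot_ti_heatmap(catalog: pd.DataFrame, family: str, path=None, ax=None):
    """Render one family's 48×48 correlation matrix as a heatmap.

    Axes are ticked per band (8 features each) in band-major order;
    returns the matplotlib Axes.  ``path`` saves the figure.
    """
    import matplotlib
    import matplotlib.pyplot as plt

    mat = ti_heatmap(catalog, family)
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1, vmax=1)
    ticks = np.arange(4, 48, 8)
    bands = [n.split("_")[0] for n in mat.index[ticks]]
    ax.set_xticks(ticks, bands)
    ax.set_yticks(ticks, bands)
    ax.set_xlabel("T2")
    ax.set_ylabel("T1")
    ax.set_title(f"{family} vs PNC (Pearson r)")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def ti_feature_name(family: str, t1: str, t2: str) -> str:
    return f"{family}({t1},{t2})"


def parse_ti_feature_name(name: str) -> tuple[str, str, str] | None:
    """Inverse of :func:`ti_feature_name`; None if not a TI feature name."""
    for family in FAMILIES:
        prefix = family + "("
        if name.startswith(prefix) and name.endswith(")"):
            inner = name[len(prefix):-1]
            parts = inner.split(",")
            if len(parts) == 2:
                return family, parts[0], parts[1]
    return None


def add_ti_columns(
    table: pd.DataFrame,
    selections: Sequence[tuple[str, str, str]],
) -> pd.DataFrame:
    """Append selected texture-index columns computed from TFV columns."""
    out = table.copy()
    for family, t1, t2 in selections:
        out[ti_feature_name(family, t1, t2)] = compute_ti(
            family, table[t1].to_numpy(float), table[t2].to_numpy(float)
        )
    return out
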