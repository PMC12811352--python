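"""Along-track habitat extraction and 2-h interval summarisation.

To capture the dominant habitat experienced during each 2-h interval rather
than the value under the interval midpoint alone, the original fix series is
densified to 1-min spacing by piecewise-linear interpolation, habitat layers
are looked up at every dense point, and the points falling within each
interval are summarised: median for the continuous stratification field
(PEA), mode for the categorical layers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import SeascapeGrid

__all__ = ["interpolate_1min", "summarize_intervals", "extract_habitat"]


def interpolate_1min(fixes: pd.DataFrame) -> pd.DataFrame:
    """Densify each individual's fix series to 1-min spacing.

    Points run from the first to the last fix; each timestamp appears once
    (fix times that fall on the 1-min grid are not duplicated). An
    individual with fewer than two fixes yields no points (with a warning).
    """
    out = []
    for ind, f in fixes.groupby("individual", sort=True):
        f = f.sort_values("timestamp")
        if len(f) < 2:
            warnings.warn(f"individual {ind} has fewer than two fixes; skipped")
            continue
        ft = pd.to_datetime(f["timestamp"])
        t0, t1 = ft.iloc[0], ft.iloc[-1]
        times = pd.date_range(t0.ceil("min"), t1.floor("min"), freq="min")
        times = times.union(pd.DatetimeIndex([t0, t1]))
        ts = times.astype("int64").to_numpy() / 1e9
        fts = ft.astype("int64").to_numpy() / 1e9
        out.append(pd.DataFrame({
            "individual": ind,
            "timestamp": times,
            "x": np.interp(ts, fts, f["x_km"].to_numpy()),
            "y": np.interp(ts, fts, f["y_km"].to_numpy()),
        }))
    if not out:
        return pd.DataFrame(columns=["individual", "timestamp", "x", "y"])
    return pd.concat(out, ignore_index=True)


def _mode_earliest(values) -> object:
    """Most frequent value; ties broken by earliest occurrence in the interval."""
    counts = {}
    order = {}
    for i, v in enumerate(values):
        if pd.isna(v):
            continue
        counts[v] = counts.get(v, 0) + 1
        order.setdefault(v, i)
    if not counts:
        return pd.NA
    best = max(counts, key=lambda v: (counts[v], -order[v]))
    return best


def summarize_intervals(points: pd.DataFrame, intervals: pd.DataFrame,
                        categorical=("geomorphology", "substrate", "region"),
                        continuous=("pea",)) -> pd.DataFrame:
    """Summarise dense habitat points into the 2-h intervals.

    ``points`` must carry habitat columns; ``intervals`` must carry
    ``individual`` and ``midpoint``. Membership is half-open
    ``[midpoint - 1 h, midpoint + 1 h)``. Intervals whose points all lack
    habitat data are flagged ``missing_covariates``.
    """
    out = intervals.copy()
    for col in categorical:
        out[col] = pd.NA
    for col in continuous:
        out[col] = np.nan
    out["missing_covariates"] = True
    for ind, iv in intervals.groupby("individual", sort=True):
        p = points[points["individual"] == ind]
        if not len(p):
            continue
        pt = pd.to_datetime(p["timestamp"]).to_numpy()
        mids = pd.to_datetime(iv["midpoint"]).to_numpy()
        for row, mid in zip(iv.index, mids):
            lo = mid - np.timedelta64(3600, "s")
            hi = mid + np.timedelta64(3600, "s")
            sel = (pt >= lo) & (pt < hi)
            if not sel.any():
                continue
            sub = p.loc[sel]
            any_data = False
            for col in continuous:
                vals = pd.to_numeric(sub[col], errors="coerce").dropna()
                if len(vals):
                    out.loc[row, col] = float(vals.median())
                    any_data = True
            for col in categorical:
                m = _mode_earliest(sub[col].tolist())
                if not pd.isna(m):
                    out.loc[row, col] = m
                    any_data = True
            out.loc[row, "missing_covariates"] = not any_data
    return out


def extract_habitat(fixes: pd.DataFrame, intervals: pd.DataFrame,
                    seascape: SeascapeGrid,
                    layers=("geomorphology", "substrate", "region", "pea")) -> pd.DataFrame:
    """Densify fixes, look habitat up on the seascape grid, summarise.

    Raster lookup is nearest-cell for every layer (categorical layers cannot
    be interpolated; PEA uses the same convention for consistency).
    """
    points = interpolate_1min(fixes)
    if len(points):
        looked = seascape.lookup(points["x"].to_numpy(), points["y"].to_numpy())
        for col in layers:
            points[col] = looked[col].to_numpy()
    categorical = tuple(c for c in layers if c != "pea")
    continuous = ("pea",) if "pea" in layers else ()
    return summarize_intervals(points, intervals, categorical, continuous)
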