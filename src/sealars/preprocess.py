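"""Raw telemetry tables to regularised 2-h interval series.

The pipeline is: clean location fixes on tag quality, segment at-sea trips
between haulout events, linearly interpolate positions to the midpoints of
the 2-h summary intervals, derive step lengths and turn angles, flag
unreliable intervals, code the a-priori known states, apply trip-level
filters (post-capture window, minimum duration, seasonal clip, exclusion
polygons), and assign trips to regions via their haulout sites.

All positions are planar kilometres. Expected input schemas match the CSVs
written by :mod:`sealars.simulate` (real data in the same layout works too):

* fixes: ``individual, timestamp, x_km, y_km, n_satellites, residual``
* summaries: ``individual, interval_start, interval_end, prop_diving``
* haulout events: ``individual, start, end, x, y``
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import DIVE_THRESHOLD, MAX_DIVE_PROP

__all__ = [
    "clean_fixes",
    "segment_trips",
    "regularize_track",
    "flag_unreliable",
    "code_known_states",
    "filter_trips",
    "assign_regions",
    "run_pipeline",
]

MIN_SATELLITES = 5
MAX_RESIDUAL = 25.0
MAX_FIX_GAP_H = 6.0
#: dry-at-sea haulout events at least this short are treated as erroneous
MIN_HAULOUT_MIN = 10.0
POST_CAPTURE_DAYS = 7.0
MIN_TRIP_H = 8.0

#: inclusive month windows per species
SEASON_MONTHS = {
    "grey": tuple(range(5, 10)),                    # May - September
    "harbour": (9, 10, 11, 12, 1, 2, 3, 4, 5),      # September - May
}


def clean_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Drop low-quality fixes: < 5 satellites or residual error > 25.

    Both thresholds are applied inclusively (5 satellites and residual 25
    are retained). Row order is preserved.
    """
    for col in ("n_satellites", "residual"):
        if col not in fixes.columns:
            raise ValueError(f"fixes table is missing quality column {col!r}")
    keep = (fixes["n_satellites"] >= MIN_SATELLITES) & (fixes["residual"] <= MAX_RESIDUAL)
    return fixes.loc[keep]


def segment_trips(fixes: pd.DataFrame, haulout_events: pd.DataFrame) -> pd.DataFrame:
    """Assign a trip identifier to each maximal at-sea gap between haulouts.

    A trip is any at-sea location data between recorded haulout events;
    haulout events shorter than 10 minutes are treated as erroneous
    (dry-at-sea sensor artefacts) and ignored. Fixes timestamped inside a
    haulout event are warned about and not assigned to any trip.

    Returns a trip table (``trip, individual, start, end, duration_h,
    n_fixes``); the fixes frame gains a ``trip`` column (NaN inside
    haulouts).
    """
    fixes = fixes.copy()
    fixes["trip"] = pd.NA
    rows = []
    counter = 0
    for ind, f in fixes.groupby("individual", sort=True):
        ev = haulout_events[haulout_events["individual"] == ind] if len(haulout_events) else haulout_events
        if len(ev):
            dur_min = (pd.to_datetime(ev["end"]) - pd.to_datetime(ev["start"])).dt.total_seconds() / 60.0
            ev = ev.loc[dur_min >= MIN_HAULOUT_MIN].sort_values("start")
        t = pd.to_datetime(f["timestamp"])
        bounds = [t.min() - pd.Timedelta(seconds=1)]
        edges = []
        for _, e in (ev.iterrows() if len(ev) else ()):
            edges.append((pd.to_datetime(e["start"]), pd.to_datetime(e["end"]), e))
        edges.sort(key=lambda x: x[0])
        segments = []
        lo = t.min() - pd.Timedelta(seconds=1)
        prev_event = None
        for start, end, e in edges:
            segments.append((lo, start, prev_event, e))
            lo = end
            prev_event = e
        segments.append((lo, t.max() + pd.Timedelta(seconds=1), prev_event, None))
        inside = pd.Series(False, index=f.index)
        for start, end, _ in edges:
            inside |= (t >= start) & (t <= end)
        if inside.any():
            warnings.warn(
                f"{int(inside.sum())} fixes for {ind} fall inside haulout events; "
                "left unassigned to any trip")
        for lo, hi, ev_from, ev_to in segments:
            sel = (t > lo) & (t < hi) & ~inside
            if not sel.any():
                continue
            trip_id = f"trip{counter:05d}"
            counter += 1
            fixes.loc[f.index[sel], "trip"] = trip_id
            ts = t[sel]
            rows.append({
                "trip": trip_id, "individual": ind,
                "start": ts.min(), "end": ts.max(),
                "duration_h": (ts.max() - ts.min()).total_seconds() / 3600.0,
                "n_fixes": int(sel.sum()),
                "start_haulout": None if ev_from is None else (ev_from["x"], ev_from["y"]),
                "end_haulout": None if ev_to is None else (ev_to["x"], ev_to["y"]),
            })
    trips = pd.DataFrame(rows)
    return trips, fixes


def regularize_track(fixes: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Interpolate positions to 2-h summary midpoints; derive steps and angles.

    Positions are linearly interpolated in x and y at each summary-interval
    midpoint lying between an individual's first and last fix. The step
    ``l_t`` is the Euclidean distance to the next midpoint position and the
    turn angle ``phi_t`` the signed angle between consecutive displacement
    vectors, missing whenever either adjoining displacement is missing or
    zero (and always at the first interval).
    """
    out = []
    for ind, s in summaries.groupby("individual", sort=True):
        f = fixes[fixes["individual"] == ind].sort_values("timestamp")
        start = pd.to_datetime(s["interval_start"])
        end = pd.to_datetime(s["interval_end"])
        mid = start + (end - start) / 2
        d = pd.DataFrame({
            "individual": ind, "midpoint": mid.to_numpy(),
            "prop_diving": pd.to_numeric(s["prop_diving"], errors="coerce").to_numpy(),
            "summary_missing": s["prop_diving"].isna().to_numpy(),
        }).sort_values("midpoint")
        if len(f) >= 2:
            ft = pd.to_datetime(f["timestamp"]).astype("int64").to_numpy() / 1e9
            mt = pd.to_datetime(d["midpoint"]).astype("int64").to_numpy() / 1e9
            inside = (mt >= ft[0]) & (mt <= ft[-1])
            x = np.where(inside, np.interp(mt, ft, f["x_km"].to_numpy()), np.nan)
            y = np.where(inside, np.interp(mt, ft, f["y_km"].to_numpy()), np.nan)
            # time separation of the observed fixes bracketing each midpoint
            j = np.searchsorted(ft, mt, side="right")
            j = np.clip(j, 1, len(ft) - 1)
            gap_h = (ft[j] - ft[j - 1]) / 3600.0
            d["gap_h"] = np.where(inside, gap_h, np.inf)
        else:
            x = np.full(len(d), np.nan)
            y = np.full(len(d), np.nan)
            d["gap_h"] = np.inf
        d["x"] = x
        d["y"] = y
        dx = np.diff(x)
        dy = np.diff(y)
        step = np.hypot(dx, dy)
        d["step"] = np.append(step, np.nan)
        head = np.arctan2(dy, dx)
        turn = np.full(len(d), np.nan)
        if len(d) >= 3:
            raw = head[1:] - head[:-1]
            turn[1:-1] = np.mod(raw + np.pi, 2 * np.pi) - np.pi
            # angle undefined when either adjoining displacement is missing/zero
            bad = (step[:-1] == 0) | (step[1:] == 0) | np.isnan(step[:-1]) | np.isnan(step[1:])
            turn[1:-1][bad] = np.nan
        d["angle"] = turn
        out.append(d)
    return pd.concat(out, ignore_index=True)


def flag_unreliable(intervals: pd.DataFrame) -> pd.DataFrame:
    """Flag intervals with missing summary data or a > 6 h bracketing-fix gap.

    The gap rule is a strict inequality: fixes exactly 6 h apart do not
    trigger the flag.
    """
    intervals = intervals.copy()
    intervals["unreliable"] = (
        intervals["summary_missing"].fillna(True).astype(bool)
        | (intervals["gap_h"] > MAX_FIX_GAP_H)
        | intervals["x"].isna()
    )
    return intervals


def code_known_states(intervals: pd.DataFrame) -> pd.DataFrame:
    """Assign the a-priori known-state code to each interval.

    ``Unk`` if flagged unreliable; else ``N`` (non-diving) if the dive
    proportion is strictly below 0.444 (half the 0.888 physiological
    maximum); else ``free`` — to be inferred among the movement states.
    Dive proportions above 0.888 are clamped with a warning.
    """
    intervals = intervals.copy()
    over = intervals["prop_diving"] > MAX_DIVE_PROP
    if over.any():
        warnings.warn(f"{int(over.sum())} dive proportions exceed {MAX_DIVE_PROP}; clamped")
        intervals.loc[over, "prop_diving"] = MAX_DIVE_PROP
    code = np.where(
        intervals["unreliable"], "Unk",
        np.where(intervals["prop_diving"] < DIVE_THRESHOLD, "N", "free"),
    )
    intervals["known_state"] = code
    return intervals


def _point_in_polygon(x, y, poly):
    """Even-odd ray casting for one polygon given as an (n, 2) array."""
    poly = np.asarray(poly, dtype=float)
    inside = np.zeros(np.shape(x), dtype=bool)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = ((y1 > y) != (y2 > y)) & (
            x < (x2 - x1) * (y - y1) / (y2 - y1 + 1e-300) + x1)
        inside ^= crosses
    return inside


def filter_trips(trips: pd.DataFrame, intervals: pd.DataFrame,
                 capture_dates: dict, species: str,
                 exclusion_polygons=()) -> tuple:
    """Apply the trip- and interval-level inclusion filters.

    Removes trips starting within 7 days (168 h) of the individual's capture,
    trips shorter than 8 h, intervals outside the species' season window
    (grey: May-September; harbour: September-May; both boundary months
    inclusive), and intervals inside any supplied exclusion polygon.

    Returns ``(trips, intervals, report)`` where ``report`` counts removals
    per rule.
    """
    if species not in SEASON_MONTHS:
        raise ValueError(f"unknown species {species!r}")
    report = {}
    t = trips.copy()
    cap = t["individual"].map(capture_dates)
    if cap.isna().any():
        missing = sorted(t.loc[cap.isna(), "individual"].unique())
        raise ValueError(f"capture date unknown for individuals: {missing}")
    age_h = (pd.to_datetime(t["start"]) - pd.to_datetime(cap)).dt.total_seconds() / 3600.0
    post_capture = age_h < POST_CAPTURE_DAYS * 24.0
    report["post_capture_trips"] = int(post_capture.sum())
    short = t["duration_h"] < MIN_TRIP_H
    report["short_trips"] = int((short & ~post_capture).sum())
    t = t.loc[~(post_capture | short)]
    iv = intervals[intervals["trip"].isin(t["trip"])].copy()
    report["intervals_outside_kept_trips"] = len(intervals) - len(iv)
    months = pd.to_datetime(iv["midpoint"]).dt.month
    in_season = months.isin(SEASON_MONTHS[species])
    report["out_of_season_intervals"] = int((~in_season).sum())
    iv = iv.loc[in_season]
    excluded = np.zeros(len(iv), dtype=bool)
    for poly in exclusion_polygons:
        excluded |= _point_in_polygon(iv["x"].to_numpy(), iv["y"].to_numpy(), poly)
    report["excluded_polygon_intervals"] = int(excluded.sum())
    iv = iv.loc[~excluded]
    t = t[t["trip"].isin(iv["trip"].unique())]
    return t, iv, report


def assign_regions(trips: pd.DataFrame, intervals: pd.DataFrame,
                   haulout_regions) -> pd.DataFrame:
    """Label intervals with the region of their trip's haulout sites.

    ``haulout_regions`` maps a haulout site ``(x, y)`` to a region label —
    either a callable or a list of ``(x, y, region)`` rows (nearest site
    wins). Trips whose start and end haulouts sit in different regions are
    split at the temporal midpoint: the first ``floor(n/2)`` intervals take
    the departure region, the rest the destination region.
    """
    if callable(haulout_regions):
        region_of = haulout_regions
    else:
        sites = pd.DataFrame(haulout_regions, columns=["x", "y", "region"])

        def region_of(xy):
            d2 = (sites["x"] - xy[0]) ** 2 + (sites["y"] - xy[1]) ** 2
            return sites["region"].iloc[int(np.argmin(d2))]

    intervals = intervals.copy()
    intervals["region"] = pd.NA
    for _, trip in trips.iterrows():
        sel = intervals["trip"] == trip["trip"]
        n = int(sel.sum())
        if n == 0:
            continue
        start_xy = trip.get("start_haulout") or trip.get("end_haulout")
        end_xy = trip.get("end_haulout") or trip.get("start_haulout")
        if start_xy is None and end_xy is None:
            raise ValueError(f"trip {trip['trip']} has no haulout site to map to a region")
        r1 = region_of(start_xy)
        r2 = region_of(end_xy)
        idx = intervals.index[sel]
        order = np.argsort(pd.to_datetime(intervals.loc[idx, "midpoint"]).to_numpy())
        labels = np.array([r1] * (n // 2) + [r2] * (n - n // 2), dtype=object)
        intervals.loc[idx[order], "region"] = labels
    return intervals


def run_pipeline(fixes, summaries, haulout_events, capture_dates, species,
                 haulout_regions=None, exclusion_polygons=()):
    """Full preprocessing chain; returns (intervals, trips, report)."""
    fixes = clean_fixes(fixes)
    trips, fixes = segment_trips(fixes, haulout_events)
    intervals = regularize_track(fixes, summaries)
    intervals = flag_unreliable(intervals)
    intervals = code_known_states(intervals)
    # attach trip ids to intervals by midpoint containment
    intervals["trip"] = pd.NA
    for _, trow in trips.iterrows():
        sel = ((intervals["individual"] == trow["individual"])
               & (intervals["midpoint"] >= trow["start"])
               & (intervals["midpoint"] <= trow["end"]))
        intervals.loc[sel, "trip"] = trow["trip"]
    trips, intervals, report = filter_trips(
        trips, intervals, capture_dates, species, exclusion_polygons)
    if haulout_regions is not None:
        intervals = assign_regions(trips, intervals, haulout_regions)
    return intervals, trips, report
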