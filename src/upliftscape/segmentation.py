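"""Behavioural segmentation of 1 Hz GPS bursts.

Each eligible burst (>= 120 s) is cut into consecutive 15 s segments — the
average duration of one complete soaring circle — carrying the mean vertical
speed and the absolute cumulative turning angle.  Pooled segments are
classified by an expectation-maximization binary-clustering scheme: each
variable is split into a low and a high regime by a two-component 1-D
Gaussian mixture and every segment is labelled by its quadrant — high
turning is circular soaring; the low-turning quadrants split into linear
soaring (climbing regime) and gliding (sinking regime).  An isolated-label smoother and the soaring-event extraction
(runs > 30 s, gaps < 60 s merged, centroid = mean member-fix position)
produce the uplift *presence* points used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GeoRef

SOARING_LABELS = ("circular_soaring", "linear_soaring")
SEGMENT_S = 15.0


class InputError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def compute_fix_metrics(burst: pd.DataFrame, georef: GeoRef | None = None) -> pd.DataFrame:
    """Per-fix vertical speed and turning angle for one GPS burst.

    Vertical speed at fix ``i`` is the forward height difference over the
    forward time step (undefined at the last fix).  The turning angle at fix
    ``i`` is the absolute change of the ground-track heading in [0, 180]
    degrees (undefined at the first and last fix).  Headings are planar,
    computed on the local metric grid (``x``/``y`` columns if present,
    otherwise from lon/lat via ``georef``).
    """
    if len(burst) < 3:
        raise InputError("burst needs at least 3 fixes")
    ts = pd.to_datetime(burst["timestamp"]).to_numpy()
    dt = np.diff(ts).astype("timedelta64[ns]").astype(float) / 1e9
    if np.any(dt <= 0):
        raise InputError("duplicate or non-increasing timestamps in burst")
    out = burst.copy()
    if "x" not in out.columns or "y" not in out.columns:
        geo = georef or GeoRef()
        out["x"], out["y"] = geo.to_xy(out["lon"].to_numpy(),
                                       out["lat"].to_numpy())
    h = out["height"].to_numpy(float)
    vs = np.full(len(out), np.nan)
    vs[:-1] = np.diff(h) / dt
    dx = np.diff(out["x"].to_numpy(float))
    dy = np.diff(out["y"].to_numpy(float))
    heading = np.degrees(np.arctan2(dx, -dy))  # 0 = north, y grows southward
    turn = np.full(len(out), np.nan)
    dh = np.abs(np.diff(heading))
    turn[1:-1] = np.minimum(dh, 360.0 - dh)
    out["vspeed"] = vs
    out["turn_angle"] = turn
    return out


def build_segments(burst: pd.DataFrame, window_s: float = SEGMENT_S) -> pd.DataFrame:
    """Non-overlapping 15 s segments of one burst (with fix metrics).

    Each segment carries the mean vertical speed and the sum of absolute
    turning angles of its member fixes; a trailing remainder shorter than the
    window is dropped.  Bursts shorter than 120 s are ineligible.
    """
    ts = pd.to_datetime(burst["timestamp"])
    span = (ts.iloc[-1] - ts.iloc[0]).total_seconds() + 1.0
    if span < 120:
        raise InputError("burst shorter than 120 s is not segmentable")
    off = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    seg_idx = np.floor(off / window_s).astype(int)
    n_full = int(span // window_s)
    rows = []
    for k in range(n_full):
        m = burst.loc[seg_idx == k]
        if m.empty:
            continue
        row = {
            "burst_id": m["burst_id"].iloc[0] if "burst_id" in m else "",
            "individual_id": m["individual_id"].iloc[0] if "individual_id" in m else "",
            "seg_index": k,
            "t_start": m["timestamp"].iloc[0],
            "t_end": m["timestamp"].iloc[0] + pd.Timedelta(seconds=window_s),
            "duration_s": window_s,
            "mean_vspeed": float(np.nanmean(m["vspeed"].to_numpy(float)))
            if np.isfinite(m["vspeed"].to_numpy(float)).any() else np.nan,
            "cum_turn": float(np.nansum(m["turn_angle"].to_numpy(float))),
            "mean_x": float(m["x"].mean()), "mean_y": float(m["y"].mean()),
            "mean_lon": float(m["lon"].mean()) if "lon" in m else np.nan,
            "mean_lat": float(m["lat"].mean()) if "lat" in m else np.nan,
            "n_fix": len(m),
        }
        if "truth_behaviour" in m:
            row["truth_behaviour"] = m["truth_behaviour"].mode().iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def segment_bursts(fixes: pd.DataFrame, georef: GeoRef | None = None,
                   window_s: float = SEGMENT_S) -> pd.DataFrame:
    """Fix metrics + segmentation for every eligible burst in a fix table."""
    segs = []
    for _, burst in fixes.groupby("burst_id", sort=False):
        ts = pd.to_datetime(burst["timestamp"])
        if (ts.iloc[-1] - ts.iloc[0]).total_seconds() + 1.0 < 120:
            continue
        b = compute_fix_metrics(burst.sort_values("timestamp"), georef)
        segs.append(build_segments(b, window_s))
    if not segs:
        raise InputError("no burst of at least 120 s found")
    return pd.concat(segs, ignore_index=True)


# ---------------------------------------------------------------------------
# EM binary clustering
# ---------------------------------------------------------------------------

@dataclass
class EmbcModel:
    """Fitted 4-component quadrant mixture on (vertical speed, turning)."""

    means: np.ndarray          # (4, 2)
    variances: np.ndarray      # (4, 2)
    weights: np.ndarray        # (4,)
    delimiters: tuple[float, float]   # (vspeed, turning)
    n_iter: int
    log_likelihood: float
    quadrants: tuple[str, ...] = ("LL", "LH", "HL", "HH")  # (v, turn) low/high


def _quadrant_labels(v_low, t_low):
    return np.where(v_low, np.where(t_low, 0, 1), np.where(t_low, 2, 3))


def _binary_split_1d(x: np.ndarray, max_iter: int, tol: float):
    """Two-component 1-D Gaussian EM with a deterministic median-split init.

    Returns ``(delimiter, mean_low, mean_high, log_likelihood, n_iter)``
    where the delimiter is the equal-posterior point between the two
    component means.
    """
    med = np.median(x)
    lo0 = x <= med
    if not lo0.any() or lo0.all():
        lo0 = x <= x.mean()
    mu = np.array([x[lo0].mean(), x[~lo0].mean()])
    var = np.maximum(np.array([x[lo0].var(), x[~lo0].var()]), 1e-8)
    w = np.array([lo0.mean(), 1.0 - lo0.mean()])
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_p = (-0.5 * ((x[:, None] - mu) ** 2 / var
                         + np.log(2 * np.pi * var)) + np.log(w))
        mx = log_p.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(log_p - mx).sum(axis=1))
        resp = np.exp(log_p - lse[:, None])
        ll = float(lse.sum())
        nk = resp.sum(axis=0) + 1e-12
        mu = resp.T @ x / nk
        var = np.maximum(resp.T @ (x ** 2) / nk - mu ** 2, 1e-8)
        w = nk / nk.sum()
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    else:
        if abs(ll - prev_ll) > 1e-4 * max(1.0, abs(ll)):
            raise ConvergenceError(
                f"1-D EM did not converge in {max_iter} iterations")
    lo, hi = int(np.argmin(mu)), int(np.argmax(mu))
    if mu[hi] - mu[lo] < 1e-12:
        return float(mu[lo]), float(mu[lo]), float(mu[hi]), prev_ll, n_iter
    grid = np.linspace(mu[lo], mu[hi], 1001)
    log_post = (-0.5 * ((grid[:, None] - mu) ** 2 / var
                        + np.log(2 * np.pi * var)) + np.log(w))
    delim = float(grid[np.argmin(np.abs(log_post[:, lo] - log_post[:, hi]))])
    return delim, float(mu[lo]), float(mu[hi]), prev_ll, n_iter


def embc_classify(segments: pd.DataFrame, seed: int = 1, max_iter: int = 200,
                  tol: float = 1e-6,
                  min_turn_delimiter: float = 90.0) -> tuple[pd.DataFrame, EmbcModel]:
    """Label pooled 15 s segments by EM binary clustering.

    Each clustering variable (mean vertical speed, cumulative turning) is
    split into a low and a high regime by a two-component 1-D Gaussian EM;
    the delimiter is the equal-posterior point between the regimes and every
    segment is labelled by its quadrant: high turning -> ``circular_soaring``;
    low turning with vertical speed in a climbing regime -> ``linear_soaring``;
    otherwise ``gliding``.  If the high-turning regime mean falls below
    ``min_turn_delimiter`` (degrees per segment, about a quarter circle) no
    circling regime is present and all segments are treated as low-turning;
    a vertical-speed regime whose mean is not positive never produces
    ``linear_soaring``.  The fit is deterministic (median-split
    initialization); ``seed`` is retained for interface stability.
    """
    segs = segments.reset_index(drop=True)
    X = segs[["mean_vspeed", "cum_turn"]].to_numpy(float)
    keep = np.isfinite(X).all(axis=1)
    Xf = X[keep]
    if len(Xf) < 20:
        raise InputError("need at least 20 segments with finite metrics")
    if np.any(Xf.std(axis=0) == 0):
        raise DegenerateInputError("zero variance in a clustering metric")

    delim_v, mu_v_lo, mu_v_hi, ll_v, it_v = _binary_split_1d(
        Xf[:, 0], max_iter, tol)
    delim_t, mu_t_lo, mu_t_hi, ll_t, it_t = _binary_split_1d(
        Xf[:, 1], max_iter, tol)

    # regime-collapse guard: circling means roughly a full circle per
    # segment; a "high" turning regime far below a quarter circle is just a
    # split within a single low-turning regime
    turning_bimodal = mu_t_hi >= min_turn_delimiter
    v_high = Xf[:, 0] > delim_v
    t_high = (Xf[:, 1] > delim_t) if turning_bimodal else np.zeros(len(Xf), bool)

    lab = np.where(t_high, "circular_soaring",
                   np.where(v_high & (mu_v_hi > 0), "linear_soaring",
                            np.where(~v_high & (mu_v_lo > 0),
                                     "linear_soaring", "gliding")))

    beh = np.full(len(segs), None, dtype=object)
    beh[keep] = lab
    quad_names = np.array(["LL", "LH", "HL", "HH"])  # (v, t): L/H x L/H
    qcode = _quadrant_labels(~v_high, ~t_high)
    quads = np.full(len(segs), None, dtype=object)
    quads[keep] = quad_names[qcode]

    # per-quadrant summary statistics of the fitted binary partition
    means = np.zeros((4, 2))
    var = np.zeros((4, 2))
    w = np.zeros(4)
    glob_mean = Xf.mean(axis=0)
    glob_var = Xf.var(axis=0)
    for q in range(4):
        m = qcode == q
        w[q] = m.mean()
        means[q] = Xf[m].mean(axis=0) if m.any() else glob_mean
        var[q] = Xf[m].var(axis=0) if m.any() else glob_var

    out = segs.copy()
    out["behaviour"] = beh
    out["embc_quadrant"] = quads
    model = EmbcModel(means=means, variances=var, weights=w,
                      delimiters=(float(delim_v), float(delim_t)),
                      n_iter=max(it_v, it_t), log_likelihood=ll_v + ll_t)
    return out, model


def smooth_labels(labels, burst_ids=None):
    """Reclassify isolated labels to the mode of their 2-before/2-after window.

    A label is replaced only when it differs from *both* immediate
    neighbours; the replacement is the modal value of positions
    {i-2, i-1, i+1, i+2} (the focal segment excluded), with the window
    truncated at sequence edges and modal ties keeping the original label.
    One left-to-right pass, applied independently within each burst when
    ``burst_ids`` is given.
    """
    lab = np.asarray(labels, dtype=object).copy()
    if burst_ids is None:
        groups = [np.arange(len(lab))]
    else:
        bid = np.asarray(burst_ids)
        groups = [np.where(bid == b)[0] for b in pd.unique(bid)]
    for idx in groups:
        seq = lab[idx]
        n = len(seq)
        for i in range(n):
            left = seq[i - 1] if i > 0 else None
            right = seq[i + 1] if i < n - 1 else None
            neigh = [x for x in (left, right) if x is not None]
            if not neigh or any(seq[i] == x for x in neigh):
                continue
            window = [seq[j] for j in (i - 2, i - 1, i + 1, i + 2)
                      if 0 <= j < n and j != i]
            vals, counts = np.unique(np.array(window, dtype=object),
                                     return_counts=True)
            top = counts.max()
            winners = vals[counts == top]
            if len(winners) == 1:
                seq[i] = winners[0]
        lab[idx] = seq
    return lab


def extract_soaring_events(segments: pd.DataFrame,
                           min_duration_s: float = 30.0,
                           merge_gap_s: float = 60.0) -> pd.DataFrame:
    """Soaring events (uplift presences) from labelled segments.

    Circular and linear soaring are pooled; maximal runs of soaring segments
    whose gaps are shorter than ``merge_gap_s`` are merged into one event;
    events whose total soaring duration is not strictly greater than
    ``min_duration_s`` are discarded.  The centroid is the mean position of
    the member fixes (via per-segment fix-count-weighted means).
    """
    events = []
    segs = segments.sort_values(["individual_id", "t_start"])
    for ind, g in segs.groupby("individual_id", sort=False):
        g = g.reset_index(drop=True)
        soar = g["behaviour"].isin(SOARING_LABELS).to_numpy()
        runs = []
        i = 0
        while i < len(g):
            if soar[i]:
                j = i
                while j + 1 < len(g) and soar[j + 1]:
                    j += 1
                runs.append([i, j])
                i = j + 1
            else:
                i += 1
        merged: list[list[int]] = []
        for run in runs:
            if merged:
                gap = (g.loc[run[0], "t_start"]
                       - g.loc[merged[-1][1], "t_end"]).total_seconds()
                if 0 <= gap < merge_gap_s:
                    merged[-1][1] = run[1]
                    continue
            merged.append(run)
        for i0, i1 in merged:
            mem = g.loc[i0:i1]
            mem = mem[mem["behaviour"].isin(SOARING_LABELS)]
            dur = float(mem["duration_s"].sum())
            if dur <= min_duration_s:
                continue
            wgt = mem["n_fix"].to_numpy(float)
            events.append({
                "individual_id": ind,
                "t_start": mem["t_start"].iloc[0],
                "t_end": mem["t_end"].iloc[-1],
                "duration_s": dur,
                "lon": float(np.average(mem["mean_lon"], weights=wgt)),
                "lat": float(np.average(mem["mean_lat"], weights=wgt)),
                "x": float(np.average(mem["mean_x"], weights=wgt)),
                "y": float(np.average(mem["mean_y"], weights=wgt)),
                "mean_vspeed": float(np.average(mem["mean_vspeed"], weights=wgt)),
                "n_segments": int(len(mem)),
            })
    return pd.DataFrame(events)
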