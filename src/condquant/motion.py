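"""Trajectory linking, MSD/diffusion estimation, and binding-event analysis.

The diffusion coefficient is taken from an ordinary least-squares line
through the 2nd-4th MSD points (lag 1 excluded so the free intercept can
absorb localization noise); D = slope / 4 for a 2D projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class Trajectory:
    id: int
    frames: np.ndarray  # strictly increasing ints
    xy_px: np.ndarray   # (n, 2) columns (x, y)
    channel: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy_px = np.asarray(self.xy_px, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if len(self.frames) != len(self.xy_px):
            raise ValueError("frames and positions length mismatch")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class MSDProfile:
    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray


@dataclass
class BindingEvent:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BindingSummary:
    events: list[BindingEvent] = field(default_factory=list)
    n_events: int = 0
    median_dwell_s: float = np.nan
    fraction_transient: float = np.nan  # dwell < 1 s


def link_trajectories(spots_per_frame: list[np.ndarray], max_disp_px: float,
                      max_gap: int = 1, min_length: int = 1) -> list[Trajectory]:
    """Frame-to-frame linking by optimal assignment on squared displacement.

    ``spots_per_frame[t]`` is an (n_t, 2) array of (x, y) positions. Active
    tracks missing up to ``max_gap`` consecutive frames may be continued
    (gap closing). Tracks shorter than ``min_length`` are dropped.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    BIG = 1e12
    active: list[dict] = []  # {"frames": [...], "xy": [...], "last_seen": t}
    done: list[dict] = []
    for t, pts in enumerate(spots_per_frame):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        # retire tracks that exceeded the gap allowance
        still = []
        for tr in active:
            if t - tr["last_seen"] > max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
        if len(active) and len(pts):
            last = np.array([tr["xy"][-1] for tr in active])
            d2 = ((last[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            cost = np.where(d2 <= max_disp_px ** 2, d2, BIG)
            rows, cols = linear_sum_assignment(cost)
            used = set()
            for i, j in zip(rows, cols):
                if cost[i, j] >= BIG:
                    continue
                active[i]["frames"].append(t)
                active[i]["xy"].append(pts[j])
                active[i]["last_seen"] = t
                used.add(j)
            new_idx = [j for j in range(len(pts)) if j not in used]
        else:
            new_idx = list(range(len(pts)))
        for j in new_idx:
            active.append({"frames": [t], "xy": [pts[j]], "last_seen": t})
    done.extend(active)
    out = []
    tid = 0
    for tr in done:
        if len(tr["frames"]) >= min_length:
            out.append(Trajectory(tid, np.array(tr["frames"]), np.array(tr["xy"])))
            tid += 1
    return out


def compute_msd(traj: Trajectory | np.ndarray, pixel_size_nm: float,
                frame_interval_s: float, max_lag_frac: float = 0.25) -> MSDProfile:
    """Time-averaged MSD over all overlapping pairs, lags up to length/4.

    Accepts a Trajectory (contiguous frames assumed for the FFT-free direct
    sum; single-frame gaps contribute nothing at affected lags) or a plain
    (n, 2) position array in px. Lag 0 (MSD = 0) is included.
    """
    if isinstance(traj, Trajectory):
        frames, xy = traj.frames, traj.xy_px
    else:
        xy = np.asarray(traj, dtype=float)
        frames = np.arange(len(xy))
    n = len(xy)
    if n < 5:
        raise ValueError("trajectory too short for MSD (need >= 5 points)")
    px_um = pixel_size_nm / 1000.0
    max_lag = max(4, int(np.floor(n * max_lag_frac)))
    # positions on a dense frame grid so single-frame gaps stay honest
    dense = np.full((frames.max() + 1, 2), np.nan)
    dense[frames] = xy
    lags = np.arange(0, max_lag + 1)
    msd = np.zeros(len(lags))
    n_pairs = np.zeros(len(lags), dtype=int)
    n_pairs[0] = len(frames)
    for li, lag in enumerate(lags[1:], start=1):
        d = dense[lag:] - dense[:-lag or None]
        sq = (d ** 2).sum(axis=1)
        valid = np.isfinite(sq)
        n_pairs[li] = int(valid.sum())
        msd[li] = float(sq[valid].mean()) * px_um ** 2 if n_pairs[li] else np.nan
    return MSDProfile(lag_s=lags * frame_interval_s, msd_um2=msd, n_pairs=n_pairs)


def fit_diffusion(msd: MSDProfile, points: tuple[int, ...] = (2, 3, 4)
                  ) -> tuple[float, float]:
    """OLS line through the chosen MSD data points (lag indices counted with
    lag 0 excluded, so ``(2, 3, 4)`` means lags 2dt, 3dt, 4dt).

    Returns ``(D, intercept)`` with D = slope / 4 (2D). The intercept may be
    negative and is reported as-is.
    """
    idx = np.asarray(points, dtype=int)
    if len(msd.lag_s) <= idx.max():
        raise ValueError("MSD profile too short for the requested fit points")
    x = msd.lag_s[idx]
    y = msd.msd_um2[idx]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite MSD values at fit points")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope / 4.0), float(intercept)


def ensemble_diffusion(trajectories, pixel_size_nm: float, frame_interval_s: float
                       ) -> float:
    """Mean of per-track D estimates (tracks too short to fit are skipped)."""
    ds = []
    for tr in trajectories:
        try:
            prof = compute_msd(tr, pixel_size_nm, frame_interval_s)
            ds.append(fit_diffusion(prof)[0])
        except ValueError:
            continue
    if not ds:
        raise ValueError("no trajectory long enough for a diffusion fit")
    return float(np.mean(ds))


def distance_trace(mrna_traj: Trajectory, condensate_trajs: list[Trajectory],
                   pixel_size_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame distance (nm) from an mRNA to the nearest condensate.

    Returns ``(frames, distances_nm)`` over the union of the mRNA's frames;
    frames where no condensate position exists are NaN.
    """
    if not condensate_trajs:
        raise ValueError("need at least one condensate trajectory")
    frames = mrna_traj.frames
    out = np.full(len(frames), np.nan)
    cond_maps = [dict(zip(tr.frames.tolist(), tr.xy_px)) for tr in condensate_trajs]
    any_overlap = False
    for i, f in enumerate(frames):
        ds = [np.hypot(*(m[f] - mrna_traj.xy_px[i]))
              for m in cond_maps if f in m]
        if ds:
            any_overlap = True
            out[i] = min(ds) * pixel_size_nm
    if not any_overlap:
        raise ValueError("no overlapping frames between mRNA and condensates")
    return frames, out


def detect_binding_events(frames: np.ndarray, distance_nm: np.ndarray,
                          frame_interval_s: float, r_on_nm: float = 400.0,
                          r_off_nm: float = 600.0, min_frames: int = 2
                          ) -> BindingSummary:
    """Hysteresis state machine over a distance trace.

    Enter the bound state after ``min_frames`` consecutive samples below
    ``r_on``; leave it after ``min_frames`` consecutive samples above
    ``r_off``. Missing (NaN) samples reset the pending counters but do not
    flip the state. Event times are the first frame of the qualifying run.
    """
    if not r_on_nm < r_off_nm:
        raise ValueError("need r_on < r_off for hysteresis")
    frames = np.asarray(frames)
    d = np.asarray(distance_nm, dtype=float)
    valid = np.isfinite(d)
    if not valid.any():
        return BindingSummary()
    bound = False
    run_start = None
    run_len = 0
    event_start = None
    events: list[BindingEvent] = []
    for i in range(len(d)):
        if not valid[i]:
            run_len, run_start = 0, None
            continue
        crossing = (d[i] < r_on_nm) if not bound else (d[i] > r_off_nm)
        if crossing:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= min_frames:
                if not bound:
                    bound = True
                    event_start = frames[run_start] * frame_interval_s
                else:
                    bound = False
                    events.append(BindingEvent(event_start,
                                               frames[run_start] * frame_interval_s))
                run_len, run_start = 0, None
        else:
            run_len, run_start = 0, None
    if bound and event_start is not None:
        events.append(BindingEvent(event_start, frames[-1] * frame_interval_s))
    dwell = np.array([e.duration_s for e in events])
    return BindingSummary(
        events=events, n_events=len(events),
        median_dwell_s=float(np.median(dwell)) if len(dwell) else np.nan,
        fraction_transient=float(np.mean(dwell < 1.0)) if len(dwell) else np.nan)
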