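"""Functional readouts: reporter kinetics, FRAP, half-life, spine volumes,
nascent-translation quantification, and the pooled two-sample t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import filters, measure, segmentation
from scipy.ndimage import distance_transform_edt


@dataclass
class FRAPTrace:
    """Raw FRAP time series with its bleach structure."""

    times_s: np.ndarray
    values: np.ndarray
    pre_frames: int
    bleach_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bleach_index < self.pre_frames or self.pre_frames < 1:
            raise ValueError("bleach frame must come after the pre-bleach window")


@dataclass
class FRAPResult:
    mobile_fraction: float
    tau_s: float
    times_s: np.ndarray
    normalized: np.ndarray
    clipped: bool = False

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction


# ---------------------------------------------------------------------------
# reporter kinetics


def reporter_normalize(times, traces):
    """Divide each cell trace by its own t=0 value.

    Returns ``(normalized (n_cells, n_t), endpoint_mean, endpoint_sd,
    kept_index)``; cells with a non-positive initial value are excluded with
    a warning.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] < 2:
        raise ValueError("need >= 2 time points")
    init = traces[:, 0]
    keep = init > 0
    if not keep.all():
        warnings.warn(f"excluding {np.count_nonzero(~keep)} cells with zero "
                      "initial value")
    norm = traces[keep] / init[keep, None]
    end = norm[:, -1]
    return norm, float(end.mean()), float(end.std(ddof=1)) if len(end) > 1 else 0.0, \
        np.nonzero(keep)[0]


def bin_by_expression(expression, endpoints,
                      bin_edges=(0, 100, 200, 300, 400)):
    """Mean +/- SD of endpoint values in half-open expression bins [lo, hi).

    Returns a pandas DataFrame with columns (lo, hi, n, mean, sd); cells
    outside the edge range are excluded (count reported in ``df.attrs``).
    """
    import pandas as pd

    expression = np.asarray(expression, dtype=float)
    endpoints = np.asarray(endpoints, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be increasing")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (expression >= lo) & (expression < hi)
        n = int(sel.sum())
        rows.append({
            "lo": lo, "hi": hi, "n": n,
            "mean": float(endpoints[sel].mean()) if n else np.nan,
            "sd": float(endpoints[sel].std(ddof=1)) if n > 1 else
                  (0.0 if n == 1 else np.nan),
        })
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = int(((expression < edges[0])
                                  | (expression >= edges[-1])).sum())
    return df


def fit_half_life(times_h, values, with_floor: bool = False
                  ) -> tuple[float, dict]:
    """Exponential-decay fit ``A exp(-k t) (+ floor)``; half-life = ln2 / k.

    Raises for traces that do not decay. Returns ``(t_half_h, diagnostics)``.
    """
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 5:
        raise ValueError("need >= 5 points for a half-life fit")
    if v[-1] >= v[0]:
        raise ValueError("trace does not decay; half-life undefined")
    if with_floor:
        model = lambda tt, a, k, c: a * np.exp(-k * tt) + c
        p0 = (v[0] - v[-1], 0.7 / max(t[-1], 1e-9), v[-1])
        bounds = ([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf])
    else:
        model = lambda tt, a, k: a * np.exp(-k * tt)
        p0 = (v[0], 0.7 / max(t[-1], 1e-9))
        bounds = ([0, 1e-9], [np.inf, np.inf])
    popt, _ = optimize.curve_fit(model, t, v, p0=p0, bounds=bounds, maxfev=20000)
    k = popt[1]
    resid = v - model(t, *popt)
    return float(np.log(2) / k), {"k_per_h": float(k), "params": popt,
                                  "rmse": float(np.sqrt(np.mean(resid ** 2)))}


# ---------------------------------------------------------------------------
# FRAP


def frap_analyze(trace: FRAPTrace, clip_limit: float = 1.05) -> FRAPResult:
    """Mobile-fraction fit of a FRAP trace.

    Normalization: ``I_n(t) = (I(t) - I0+) / (mean_pre - I0+)`` with ``I0+``
    the first post-bleach value and t measured from the bleach; then fit
    ``M (1 - exp(-t / tau))``. The immobile fraction is ``1 - M``; M above
    ``clip_limit`` is clipped with a flag.
    """
    pre = trace.values[:trace.pre_frames].mean()
    post = trace.values[trace.bleach_index:]
    t = trace.times_s[trace.bleach_index:] - trace.times_s[trace.bleach_index]
    i0 = post[0]
    if pre <= i0:
        raise ValueError("no bleach detected (pre-bleach mean <= first "
                         "post-bleach value)")
    norm = (post - i0) / (pre - i0)
    span = max(t[-1], 1e-9)
    popt, _ = optimize.curve_fit(
        lambda tt, m, tau: m * (1 - np.exp(-tt / tau)),
        t, norm, p0=(0.8, span / 5), bounds=([0, 1e-9], [2.0, 10 * span]),
        maxfev=20000)
    m, tau = popt
    clipped = m > clip_limit
    return FRAPResult(mobile_fraction=float(min(m, clip_limit)),
                      tau_s=float(tau), times_s=t, normalized=norm,
                      clipped=bool(clipped))


# ---------------------------------------------------------------------------
# spine volumes


def phansalkar_threshold(image: np.ndarray, window: int = 15, k: float = 0.25,
                         r: float = 0.5, p: float = 2.0, q: float = 10.0
                         ) -> np.ndarray:
    """Phansalkar local threshold surface for a 2D image.

    The image is normalized to [0, 1]; the threshold at each pixel is
    ``m (1 + p exp(-q m) + k (s/r - 1))`` with m, s the local mean and
    standard deviation in a ``window`` x ``window`` neighborhood. Returned
    on the original intensity scale.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scale = hi - lo if hi > lo else 1.0
    x = (img - lo) / scale
    m = ndimage.uniform_filter(x, window, mode="nearest")
    m2 = ndimage.uniform_filter(x * x, window, mode="nearest")
    s = np.sqrt(np.clip(m2 - m * m, 0, None))
    thr = m * (1 + p * np.exp(-q * m) + k * (s / r - 1))
    return thr * scale + lo


def spine_volume(stack_series, roi_boxes, window: int = 15, k: float = 0.25,
                 r: float = 0.5, voxel_um3: float | None = None,
                 min_intensity_frac: float = 0.4) -> np.ndarray:
    """Per-spine, per-timepoint volumes by per-slice Phansalkar thresholding
    inside ROI boxes; the volume is the foreground voxel count.

    ``stack_series`` is (T, Z, Y, X); ``roi_boxes`` are
    (z0, z1, y0, y1, x0, x1) tuples. ``min_intensity_frac`` additionally
    requires voxels to exceed that fraction of the ROI intensity range:
    local thresholds alone admit background noise where the local mean is
    ~0, and 0.4 puts the cut near the half-max contour of a blurred solid
    object, which tracks its true surface. Returns volumes (n_spines, T) in
    voxels, or um^3 when ``voxel_um3`` is given.
    """
    px = np.asarray(stack_series, dtype=float)
    if px.ndim != 4:
        raise ValueError("stack series must be (T, Z, Y, X)")
    nt = px.shape[0]
    out = np.zeros((len(roi_boxes), nt))
    for s, (z0, z1, y0, y1, x0, x1) in enumerate(roi_boxes):
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            raise ValueError("empty ROI box")
        for t in range(nt):
            roi = px[t, z0:z1, y0:y1, x0:x1]
            floor = roi.min() + min_intensity_frac * (roi.max() - roi.min())
            count = 0
            for z in range(roi.shape[0]):
                sl = roi[z]
                fg = (sl > phansalkar_threshold(sl, window, k, r)) & (sl > floor)
                count += int(fg.sum())
            out[s, t] = count
    if voxel_um3 is not None:
        out = out * voxel_um3
    return out


def spine_change(volumes: np.ndarray, n_baseline: int = 3
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize each spine by the mean of its baseline volumes.

    Returns ``(normalized (n_spines, T), mean_per_t, sem_per_t)``; spines
    with a zero baseline are excluded.
    """
    v = np.asarray(volumes, dtype=float)
    if v.shape[1] < n_baseline:
        raise ValueError(f"need >= {n_baseline} baseline points")
    base = v[:, :n_baseline].mean(axis=1)
    keep = base > 0
    if not keep.all():
        warnings.warn(f"excluding {np.count_nonzero(~keep)} spines with zero "
                      "baseline volume")
    norm = v[keep] / base[keep, None]
    mean = norm.mean(axis=0)
    sem = norm.std(axis=0, ddof=1) / np.sqrt(norm.shape[0]) if norm.shape[0] > 1 \
        else np.zeros(norm.shape[1])
    return norm, mean, sem


# ---------------------------------------------------------------------------
# translation assays


def segment_nuclei(nuclei_image: np.ndarray, smooth_sigma: float = 3.0,
                   min_area_px: int = 50) -> np.ndarray:
    """Label image of nuclei: smooth, subtract median background, Otsu
    threshold, watershed split of touching nuclei, size filter."""
    img = ndimage.gaussian_filter(np.asarray(nuclei_image, dtype=float),
                                  smooth_sigma)
    img = img - np.median(img)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=int)
    mask = img > filters.threshold_otsu(img)
    if not mask.any():
        return np.zeros(img.shape, dtype=int)
    dist = distance_transform_edt(mask)
    from skimage.feature import peak_local_max

    seeds_xy = peak_local_max(dist, min_distance=7, labels=mask,
                              exclude_border=False)
    seeds = np.zeros(mask.shape, dtype=int)
    for i, (r, c) in enumerate(seeds_xy, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        seeds = measure.label(mask)
    labels = segmentation.watershed(-dist, seeds, mask=mask)
    out = np.zeros_like(labels)
    nxt = 1
    for rp in measure.regionprops(labels):
        if rp.area >= min_area_px:
            out[labels == rp.label] = nxt
            nxt += 1
    return out


def oppuro_cell_intensity(opp_stack: np.ndarray, nuclei_image: np.ndarray,
                          **segment_kwargs) -> dict[int, float]:
    """Per-cell nascent-translation intensity: for each nucleus mask, the
    mean OPP intensity per z-slice, maximized over z.

    ``opp_stack`` is (Z, Y, X) (a single 2D plane is promoted).
    """
    opp = np.asarray(opp_stack, dtype=float)
    if opp.ndim == 2:
        opp = opp[None]
    labels = segment_nuclei(nuclei_image, **segment_kwargs)
    out: dict[int, float] = {}
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        per_z = opp[:, mask].mean(axis=1)
        out[lab] = float(per_z.max())
    return out


def pla_count(stack: np.ndarray, cell_masks: np.ndarray,
              detect_kwargs: dict | None = None,
              localize_kwargs: dict | None = None) -> dict[int, int]:
    """Per-cell puncta counts from a z-stack: per-plane detection and
    localization, 3D deduplication across planes, assignment of each spot to
    the mask containing its rounded centroid.

    ``cell_masks`` is a label image (0 = background); disjoint by construction.
    """
    from .puncta import assign_z, detect_spots, localize_gaussian

    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    masks = np.asarray(cell_masks)
    detect_kwargs = detect_kwargs or {}
    localize_kwargs = localize_kwargs or {}
    per_plane = []
    for z in range(stack.shape[0]):
        cand = detect_spots(stack[z], **detect_kwargs)
        spots = [s for s in localize_gaussian(stack[z], cand, z_index=z,
                                              **localize_kwargs) if s.fit_ok]
        per_plane.append(spots)
    spots3d = assign_z(per_plane)
    counts = {lab: 0 for lab in np.unique(masks) if lab != 0}
    for s in spots3d:
        r, c = int(round(s.y_px)), int(round(s.x_px))
        if 0 <= r < masks.shape[0] and 0 <= c < masks.shape[1]:
            lab = int(masks[r, c])
            if lab:
                counts[lab] = counts.get(lab, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# statistics


def ttest_two_tailed(sample_a, sample_b, equal_var: bool = True
                     ) -> tuple[float, float, float]:
    """Two-tailed two-sample t test; pooled-variance (Student's) by default,
    Welch's when ``equal_var=False``. Returns ``(t, df, p)``.

    Identical constant samples return (0, df, 1) by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2 if equal_var else np.nan
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = (len(a) + len(b) - 2) if equal_var else float(res.df)
    return float(res.statistic), float(df), float(res.pvalue)
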