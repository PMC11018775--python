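"""Condensate segmentation and single-molecule spot detection/localization.

Spot amplitudes come in two flavors mirroring common practice: a fitted 2D
Gaussian amplitude (:func:`localize_gaussian`) and a blur-then-max-minus-min
window statistic (:func:`amplitude_maxmin`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage import filters, measure
from skimage.feature import peak_local_max

from .imgprep import bandpass, subtract_background_rolling_ball


@dataclass
class Spot:
    """Subpixel localization of a diffraction-limited punctum."""

    x_px: float
    y_px: float
    amplitude: float
    sigma_px: float
    offset: float
    fit_ok: bool
    z_index: int = 0
    channel: str = ""
    frame: int = 0
    n_planes: int = 1  # length of the z chain this spot was collapsed from


@dataclass
class CondensateRegion:
    """A labeled connected region with centroid and per-channel integrals."""

    label: int
    coords: np.ndarray  # (n, 2) row/col pixel indices
    centroid_y: float
    centroid_x: float
    area_px: int
    integrated_intensity: dict[str, float] = field(default_factory=dict)
    z_index: int = 0


def segment_condensates(image, blur_sigma: float = 2.0, bg_radius: float = 15,
                        threshold: str | float = "otsu", min_area_px: int = 4,
                        intensity_images: dict[str, np.ndarray] | None = None,
                        z_index: int = 0) -> list[CondensateRegion]:
    """Segment bright condensates in a 2D image.

    Pipeline: Gaussian blur -> rolling-ball background subtraction ->
    threshold (Otsu or absolute) -> 4-connected components -> area filter.
    Integrated intensities are summed on the *original* images (the input
    by default, plus any extra channels in ``intensity_images``) within the
    mask.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment_condensates works per 2D plane")
    work = ndimage.gaussian_filter(image, blur_sigma)
    work = subtract_background_rolling_ball(work, bg_radius)
    if threshold == "otsu":
        if np.ptp(work) == 0:
            return []
        thr = filters.threshold_otsu(work)
    else:
        thr = float(threshold)
    mask = work > thr
    labels = measure.label(mask, connectivity=1)
    channels = {"default": image}
    if intensity_images:
        channels.update({k: np.asarray(v, dtype=float) for k, v in intensity_images.items()})
    regions = []
    for rp in measure.regionprops(labels):
        if rp.area < min_area_px:
            continue
        rr, cc = rp.coords[:, 0], rp.coords[:, 1]
        regions.append(CondensateRegion(
            label=rp.label, coords=rp.coords,
            centroid_y=rp.centroid[0], centroid_x=rp.centroid[1],
            area_px=int(rp.area), z_index=z_index,
            integrated_intensity={k: float(v[rr, cc].sum())
                                  for k, v in channels.items()}))
    return regions


def detect_spots(image, low_sigma: float = 1.0, high_sigma: float = 3.0,
                 k: float = 5.0, min_separation_px: int = 2) -> np.ndarray:
    """Candidate spot pixels: local maxima of the (unclamped) DoG band-passed
    image above ``median + k * MAD``, with brighter-wins minimum separation.

    Returns an (n, 2) array of (row, col) integer candidates.
    """
    if k <= 0:
        raise ValueError("threshold factor k must be > 0")
    image = np.asarray(image, dtype=float)
    bp = bandpass(image, low_sigma, high_sigma, clip=False)
    med = np.median(bp)
    mad = np.median(np.abs(bp - med))
    if mad == 0:
        mad = bp.std() / 1.4826 if bp.std() > 0 else 0.0
    thr = med + k * 1.4826 * mad
    if np.ptp(bp) == 0:
        return np.empty((0, 2), dtype=int)
    peaks = peak_local_max(bp, min_distance=min_separation_px,
                           threshold_abs=thr, exclude_border=False)
    return peaks


def _gauss2d(params, yy, xx):
    a, y0, x0, s, c = params
    return a * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * s * s)) + c


def localize_gaussian(image, candidates, window: int = 9,
                      sigma_bounds: tuple[float, float] = (0.5, 4.0),
                      channel: str = "", z_index: int = 0,
                      frame: int = 0) -> list[Spot]:
    """Least-squares isotropic 2D Gaussian fit (amplitude, x, y, sigma,
    offset) in a ``window`` x ``window`` region around each candidate.

    ``fit_ok`` is False when the fit does not converge, sigma leaves
    ``sigma_bounds``, or the amplitude is non-positive. Candidates whose
    window falls off the image edge are skipped (flagged not-ok).
    """
    if window % 2 == 0 or window < 7:
        raise ValueError("window must be odd and >= 7")
    image = np.asarray(image, dtype=float)
    half = window // 2
    ny, nx = image.shape
    spots: list[Spot] = []
    for r, c in np.asarray(candidates, dtype=int).reshape(-1, 2):
        if not (half <= r < ny - half and half <= c < nx - half):
            spots.append(Spot(x_px=float(c), y_px=float(r), amplitude=0.0,
                              sigma_px=np.nan, offset=np.nan, fit_ok=False,
                              z_index=z_index, channel=channel, frame=frame))
            continue
        win = image[r - half:r + half + 1, c - half:c + half + 1]
        yy, xx = np.mgrid[r - half:r + half + 1, c - half:c + half + 1].astype(float)
        offset0 = float(win.min())
        amp0 = float(win.max() - offset0)
        p0 = np.array([max(amp0, 1e-6), float(r), float(c), 1.2, offset0])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.least_squares(
                    lambda p: (_gauss2d(p, yy, xx) - win).ravel(), p0,
                    bounds=([0, r - half, c - half, 0.1, -np.inf],
                            [np.inf, r + half, c + half, window, np.inf]),
                    max_nfev=2000)
            a, y0, x0, s, off = res.x
            # amplitudes indistinguishable from zero mean no peak was found
            ok = (res.success and a > 1e-3
                  and sigma_bounds[0] <= s <= sigma_bounds[1])
        except Exception:
            a, y0, x0, s, off, ok = amp0, float(r), float(c), np.nan, offset0, False
        spots.append(Spot(x_px=float(x0), y_px=float(y0), amplitude=float(a),
                          sigma_px=float(s), offset=float(off), fit_ok=bool(ok),
                          z_index=z_index, channel=channel, frame=frame))
    return spots


def amplitude_maxmin(image, spot: Spot, blur_sigma: float = 1.0,
                     window: int = 9, _blurred: np.ndarray | None = None) -> float:
    """Window amplitude statistic: max - min of the sigma-blurred image over
    the ``window`` x ``window`` region centered on the rounded spot position.

    When two puncta share a window the value reflects the brighter peak —
    a documented bias of this statistic. Pass a precomputed ``_blurred``
    image to amortize the blur over many spots.
    """
    image = np.asarray(image, dtype=float)
    blurred = (_blurred if _blurred is not None
               else ndimage.gaussian_filter(image, blur_sigma))
    half = window // 2
    r, c = int(round(spot.y_px)), int(round(spot.x_px))
    r0, r1 = max(0, r - half), min(image.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(image.shape[1], c + half + 1)
    win = blurred[r0:r1, c0:c1]
    return float(win.max() - win.min())


def assign_z(spot_lists: list[list[Spot]], max_xy_link_px: float = 2.0) -> list[Spot]:
    """Collapse per-plane detections of the same punctum to a single 3D spot.

    Spots in adjacent planes within ``max_xy_link_px`` (nearest neighbor,
    greedy by distance) are chained; each chain is reduced to the member
    with maximal amplitude (ties -> lower plane index). ``n_planes`` records
    chain length.
    """
    chains: list[list[Spot]] = []
    open_chains: list[list[Spot]] = []
    for plane_idx, plane in enumerate(spot_lists):
        plane = [s for s in plane]
        for s in plane:
            s.z_index = plane_idx
        next_open: list[list[Spot]] = []
        if open_chains and plane:
            tails = np.array([[ch[-1].y_px, ch[-1].x_px] for ch in open_chains])
            heads = np.array([[s.y_px, s.x_px] for s in plane])
            d = np.linalg.norm(tails[:, None] - heads[None, :], axis=2)
            used_chain, used_spot = set(), set()
            for idx in np.argsort(d, axis=None):
                i, j = np.unravel_index(idx, d.shape)
                if d[i, j] > max_xy_link_px:
                    break
                if i in used_chain or j in used_spot:
                    continue
                open_chains[i].append(plane[j])
                used_chain.add(i)
                used_spot.add(j)
            next_open = [ch for i, ch in enumerate(open_chains) if i in used_chain]
            chains.extend(ch for i, ch in enumerate(open_chains) if i not in used_chain)
            plane = [s for j, s in enumerate(plane) if j not in used_spot]
        else:
            chains.extend(open_chains)
        for s in plane:
            next_open.append([s])
        open_chains = next_open
    chains.extend(open_chains)

    out: list[Spot] = []
    for ch in chains:
        best = max(ch, key=lambda s: (s.amplitude, -s.z_index))
        best.n_planes = len(ch)
        out.append(best)
    return out


def collapse_regions_z(regions_per_plane: list[list[CondensateRegion]],
                       max_xy_link_px: float = 3.0) -> list[CondensateRegion]:
    """Collapse per-plane segmentations of the same 3D object to the plane
    where its integrated intensity is maximal (ties -> lower plane).

    Regions in adjacent planes are chained by centroid nearest neighbor
    within ``max_xy_link_px``, mirroring :func:`assign_z` for spots; the
    surviving region keeps its own label/coords and is relabeled 0..n-1.
    """
    chains: list[list[CondensateRegion]] = []
    open_chains: list[list[CondensateRegion]] = []
    for plane in regions_per_plane:
        plane = list(plane)
        next_open: list[list[CondensateRegion]] = []
        if open_chains and plane:
            tails = np.array([[ch[-1].centroid_y, ch[-1].centroid_x]
                              for ch in open_chains])
            heads = np.array([[r.centroid_y, r.centroid_x] for r in plane])
            d = np.linalg.norm(tails[:, None] - heads[None, :], axis=2)
            used_chain, used_region = set(), set()
            for idx in np.argsort(d, axis=None):
                i, j = np.unravel_index(idx, d.shape)
                if d[i, j] > max_xy_link_px:
                    break
                if i in used_chain or j in used_region:
                    continue
                open_chains[i].append(plane[j])
                used_chain.add(i)
                used_region.add(j)
            next_open = [ch for i, ch in enumerate(open_chains) if i in used_chain]
            chains.extend(ch for i, ch in enumerate(open_chains)
                          if i not in used_chain)
            plane = [r for j, r in enumerate(plane) if j not in used_region]
        else:
            chains.extend(open_chains)
        for r in plane:
            next_open.append([r])
        open_chains = next_open
    chains.extend(open_chains)

    def _total(r: CondensateRegion) -> float:
        return sum(r.integrated_intensity.values())

    out = []
    for new_label, ch in enumerate(chains):
        best = max(ch, key=lambda r: (_total(r), -r.z_index))
        best.label = new_label
        out.append(best)
    return out


def condensate_intensity_timecourse(movie, channel_index: int = 0,
                                    **segment_kwargs) -> np.ndarray:
    """Per-frame sum of integrated intensities over all segmented condensates.

    ``movie`` is a (T, Y, X) array or an ImageStack with a T axis (and
    optionally a C axis, selected by ``channel_index``).
    """
    from .core import ImageStack

    if isinstance(movie, ImageStack):
        px = movie.channel(channel_index) if "C" in movie.axes else movie.pixels
    else:
        px = np.asarray(movie, dtype=float)
    if px.ndim != 3:
        raise ValueError("movie must be (T, Y, X)")
    trace = np.zeros(px.shape[0])
    for t in range(px.shape[0]):
        regions = segment_condensates(px[t], **segment_kwargs)
        trace[t] = sum(r.integrated_intensity["default"] for r in regions)
    return trace


def spots_to_table(spots: list[Spot]):
    """Spot list as a pandas DataFrame with the standard column set."""
    import pandas as pd

    return pd.DataFrame([{
        "channel": s.channel, "frame": s.frame, "z_index": s.z_index,
        "x_px": s.x_px, "y_px": s.y_px, "amplitude": s.amplitude,
        "sigma_px": s.sigma_px, "offset": s.offset, "fit_ok": s.fit_ok,
    } for s in spots])
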