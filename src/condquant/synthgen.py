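"""Synthetic microscopy data with known ground truth.

Every generator takes an explicit integer seed and draws from a single
``numpy.random.default_rng`` stream, so identical seed + config yields
bit-identical output. Optics and noise defaults are conventions (the
experiments these emulate do not pin down camera pixel size or gain);
everything is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack

# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class OpticsConfig:
    """Imaging geometry: pixel pitch, z sampling, PSF width, frame timing."""

    pixel_size_nm: float = 110.0
    z_step_um: float = 0.5
    psf_sigma_nm: float = 130.0
    frame_interval_s: float = 0.05
    channel_offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.pixel_size_nm, self.z_step_um, self.psf_sigma_nm) <= 0:
            raise ValueError("lengths must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.psf_sigma_nm < self.pixel_size_nm / 4:
            raise ValueError("psf_sigma_nm must be >= pixel_size_nm / 4")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm


@dataclass(frozen=True)
class NoiseConfig:
    """Camera/illumination noise model.

    Detected value = Poisson(clean * gain) / gain + N(0, read_noise_sd),
    on top of ``background_level`` and an optional multiplicative
    flat-field gradient of relative amplitude ``flatfield_amplitude``.
    """

    photon_gain: float = 1.0
    read_noise_sd: float = 2.0
    background_level: float = 100.0
    flatfield_amplitude: float = 0.0
    bleach_rate_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_gain <= 0:
            raise ValueError("photon_gain must be > 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if not 0 <= self.flatfield_amplitude < 1:
            raise ValueError("flatfield_amplitude must be in [0, 1)")


@dataclass(frozen=True)
class ReporterConfig:
    half_life_h: float = 6.0
    inhibition_alpha: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if not 0 <= self.inhibition_alpha <= 1:
            raise ValueError("inhibition_alpha must be in [0, 1]")


@dataclass
class SceneTruth:
    """Generator ground truth against which estimators are scored."""

    seed: int
    condensates: list[dict] = field(default_factory=list)
    mrnas: list[dict] = field(default_factory=list)
    recruitment_fraction_true: float | None = None
    D_true: dict[str, float] | None = None
    mobile_fraction_true: float | None = None
    csat_true: float | None = None
    chi: np.ndarray | None = None
    # per-frame arrays for movies: positions (n, T, 2) px, bound (n, T) bool
    mrna_positions: np.ndarray | None = None
    condensate_positions: np.ndarray | None = None
    bound_state: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rendering primitives


def add_gaussian_2d(image: np.ndarray, y: float, x: float, amplitude: float,
                    sigma: float, truncate: float = 5.0) -> None:
    """Accumulate a 2D Gaussian peak into ``image`` in place (patch-based)."""
    if amplitude == 0:
        return
    h, w = image.shape
    r = int(np.ceil(truncate * sigma))
    y0, y1 = max(0, int(np.floor(y)) - r), min(h, int(np.floor(y)) + r + 1)
    x0, x1 = max(0, int(np.floor(x)) - r), min(w, int(np.floor(x)) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1, dtype=float)[:, None]
    xx = np.arange(x0, x1, dtype=float)[None, :]
    image[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * sigma * sigma)
    )


def _z_envelope(z_planes: np.ndarray, z_center: float, sigma_z_planes: float) -> np.ndarray:
    return np.exp(-((z_planes - z_center) ** 2) / (2.0 * sigma_z_planes ** 2))


def render_spots_3d(shape_zyx: tuple[int, int, int], spots: list[dict],
                    sigma_px: float, sigma_z_planes: float = 0.7) -> np.ndarray:
    """Render diffraction-limited spots as per-plane 2D Gaussians with a
    Gaussian amplitude envelope along z."""
    nz, ny, nx = shape_zyx
    out = np.zeros(shape_zyx, dtype=float)
    zz = np.arange(nz, dtype=float)
    for s in spots:
        env = _z_envelope(zz, s["z"], sigma_z_planes)
        for k in np.nonzero(env > 1e-3)[0]:
            add_gaussian_2d(out[k], s["y"], s["x"], s["amplitude"] * env[k], sigma_px)
    return out


def render_sphere(volume: np.ndarray, z: float, y: float, x: float,
                  radius: float, value: float) -> float:
    """Add a filled sphere (index-space radius) to ``volume``; returns the
    clean integrated intensity actually deposited."""
    nz, ny, nx = volume.shape
    r = int(np.ceil(radius)) + 1
    z0, z1 = max(0, int(z) - r), min(nz, int(z) + r + 1)
    y0, y1 = max(0, int(y) - r), min(ny, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(nx, int(x) + r + 1)
    zz = np.arange(z0, z1, dtype=float)[:, None, None]
    yy = np.arange(y0, y1, dtype=float)[None, :, None]
    xx = np.arange(x0, x1, dtype=float)[None, None, :]
    d = np.sqrt((zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2)
    # anti-aliased edge: linear partial-volume weight over one voxel, so the
    # deposited volume varies smoothly with radius (no voxelization jumps)
    weight = np.clip(radius - d + 0.5, 0.0, 1.0)
    volume[z0:z1, y0:y1, x0:x1] += value * weight
    return float(value * weight.sum())


def apply_noise(clean: np.ndarray, noise: NoiseConfig, rng: np.random.Generator,
                frame_index: int = 0, flatfield: np.ndarray | None = None) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise on background + signal.

    Bleaching scales the signal (not the background) by
    ``exp(-bleach_rate * frame)``. ``flatfield`` multiplies signal and
    background (illumination non-uniformity).
    """
    signal = clean * np.exp(-noise.bleach_rate_per_frame * frame_index)
    expected = signal + noise.background_level
    if flatfield is not None:
        expected = expected * flatfield
    photons = rng.poisson(np.maximum(expected, 0) * noise.photon_gain)
    out = photons / noise.photon_gain
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    return out


def make_flatfield(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative gradient with mean ~1 and relative range ``amplitude``."""
    ny, nx = shape
    yy = np.linspace(-1, 1, ny)[:, None]
    xx = np.linspace(-1, 1, nx)[None, :]
    g = 1.0 + 0.5 * amplitude * (xx + 0.5 * yy)
    return g / g.mean()


# ---------------------------------------------------------------------------
# scene generators


def _sample_separated(rng: np.random.Generator, n: int, lo: np.ndarray,
                      hi: np.ndarray, min_sep: float,
                      existing: np.ndarray | None = None,
                      reject=None, max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample ``n`` points in the box [lo, hi) with pairwise xy
    separation >= min_sep (also vs ``existing``); ``reject(p)`` may veto."""
    pts: list[np.ndarray] = []
    base = existing if existing is not None and len(existing) else np.empty((0, 2))
    for _ in range(max_tries):
        if len(pts) == n:
            break
        p = lo + rng.random(2) * (hi - lo)
        if reject is not None and reject(p):
            continue
        all_pts = np.vstack([base] + [np.asarray(pts)]) if pts else base
        if len(all_pts) and np.min(np.hypot(*(all_pts - p).T)) < min_sep:
            continue
        pts.append(p)
    if len(pts) < n:
        raise RuntimeError("could not place points with requested separation; "
                           "reduce density or min_sep")
    return np.asarray(pts)


def make_fish_scene(n_condensates: int, n_mrnas: int, recruitment_p: float,
                    optics: OpticsConfig = OpticsConfig(),
                    noise: NoiseConfig = NoiseConfig(),
                    seed: int = 0, *,
                    shape_yx: tuple[int, int] = (256, 256),
                    n_planes: int = 7,
                    condensate_radius_px: float = 3.0,
                    condensate_intensity: float = 300.0,
                    mrna_amplitude: tuple[float, float] = (150.0, 250.0),
                    recruit_radius_nm: float = 330.0,
                    min_spot_sep_px: float = 2.5) -> tuple[ImageStack, SceneTruth]:
    """Two-channel smFISH-like z-stack: condensates (channel 0) plus mRNA
    spots (channel 1), with per-molecule recruitment ground truth.

    Each mRNA is recruited with probability ``recruitment_p``: placed within
    ``0.8 * recruit_radius`` (planar) and one z-step of a uniformly chosen
    condensate centroid. Non-recruited mRNAs are placed farther than twice
    the recruitment radius from every condensate, so truth labels stay
    unambiguous under the downstream distance classifier. All mRNAs keep a
    minimum pairwise planar separation so detection does not merge them.
    """
    if n_condensates < 0 or n_mrnas < 0:
        raise ValueError("counts must be >= 0")
    if not 0 <= recruitment_p <= 1:
        raise ValueError("recruitment_p must be in [0, 1]")
    if n_condensates == 0 and recruitment_p > 0:
        raise ValueError("cannot recruit mRNAs with zero condensates")
    rng = np.random.default_rng(seed)
    ny, nx = shape_yx
    margin = 12.0
    lo = np.array([margin, margin])
    hi = np.array([ny - margin, nx - margin])
    recruit_r_px = recruit_radius_nm / optics.pixel_size_nm

    cond_xy = (_sample_separated(rng, n_condensates, lo, hi,
                                 min_sep=4 * recruit_r_px + 2 * condensate_radius_px)
               if n_condensates else np.empty((0, 2)))
    cond_z = rng.integers(1, max(2, n_planes - 1), size=n_condensates).astype(float)

    clean_cond = np.zeros((n_planes, ny, nx))
    condensates = []
    for i in range(n_condensates):
        integ = render_sphere(clean_cond, cond_z[i], cond_xy[i, 0], cond_xy[i, 1],
                              condensate_radius_px, condensate_intensity)
        condensates.append({
            "x": cond_xy[i, 1], "y": cond_xy[i, 0], "z": cond_z[i],
            "radius_px": condensate_radius_px,
            "intensity": {"cond": condensate_intensity, "fish": 0.0},
            "clean_integrated": integ,
        })

    recruited_flags = rng.random(n_mrnas) < recruitment_p
    mrnas: list[dict] = []
    placed_yxz = np.empty((0, 3))

    def _sep_ok(p, z):
        # pairs within two z-planes interact through the z-envelope tails
        # (same-plane peaks merge under the detection band-pass; tails at the
        # intermediate plane can bridge z-chains), so they need the full
        # separation; pairs three or more planes apart do not compete
        if len(placed_yxz) == 0:
            return True
        d_xy = np.hypot(placed_yxz[:, 0] - p[0], placed_yxz[:, 1] - p[1])
        dz = np.abs(placed_yxz[:, 2] - z)
        need = np.where(dz <= 2, min_spot_sep_px + 1.7, 2.2)
        return bool(np.all(d_xy >= need))

    # recruited mRNAs occupy slots on a ring inside the recruitment radius:
    # three slots at 120 degrees keep pairwise separation above the detection
    # merge distance, which random rejection cannot achieve in so small a disc
    slot_r = recruit_r_px * 0.83
    slots: list[list[np.ndarray]] = []
    for j in range(n_condensates):
        rot = rng.uniform(0, 2 * np.pi)
        slots.append([cond_xy[j] + slot_r * np.array([np.sin(rot + a), np.cos(rot + a)])
                      for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)])

    for i in range(n_mrnas):
        amp = float(rng.uniform(*mrna_amplitude))
        if recruited_flags[i]:
            avail = [j for j in range(n_condensates) if slots[j]]
            if not avail:
                raise RuntimeError("recruited placement failed; increase "
                                   "n_condensates or the scene size")
            j = avail[int(rng.integers(len(avail)))]
            p = slots[j].pop(int(rng.integers(len(slots[j]))))
            p = p + rng.uniform(-0.15, 0.15, size=2)
            z = float(np.clip(cond_z[j] + rng.integers(-1, 2), 0, n_planes - 1))
        else:
            for _ in range(20000):
                p = lo + rng.random(2) * (hi - lo)
                z = float(rng.integers(1, max(2, n_planes - 1)))
                if (n_condensates
                        and np.min(np.hypot(*(cond_xy - p).T))
                        <= 2 * recruit_r_px + 2.0):
                    continue
                if _sep_ok(p, z):
                    break
            else:  # pragma: no cover - density guard
                raise RuntimeError("non-recruited placement failed; reduce density")
        placed_yxz = np.vstack([placed_yxz, [p[0], p[1], z]])
        mrnas.append({"x": p[1], "y": p[0], "z": z, "amplitude": amp,
                      "recruited": bool(recruited_flags[i])})

    clean_fish = render_spots_3d((n_planes, ny, nx),
                                 [{"x": m["x"], "y": m["y"], "z": m["z"],
                                   "amplitude": m["amplitude"]} for m in mrnas],
                                 sigma_px=optics.psf_sigma_px)

    ff = (make_flatfield((ny, nx), noise.flatfield_amplitude)
          if noise.flatfield_amplitude > 0 else None)
    pixels = np.stack([
        np.stack([apply_noise(clean_cond[k], noise, rng, flatfield=ff)
                  for k in range(n_planes)]),
        np.stack([apply_noise(clean_fish[k], noise, rng, flatfield=ff)
                  for k in range(n_planes)]),
    ])
    stack = ImageStack(pixels, "CZYX", pixel_size_nm=optics.pixel_size_nm,
                       z_step_um=optics.z_step_um,
                       channel_names=("cond", "fish"),
                       provenance=[f"make_fish_scene(seed={seed})"])
    truth = SceneTruth(seed=seed, condensates=condensates, mrnas=mrnas,
                       recruitment_fraction_true=(
                           float(np.mean(recruited_flags)) if n_mrnas else None))
    return stack, truth


def simulate_tracks(n_tracks: int, D_um2_s: float, frame_interval_s: float,
                    n_frames: int, pixel_size_nm: float, seed: int,
                    loc_noise_px: float = 0.0) -> np.ndarray:
    """Pure Brownian 2D trajectories in pixel units, shape (n, T, 2).

    Per-axis step variance is ``2 D dt`` (so 4 D dt summed over x and y).
    """
    if D_um2_s < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    px_um = pixel_size_nm / 1000.0
    step_sd_px = np.sqrt(2.0 * D_um2_s * frame_interval_s) / px_um
    steps = rng.normal(0.0, step_sd_px, size=(n_tracks, n_frames - 1, 2))
    pos = np.concatenate([np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if loc_noise_px > 0:
        pos = pos + rng.normal(0.0, loc_noise_px, size=pos.shape)
    return pos


def make_live_movie(n_mrnas: int, D_mrna: float, D_condensate: float,
                    binding: tuple[float, float, float] = (0.0, 0.0, 400.0),
                    optics: OpticsConfig = OpticsConfig(),
                    noise: NoiseConfig = NoiseConfig(),
                    n_frames: int = 100, seed: int = 0, *,
                    n_condensates: int = 3,
                    shape_yx: tuple[int, int] = (128, 128),
                    mrna_amplitude: float = 200.0,
                    condensate_amplitude: float = 400.0,
                    condensate_sigma_px: float = 2.5,
                    render: bool = True) -> tuple[ImageStack | None, SceneTruth]:
    """Two-channel live movie of diffusing mRNAs and condensates with
    telegraph-style binding.

    Within ``capture_radius`` of a condensate an unbound mRNA binds at rate
    ``k_on`` (per second); a bound mRNA unbinds at ``k_off`` and while bound
    follows the motion of its condensate. The truth logs per-frame positions
    and the bound state.
    """
    if D_mrna < 0 or D_condensate < 0:
        raise ValueError("diffusion coefficients must be >= 0")
    k_on, k_off, capture_radius_nm = binding
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be >= 0")
    if optics.frame_interval_s is None or optics.frame_interval_s <= 0:
        raise ValueError("frame_interval_s required")
    rng = np.random.default_rng(seed)
    ny, nx = shape_yx
    dt = optics.frame_interval_s
    px_um = optics.pixel_size_nm / 1000.0
    cap_px = capture_radius_nm / optics.pixel_size_nm
    sd_m = np.sqrt(2 * D_mrna * dt) / px_um
    sd_c = np.sqrt(2 * D_condensate * dt) / px_um
    p_on = 1.0 - np.exp(-k_on * dt)
    p_off = 1.0 - np.exp(-k_off * dt)

    cond = rng.uniform([0.2 * ny, 0.2 * nx], [0.8 * ny, 0.8 * nx],
                       size=(n_condensates, 2))
    mrna = rng.uniform([0.1 * ny, 0.1 * nx], [0.9 * ny, 0.9 * nx],
                       size=(n_mrnas, 2))
    cond_pos = np.zeros((n_condensates, n_frames, 2))
    mrna_pos = np.zeros((n_mrnas, n_frames, 2))
    bound = np.zeros((n_mrnas, n_frames), dtype=bool)
    partner = np.full(n_mrnas, -1)

    for t in range(n_frames):
        cond_step = rng.normal(0, sd_c, size=(n_condensates, 2)) if sd_c > 0 else 0
        if t > 0:
            cond = cond + cond_step
        cond_pos[:, t] = cond
        for i in range(n_mrnas):
            if t > 0:
                if partner[i] >= 0:
                    mrna[i] = mrna[i] + (cond_step[partner[i]]
                                         if np.ndim(cond_step) else 0)
                elif sd_m > 0:
                    mrna[i] = mrna[i] + rng.normal(0, sd_m, size=2)
            # state update after the move, based on current geometry
            if partner[i] >= 0:
                if rng.random() < p_off:
                    partner[i] = -1
            else:
                d = np.hypot(*(cond - mrna[i]).T) if n_condensates else np.array([np.inf])
                j = int(np.argmin(d)) if n_condensates else -1
                if n_condensates and d[j] < cap_px and rng.random() < p_on:
                    partner[i] = j
            mrna_pos[i, t] = mrna[i]
            bound[i, t] = partner[i] >= 0

    stack = None
    if render:
        frames = np.zeros((2, n_frames, ny, nx))
        for t in range(n_frames):
            clean_c = np.zeros((ny, nx))
            clean_m = np.zeros((ny, nx))
            for j in range(n_condensates):
                add_gaussian_2d(clean_c, *cond_pos[j, t], condensate_amplitude,
                                condensate_sigma_px)
            for i in range(n_mrnas):
                add_gaussian_2d(clean_m, *mrna_pos[i, t], mrna_amplitude,
                                optics.psf_sigma_px)
            frames[0, t] = apply_noise(clean_c, noise, rng, frame_index=t)
            frames[1, t] = apply_noise(clean_m, noise, rng, frame_index=t)
        stack = ImageStack(frames, "CTYX", pixel_size_nm=optics.pixel_size_nm,
                           frame_interval_s=dt, channel_names=("cond", "mrna"),
                           provenance=[f"make_live_movie(seed={seed})"])
    truth = SceneTruth(seed=seed, D_true={"mrna": D_mrna, "condensate": D_condensate},
                       mrna_positions=mrna_pos, condensate_positions=cond_pos,
                       bound_state=bound,
                       extras={"k_on": k_on, "k_off": k_off,
                               "capture_radius_nm": capture_radius_nm})
    return stack, truth


def make_frap_trace(mobile_fraction: float, tau_s: float, pre_frames: int = 10,
                    noise_sd: float = 0.0, seed: int = 0, *,
                    bleach_depth: float = 0.3, n_post: int = 200,
                    frame_interval_s: float = 1.0):
    """FRAP time series: pre-bleach plateau at 1, bleach to ``bleach_depth``,
    recovery ``b + (1-b) * M * (1 - exp(-t/tau))`` plus Gaussian noise.

    Returns ``(times_s, values, pre_frames, bleach_index)``.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    if pre_frames <= 0:
        raise ValueError("pre_frames must be >= 1 (normalization undefined)")
    rng = np.random.default_rng(seed)
    b = bleach_depth
    t_post = np.arange(n_post) * frame_interval_s
    post = b + (1 - b) * mobile_fraction * (1 - np.exp(-t_post / tau_s))
    values = np.concatenate([np.ones(pre_frames), post])
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=values.size)
    times = np.arange(values.size) * frame_interval_s
    return times, values, pre_frames, pre_frames


def make_reporter_traces(n_cells: int, cfg: ReporterConfig = ReporterConfig(),
                         duration_h: float = 12.0, seed: int = 0, *,
                         n_points: int = 25,
                         alphas: np.ndarray | None = None,
                         initial_range: tuple[float, float] = (50.0, 500.0)):
    """Per-cell reporter decay traces in absolute units.

    Normalized form is ``P(t)/P(0) = (1 - alpha) + alpha * 2**(-t/T_half)``:
    a fraction ``alpha`` of synthesis stops at t=0 and the corresponding
    protein pool decays with the stated half-life. Noise is multiplicative
    lognormal. Returns ``(times_h, traces)`` with traces shaped (n_cells, n_points).
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration_h, n_points)
    a = (np.full(n_cells, cfg.inhibition_alpha) if alphas is None
         else np.asarray(alphas, dtype=float))
    p0 = rng.uniform(*initial_range, size=n_cells)
    norm = (1 - a[:, None]) + a[:, None] * np.exp2(-t[None, :] / cfg.half_life_h)
    traces = p0[:, None] * norm
    if cfg.noise_sd > 0:
        traces = traces * rng.lognormal(0.0, cfg.noise_sd, size=traces.shape)
    return t, traces


def make_phase_scan(n_cells: int, csat: float = 100.0,
                    expression_dist: tuple[float, float] = (4.6, 0.5),
                    shift_with_mrna: float = 0.0, seed: int = 0, *,
                    with_mrna_fraction: float = 0.5,
                    edge_width: float = 0.04,
                    intensity_gain: float = 5.0,
                    intensity_noise: float = 0.05):
    """Per-cell phase-behavior scan around a saturation concentration.

    Cytoplasmic intensity c ~ lognormal(mu, sigma); a cell clusters with
    probability ``expit((ln c - ln csat_i) / edge_width)`` where
    ``csat_i = csat * (1 - shift_with_mrna)`` for with-mRNA cells.
    Condensate integrated intensity is ``gain * (c - csat_i)_+`` with
    multiplicative noise. Returns a pandas DataFrame.
    """
    import pandas as pd
    from scipy.special import expit

    if csat <= 0:
        raise ValueError("csat must be > 0")
    rng = np.random.default_rng(seed)
    mu, sigma = expression_dist
    c = rng.lognormal(mu, sigma, size=n_cells)
    with_mrna = rng.random(n_cells) < with_mrna_fraction
    csat_i = np.where(with_mrna, csat * (1 - shift_with_mrna), csat)
    p_clustered = expit((np.log(c) - np.log(csat_i)) / edge_width)
    clustered = rng.random(n_cells) < p_clustered
    intensity = np.where(
        clustered,
        intensity_gain * np.maximum(c - csat_i, 0.0)
        * rng.lognormal(0, intensity_noise, n_cells)
        + rng.uniform(0, 1, n_cells),
        rng.uniform(0, 1, n_cells))
    return pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "cytoplasmic_intensity": c,
        "with_mrna": with_mrna,
        "clustered": clustered,
        "condensate_total_intensity": intensity,
        "csat_true": csat_i,
    })


def make_spine_series(n_spines: int, radii_px: list[float],
                      growth_factor: float = 1.0,
                      optics: OpticsConfig = OpticsConfig(),
                      noise: NoiseConfig = NoiseConfig(),
                      seed: int = 0, *,
                      n_frames: int = 6, stim_frame: int = 3,
                      spacing_px: int = 28, n_planes: int = 16,
                      dendrite_radius_px: float = 2.5,
                      intensity: float = 400.0,
                      psf_blur_px: float = 1.0):
    """Time series of z-stacks with spherical 'spines' on a dendrite cylinder.

    After ``stim_frame`` every spine volume scales by ``growth_factor``
    (radius by its cube root). Truth volumes are exact voxel counts of the
    rendered spheres per frame. Returns ``(ImageStack TZYX, truth_volumes,
    roi_boxes)`` where roi_boxes are (z0, z1, y0, y1, x0, x1) slabs per spine.
    """
    from scipy.ndimage import gaussian_filter

    radii = np.asarray(radii_px, dtype=float)
    if len(radii) != n_spines:
        raise ValueError("radii_px must have n_spines entries")
    if np.any(radii < 2):
        raise ValueError("spine radii must be >= 2 px")
    rng = np.random.default_rng(seed)
    r_max = float(radii.max()) * growth_factor ** (1 / 3)
    if spacing_px < 2 * r_max + 4:
        raise ValueError("spines would overlap at this spacing")
    ny = int(2 * r_max + dendrite_radius_px * 2 + 24)
    nx = n_spines * spacing_px + 20
    zc, yc = n_planes // 2, ny - int(dendrite_radius_px) - 6
    xs = 10 + spacing_px * np.arange(n_spines) + spacing_px // 2

    frames = np.zeros((n_frames, n_planes, ny, nx))
    truth = np.zeros((n_spines, n_frames))
    roi_boxes = []
    for s in range(n_spines):
        r_big = radii[s] * growth_factor ** (1 / 3)
        yc_s = yc - dendrite_radius_px - r_big - 4
        half = int(np.ceil(r_big)) + 4
        # cap the box above the dendrite shaft so it holds only the spine
        y_top = int(yc - dendrite_radius_px - 2)
        roi_boxes.append((max(0, zc - half), min(n_planes, zc + half + 1),
                          max(0, int(yc_s) - half), min(y_top, int(yc_s) + half + 1),
                          max(0, xs[s] - half), min(nx, xs[s] + half + 1)))
    for t in range(n_frames):
        clean = np.zeros((n_planes, ny, nx))
        # dendrite shaft along x
        zz = np.arange(n_planes)[:, None]
        yy = np.arange(ny)[None, :]
        shaft = ((zz - zc) ** 2 + (yy - yc) ** 2) <= dendrite_radius_px ** 2
        clean += intensity * shaft[:, :, None]
        for s in range(n_spines):
            r = radii[s] * (growth_factor ** (1 / 3) if t >= stim_frame else 1.0)
            yc_s = yc - dendrite_radius_px - radii[s] * growth_factor ** (1 / 3) - 4
            vol = np.zeros((n_planes, ny, nx))
            render_sphere(vol, zc, yc_s, xs[s], r, 1.0)
            truth[s, t] = vol.sum()
            clean += intensity * vol
        clean = gaussian_filter(clean, (0, psf_blur_px, psf_blur_px))
        frames[t] = apply_noise(clean, noise, rng, frame_index=t)
    stack = ImageStack(frames, "TZYX", pixel_size_nm=optics.pixel_size_nm,
                       z_step_um=optics.z_step_um,
                       frame_interval_s=optics.frame_interval_s,
                       provenance=[f"make_spine_series(seed={seed})"])
    return stack, truth, roi_boxes


def make_bead_pair(n_beads: int, offset_px: tuple[float, float] = (0.0, 0.0),
                   optics: OpticsConfig = OpticsConfig(),
                   noise: NoiseConfig = NoiseConfig(),
                   seed: int = 0, *,
                   shape_yx: tuple[int, int] = (256, 256),
                   amplitude: float = 800.0) -> tuple[ImageStack, ImageStack]:
    """Same bead field rendered in two channels, the second shifted by
    ``offset_px`` (dy, dx). Used for channel-registration recovery."""
    if n_beads < 3:
        raise ValueError("need at least 3 beads for registration")
    rng = np.random.default_rng(seed)
    ny, nx = shape_yx
    pos = _sample_separated(rng, n_beads, np.array([20.0, 20.0]),
                            np.array([ny - 20.0, nx - 20.0]), min_sep=15.0)
    clean_a = np.zeros((ny, nx))
    clean_b = np.zeros((ny, nx))
    dy, dx = offset_px
    for y, x in pos:
        add_gaussian_2d(clean_a, y, x, amplitude, optics.psf_sigma_px)
        add_gaussian_2d(clean_b, y + dy, x + dx, amplitude, optics.psf_sigma_px)
    a = apply_noise(clean_a, noise, rng)
    b = apply_noise(clean_b, noise, rng)
    meta = dict(pixel_size_nm=optics.pixel_size_nm)
    return (ImageStack(a, "YX", **meta, provenance=[f"make_bead_pair(seed={seed})/ref"]),
            ImageStack(b, "YX", **meta, provenance=[f"make_bead_pair(seed={seed})/moving"]))
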