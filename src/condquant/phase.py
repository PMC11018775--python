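"""Saturation-concentration estimation and a ternary regular-solution
(Flory-Huggins) coexistence calculator.

Free energy per lattice site (units of kT), components 1 and 2 plus solvent
s with phi_s = 1 - phi1 - phi2:

    f = sum_i (phi_i / N_i) ln phi_i + phi_s ln phi_s
        + chi_12 phi1 phi2 + chi_1s phi1 phi_s + chi_2s phi2 phi_s

Coexistence is computed from the lower convex hull of f sampled on a simplex
grid: hull facets whose vertices are farther apart than a merge tolerance
are tie simplices; the lever rule on the containing facet gives phase
fractions. This is robust for ternary systems where common-tangent root
finding is fragile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import ConvexHull
from scipy.special import expit


@dataclass(frozen=True)
class RSParams:
    """chi is a symmetric 3x3 interaction matrix over (1, 2, solvent); N the
    polymerization sizes (N1, N2, Ns)."""

    chi: np.ndarray
    N: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        object.__setattr__(self, "chi", chi)
        if chi.shape != (3, 3) or not np.allclose(chi, chi.T):
            raise ValueError("chi must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(chi), 0):
            raise ValueError("chi diagonal must be zero")
        if any(n < 1 for n in self.N):
            raise ValueError("N >= 1 required")

    @classmethod
    def from_pairs(cls, chi12: float, chi1s: float, chi2s: float,
                   N: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> "RSParams":
        chi = np.array([[0.0, chi12, chi1s],
                        [chi12, 0.0, chi2s],
                        [chi1s, chi2s, 0.0]])
        return cls(chi=chi, N=N)


@dataclass
class CellPhaseRecord:
    cell_id: int
    c1: float
    clustered: bool
    condensate_total_intensity: float = 0.0
    c2: float | None = None


@dataclass
class CompositionRecord:
    condensate_id: int
    ratio: float
    weight: float = 0.0
    valid: bool = True


@dataclass
class CsatEstimate:
    csat: float
    width: float
    ci_low: float
    ci_high: float


@dataclass
class CoexistenceResult:
    n_phases: int
    phase_compositions: np.ndarray  # (n_phases, 2) of (phi1, phi2)
    phase_fractions: np.ndarray     # lever-rule fractions, sum to 1
    overall_phi: np.ndarray = field(default_factory=lambda: np.zeros(2))


# ---------------------------------------------------------------------------
# saturation concentration


def classify_clustered(condensate_total_intensity: float, floor: float) -> bool:
    """Cluster call: condensate signal above a blank-scene-derived floor."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    return condensate_total_intensity > floor


def _logistic_nll(params, ln_c, y):
    ln_csat, ln_w = params
    w = np.exp(ln_w)
    p = expit((ln_c - ln_csat) / w)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))


def estimate_csat(concentrations, clustered, n_boot: int = 1000,
                  seed: int = 0) -> CsatEstimate:
    """Maximum-likelihood logistic fit of P(clustered) against ln
    concentration; csat is the concentration at P = 0.5, with a bootstrap
    percentile CI.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(clustered, dtype=bool)
    if len(c) < 20:
        raise ValueError("need >= 20 cells spanning the transition")
    if y.all() or not y.any():
        raise ValueError("both clustered and non-clustered cells required")
    ln_c = np.log(c)

    def _fit(lc, yy):
        x0 = np.array([np.median(lc), np.log(0.1)])
        res = minimize(_logistic_nll, x0, args=(lc, yy), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        return res.x

    ln_csat, ln_w = _fit(ln_c, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(c), len(c))
        if y[idx].all() or not y[idx].any():
            continue
        boots.append(np.exp(_fit(ln_c[idx], y[idx])[0]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots
              else (np.nan, np.nan))
    return CsatEstimate(csat=float(np.exp(ln_csat)), width=float(np.exp(ln_w)),
                        ci_low=float(lo), ci_high=float(hi))


def csat_shift(conc_a, clust_a, conc_b, clust_b, n_boot: int = 200,
               seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Relative saturation-concentration change (csat_B - csat_A) / csat_A
    with a paired-bootstrap CI. Negative means B phase-separates at lower
    concentration than A."""
    est_a = estimate_csat(conc_a, clust_a, n_boot=0)
    est_b = estimate_csat(conc_b, clust_b, n_boot=0)
    shift = (est_b.csat - est_a.csat) / est_a.csat
    rng = np.random.default_rng(seed)
    conc_a, clust_a = np.asarray(conc_a), np.asarray(clust_a, dtype=bool)
    conc_b, clust_b = np.asarray(conc_b), np.asarray(clust_b, dtype=bool)
    boots = []
    for _ in range(n_boot):
        ia = rng.integers(0, len(conc_a), len(conc_a))
        ib = rng.integers(0, len(conc_b), len(conc_b))
        try:
            a = estimate_csat(conc_a[ia], clust_a[ia], n_boot=0).csat
            b = estimate_csat(conc_b[ib], clust_b[ib], n_boot=0).csat
        except ValueError:
            continue
        boots.append((b - a) / a)
    ci = (tuple(np.percentile(boots, [2.5, 97.5])) if boots
          else (np.nan, np.nan))
    return float(shift), ci


# ---------------------------------------------------------------------------
# condensate composition


def composition_ratio(regions_ch1, regions_ch2=None,
                      background: tuple[float, float] = (0.0, 0.0),
                      ch1: str = "ch1", ch2: str = "ch2"
                      ) -> tuple[list[CompositionRecord], float]:
    """Per-condensate channel-2 / channel-1 background-subtracted integrated
    intensity ratio, plus a channel-1-intensity-weighted cell mean.

    ``regions_ch1`` are CondensateRegions whose ``integrated_intensity``
    carries both channel keys (registered channels measured on one mask).
    Records with non-positive channel-1 integral are flagged and excluded
    from the summary.
    """
    records: list[CompositionRecord] = []
    for i, reg in enumerate(regions_ch1):
        i1 = reg.integrated_intensity[ch1] - background[0] * reg.area_px
        i2 = reg.integrated_intensity[ch2] - background[1] * reg.area_px
        if i1 <= 0:
            records.append(CompositionRecord(i, np.nan, 0.0, valid=False))
            continue
        records.append(CompositionRecord(i, max(i2, 0.0) / i1, i1, valid=True))
    valid = [r for r in records if r.valid]
    if valid:
        w = np.array([r.weight for r in valid])
        ratios = np.array([r.ratio for r in valid])
        mean_ratio = float((w * ratios).sum() / w.sum())
    else:
        mean_ratio = np.nan
    return records, mean_ratio


# ---------------------------------------------------------------------------
# regular-solution model


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def rs_free_energy(phi1, phi2, params: RSParams):
    """Mixing free energy per site in kT; accepts scalars or arrays.

    Uses the x ln x -> 0 limit at zero volume fractions. Raises for points
    outside the composition simplex.
    """
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    phis = 1.0 - phi1 - phi2
    if np.any(phi1 < 0) or np.any(phi2 < 0) or np.any(phis < -1e-12):
        raise ValueError("composition outside the simplex")
    phis = np.clip(phis, 0.0, 1.0)
    chi, (n1, n2, ns) = params.chi, params.N
    f = (_xlogx(phi1) / n1 + _xlogx(phi2) / n2 + _xlogx(phis) / ns
         + chi[0, 1] * phi1 * phi2 + chi[0, 2] * phi1 * phis
         + chi[1, 2] * phi2 * phis)
    return f if f.ndim else float(f)


def binary_binodal(chi: float, N: float = 1.0, grid_n: int = 2001
                   ) -> tuple[float, float] | None:
    """Miscibility gap of the binary (component 1 + solvent) system via the
    lower convex hull of f(phi) on a 1D grid.

    Returns (phi_dilute, phi_dense) or None when the free energy is convex
    (single phase everywhere).
    """
    params = RSParams.from_pairs(0.0, chi, 0.0, N=(N, 1.0, 1.0))
    phi = np.linspace(0.0, 1.0, grid_n)
    f = rs_free_energy(phi, np.zeros_like(phi), params)
    # Andrew monotone chain on (phi, f): keep the lower hull
    hull: list[int] = []
    for i in range(grid_n):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = ((phi[i2] - phi[i1]) * (f[i] - f[i1])
                     - (f[i2] - f[i1]) * (phi[i] - phi[i1]))
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = np.diff(phi[hull])
    widest = int(np.argmax(gaps))
    if gaps[widest] <= 2.5 * (phi[1] - phi[0]):
        return None
    return float(phi[hull[widest]]), float(phi[hull[widest + 1]])


def _simplex_grid(grid_n: int) -> np.ndarray:
    pts = []
    step = 1.0 / (grid_n - 1)
    for i in range(grid_n):
        for j in range(grid_n - i):
            pts.append((i * step, j * step))
    return np.asarray(pts)


def _lower_hull_facets(points_2d: np.ndarray, f: np.ndarray) -> list[np.ndarray]:
    """Simplices (index triples) of the lower convex hull of (x, y, f)."""
    pts3 = np.column_stack([points_2d, f])
    hull = ConvexHull(pts3, qhull_options="Qt")
    facets = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        if eq[2] < -1e-12:  # normal points downward -> lower hull facet
            facets.append(simplex)
    return facets


def rs_coexistence(params: RSParams, overall_phi, grid_n: int = 201,
                   merge_tol_cells: float = 2.5) -> CoexistenceResult:
    """Phase split of an overall composition on the ternary simplex.

    The lower convex hull of f on a uniform simplex grid is computed; the
    facet containing ``overall_phi`` is found, and facet vertices closer
    together than ``merge_tol_cells`` grid cells are merged into one phase.
    Lever-rule fractions are the barycentric coordinates of the overall
    composition in the facet.
    """
    if grid_n < 51:
        raise ValueError("grid_n must be >= 51")
    overall = np.asarray(overall_phi, dtype=float)
    if overall.min() < 0 or overall.sum() >= 1:
        raise ValueError("overall composition outside the simplex")
    pts = _simplex_grid(grid_n)
    f = rs_free_energy(pts[:, 0], pts[:, 1], params)
    facets = _lower_hull_facets(pts, f)
    cell = 1.0 / (grid_n - 1)

    # check facets nearest the overall point first: the containing facet's
    # centroid is close unless the point sits inside a wide tie simplex
    centroids = np.array([pts[s].mean(axis=0) for s in facets])
    order_f = np.argsort(np.linalg.norm(centroids - overall, axis=1))
    for fi in order_f:
        simplex = facets[fi]
        tri = pts[simplex]
        # barycentric coordinates of the overall point in this facet
        T = np.column_stack([tri[1] - tri[0], tri[2] - tri[0]])
        det = np.linalg.det(T)
        if abs(det) < 1e-15:
            continue
        lam12 = np.linalg.solve(T, overall - tri[0])
        lam = np.array([1 - lam12.sum(), lam12[0], lam12[1]])
        if np.all(lam >= -1e-9):
            lam = np.clip(lam, 0, None)
            lam = lam / lam.sum()
            # merge vertices closer than the tolerance into single phases
            groups: list[list[int]] = []
            for v in range(3):
                for g in groups:
                    if np.linalg.norm(tri[v] - tri[g[0]]) < merge_tol_cells * cell:
                        g.append(v)
                        break
                else:
                    groups.append([v])
            comps = np.array([
                np.average(tri[g], axis=0, weights=np.maximum(lam[g], 1e-12))
                for g in groups])
            fracs = np.array([lam[g].sum() for g in groups])
            order = np.argsort(-fracs)
            return CoexistenceResult(n_phases=len(groups),
                                     phase_compositions=comps[order],
                                     phase_fractions=fracs[order],
                                     overall_phi=overall)
    raise RuntimeError("no lower-hull facet contains the overall composition")


def predict_dense_composition(params: RSParams, overall_phi,
                              grid_n: int = 201) -> float:
    """phi2/phi1 ratio of the dense phase at a given overall composition.

    Raises ``ValueError`` in a single-phase region.
    """
    res = rs_coexistence(params, overall_phi, grid_n=grid_n)
    if res.n_phases < 2:
        raise ValueError("overall composition is in a single-phase region")
    totals = res.phase_compositions.sum(axis=1)
    dense = res.phase_compositions[np.argmax(totals)]
    if dense[0] <= 0:
        return np.inf if dense[1] > 0 else 0.0
    return float(dense[1] / dense[0])
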