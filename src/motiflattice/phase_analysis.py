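"""Histogram reweighting and phase-diagram extraction.

The workflow mirrors standard grand-canonical phase-equilibrium
practice for lattice models:

1. sample a joint histogram ``P(N, E)`` near the transition;
2. reweight it exactly to nearby ``(beta, mu)``;
3. locate the phase boundary ``mu*`` where the dilute and dense peaks
   of ``P(N)`` carry equal weight (peaks from a two-component Gaussian
   mixture fit);
4. locate the critical point by matching the distribution of the mixed
   order parameter ``M = N - x*E`` to the universal order-parameter
   distribution of the 3D Ising class, fitting the mixing parameter
   ``x`` along with ``(beta_c, mu_c)``;
5. walk the binodal to lower temperatures iteratively, building a
   multicanonical weight ``h(N)`` from the previous temperature's
   reweighted histogram so that the inter-phase barrier stays crossable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from .histograms import JointHistogram, MulticanonicalWeight
from .montecarlo import (GceResult, MoveMixture, RunParams,
                         build_multicanonical_weight, run_gce)

#: Binder cumulant <m^4>/<m^2>^2 of the 3D Ising class at criticality
ISING_U4 = 1.6036


class AboveCriticalError(RuntimeError):
    """P(N) is unimodal everywhere in the scan range."""


class OverlapError(RuntimeError):
    """Reweighting target is outside the trust region of the data."""


# ---------------------------------------------------------------------------
# reweighting

def reweight(hist: JointHistogram, beta1: float, mu1: float,
             h1: MulticanonicalWeight | None = None,
             ess_warn: float = 100.0) -> JointHistogram:
    """Exact reexpression of ``P(N, E)`` at nearby ``(beta1, mu1, h1)``.

    P~(N,E) ~ P(N,E) * exp(-(b1-b0)E + (b1 mu1 - b0 mu0)N
                           + b0 h0(N) - b1 h1(N)).

    The effective sample size of the reweighted histogram is reported in
    ``meta['ess']``; a warning is emitted when it falls below
    ``ess_warn``.
    """
    b0, m0 = hist.beta, hist.mu
    n = np.arange(hist.n_max + 1, dtype=float)
    e = hist.e_centers()
    h0t = hist.h_table()
    h1t = h1.table(hist.n_max) if h1 is not None else np.zeros(hist.n_max + 1)
    logf = (-(beta1 - b0) * e[None, :]
            + (beta1 * mu1 - b0 * m0) * n[:, None]
            + (b0 * h0t - beta1 * h1t)[:, None])
    mask = hist.counts > 0
    if not mask.any():
        raise ValueError("cannot reweight an empty histogram")
    logf = logf - logf[mask].max()
    w = np.where(mask, np.exp(np.minimum(logf, 500.0)), 0.0)
    new_counts = hist.counts * w
    tot_w = (hist.counts * w).sum()
    tot_w2 = (hist.counts * w * w).sum()
    ess = tot_w ** 2 / tot_w2 if tot_w2 > 0 else 0.0
    if ess < ess_warn:
        warnings.warn(
            f"reweighting to (beta={beta1:.4g}, mu={mu1:.4g}) has effective "
            f"sample size {ess:.1f}; the target is poorly covered",
            stacklevel=2)
    out = JointHistogram(new_counts, hist.e_min, hist.e_bin, beta1, mu1,
                         h=h1, total_sweeps=hist.total_sweeps,
                         meta=dict(hist.meta))
    out.meta["ess"] = float(ess)
    return out


# ---------------------------------------------------------------------------
# Gaussian-mixture peak extraction and the equal-weight boundary

@dataclass
class GaussianMixture1D:
    w: np.ndarray       # component weights (2,)
    mean: np.ndarray
    sd: np.ndarray

    @property
    def separation(self) -> float:
        """Ashman's D; > 2 indicates a clearly bimodal mixture."""
        return abs(self.mean[1] - self.mean[0]) * np.sqrt(
            2.0 / (self.sd[0] ** 2 + self.sd[1] ** 2))


def fit_two_gaussians(x: np.ndarray, weights: np.ndarray,
                      n_iter: int = 500, tol: float = 1e-10
                      ) -> GaussianMixture1D:
    """Weighted EM fit of a two-component Gaussian mixture.

    ``x`` are the support points (polymer numbers), ``weights`` the
    histogram masses.  Components are returned sorted by mean.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mean_all = float(w @ x)
    lo = x[x <= mean_all]
    hi = x[x >= mean_all]
    wlo, whi = w[x <= mean_all], w[x >= mean_all]
    m = np.array([float(wlo @ lo / wlo.sum()), float(whi @ hi / whi.sum())])
    sd_all = float(np.sqrt(w @ (x - mean_all) ** 2))
    s = np.array([max(sd_all / 2, 0.5)] * 2)
    pi = np.array([wlo.sum(), whi.sum()])
    prev = -np.inf
    for _ in range(n_iter):
        log_r = (np.log(np.maximum(pi, 1e-300))[:, None]
                 - 0.5 * ((x[None, :] - m[:, None]) / s[:, None]) ** 2
                 - np.log(s[:, None]))
        mx = log_r.max(axis=0)
        ll = float(w @ (mx + np.log(np.exp(log_r - mx).sum(axis=0))))
        r = np.exp(log_r - mx)
        r = r / r.sum(axis=0)
        for c in (0, 1):
            wc = w * r[c]
            tot = wc.sum()
            if tot < 1e-12:
                continue
            pi[c] = tot
            m[c] = float(wc @ x) / tot
            s[c] = max(np.sqrt(float(wc @ (x - m[c]) ** 2) / tot), 0.3)
        if abs(ll - prev) < tol:
            break
        prev = ll
    order = np.argsort(m)
    return GaussianMixture1D(pi[order], m[order], s[order])


@dataclass
class EqualWeightResult:
    mu_star: float
    phi_dilute: float
    phi_dense: float
    weights: tuple[float, float]
    mixture: GaussianMixture1D
    p_of_n: np.ndarray


def _hist_vl(hist: JointHistogram) -> tuple[int, int]:
    V = int(hist.meta["V"])
    L = len(str(hist.meta["sequence"]))
    return V, L


def equal_weight_mu(hist: JointHistogram, beta: float,
                    mu_window: float = 1.0, weight_tol: float = 1e-6,
                    min_separation: float = 1.8,
                    min_phi_gap: float = 0.05) -> EqualWeightResult:
    """Chemical potential at which the two phases have equal weight.

    Reweights ``hist`` to ``beta`` and root-finds the ``mu`` where the
    two fitted mixture components carry equal weight.  The phase
    densities are the component means converted to volume fractions.
    Raises :class:`AboveCriticalError` when no bimodal distribution is
    found anywhere in the scan window.
    """
    V, L = _hist_vl(hist)
    n = np.arange(hist.n_max + 1, dtype=float)
    # the mu dependence only multiplies each N-slice, so the energy axis
    # can be collapsed once at the target beta
    e = hist.e_centers()
    logf = (-(beta - hist.beta) * e[None, :]
            + (hist.beta * hist.h_table())[:, None])
    mask = hist.counts > 0
    logf -= logf[mask].max() if mask.any() else 0.0
    base = (hist.counts
            * np.where(mask, np.exp(np.minimum(logf, 500.0)), 0.0)
            ).sum(axis=1)
    logbase = np.where(base > 0, np.log(np.maximum(base, 1e-300)), -np.inf)

    def mixture_at(mu):
        logp = logbase + (beta * mu - hist.beta * hist.mu) * n
        logp -= logp.max()
        p = np.exp(logp)
        p = p / p.sum()
        return fit_two_gaussians(n, p + 1e-300), p

    def fvalue(mu):
        gm, _ = mixture_at(mu)
        return np.log(gm.w[1] / gm.w[0])

    mu0 = hist.mu
    # bracket the equal-weight point
    grid = mu0 + mu_window * np.linspace(-1, 1, 41)
    vals = []
    best = None
    for mu in grid:
        gm, p = mixture_at(mu)
        vals.append((mu, gm))
        if best is None or abs(np.log(gm.w[1] / gm.w[0])) < best[0]:
            best = (abs(np.log(gm.w[1] / gm.w[0])), mu, gm)
    bimodal = [(mu, gm) for mu, gm in vals
               if gm.separation > min_separation
               and (gm.mean[1] - gm.mean[0]) * L / V >= min_phi_gap]
    if not bimodal:
        raise AboveCriticalError(
            "P(N) is unimodal for every mu in the scan window; the system "
            "appears to be above its critical point")
    # pick the sign change whose endpoints are most strongly bimodal:
    # outside the genuine coexistence window the mixture fit degenerates
    # and produces spurious crossings
    mus = [mu for mu, _ in bimodal]
    fs = [np.log(gm.w[1] / gm.w[0]) for _, gm in bimodal]
    seps = [gm.separation for _, gm in bimodal]
    candidates = []
    for i in range(len(mus) - 1):
        if fs[i] == 0 or fs[i] * fs[i + 1] < 0:
            candidates.append((min(seps[i], seps[i + 1]),
                               (mus[i], mus[i + 1])))
    if not candidates:
        raise AboveCriticalError(
            "equal-weight point not bracketed inside the bimodal region; "
            "widen mu_window or simulate closer to the boundary")
    sign_change = max(candidates)[1]
    mu_star = brentq(fvalue, *sign_change, xtol=1e-10)
    gm, p = mixture_at(mu_star)
    if abs(gm.w[1] - gm.w[0]) > weight_tol:
        mu_star = brentq(fvalue, sign_change[0], sign_change[1], xtol=1e-14)
        gm, p = mixture_at(mu_star)
    return EqualWeightResult(
        mu_star=float(mu_star),
        phi_dilute=float(gm.mean[0] * L / V),
        phi_dense=float(gm.mean[1] * L / V),
        weights=(float(gm.w[0]), float(gm.w[1])),
        mixture=gm, p_of_n=p)


# ---------------------------------------------------------------------------
# universal order-parameter reference

# Standardized (unit-variance) order-parameter distribution of the 3D
# Ising universality class, in the double-peaked closed form
#     p(y) ~ exp(-(y^2/y0^2 - 1)^2 (a y^2/y0^2 + c))
# with the universal constants a = 0.158, c = 0.776 from the
# Tsypin-Bloete fit to the critical 3D Ising magnetization distribution.
_TB_A, _TB_C = 0.158, 0.776


def ising_reference_table(grid: np.ndarray) -> np.ndarray:
    """Universal reference interpolated from the shipped data asset.

    The asset (``data/ising3d_orderparam.tsv``) tabulates the
    standardized 3D-Ising order-parameter distribution; it can be
    replaced by any other tabulation of the same observable.  Falls
    back to the closed form when the asset is unavailable.
    """
    try:
        from importlib import resources
        with resources.files("motiflattice").joinpath(
                "data/ising3d_orderparam.tsv").open("rb") as fh:
            data = np.loadtxt(fh)
        return np.interp(grid, data[:, 0], data[:, 1], left=0.0, right=0.0)
    except (FileNotFoundError, OSError):  # pragma: no cover
        return ising_reference(grid)


def ising_reference(grid: np.ndarray) -> np.ndarray:
    """Universal 3D-Ising order-parameter density on ``grid`` (unit var)."""
    y = np.linspace(-6, 6, 4001)

    def raw(y, y0):
        u = (y / y0) ** 2
        return np.exp(-((u - 1.0) ** 2) * (_TB_A * u + _TB_C))

    # fix the peak position y0 so the standardized variance is one
    def variance(y0):
        p = raw(y, y0)
        p /= np.trapezoid(p, y)
        return np.trapezoid(p * y ** 2, y)

    lo, hi = 0.5, 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if variance(mid) < 1.0:
            lo = mid
        else:
            hi = mid
    y0 = 0.5 * (lo + hi)
    p = raw(grid, y0)
    norm = np.trapezoid(raw(y, y0), y)
    return p / norm


def double_gaussian_reference(grid: np.ndarray,
                              separation: float = 1.1) -> np.ndarray:
    """Symmetric double-Gaussian surrogate (smoke-test fallback)."""
    s = np.sqrt(max(1.0 - separation ** 2, 1e-6))
    p = (np.exp(-0.5 * ((grid - separation) / s) ** 2)
         + np.exp(-0.5 * ((grid + separation) / s) ** 2))
    return p / np.trapezoid(p, grid)


# ---------------------------------------------------------------------------
# critical point

@dataclass
class CriticalPoint:
    beta_c: float
    mu_c: float
    x: float            # mixing parameter of the order parameter N - xE
    phi_c: float
    residual: float     # L2 distance to the universal distribution
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.beta_c <= 0:
            raise ValueError("beta_c must be positive")

    @property
    def t_c(self) -> float:
        return 1.0 / self.beta_c

    def to_json(self) -> dict:
        return {"beta_c": self.beta_c, "mu_c": self.mu_c, "x": self.x,
                "phi_c": self.phi_c, "residual": self.residual,
                "T_c_over_eps": self.t_c, **{f"meta_{k}": v
                                             for k, v in self.meta.items()}}


def order_parameter_density(hist: JointHistogram, beta: float, mu: float,
                            x: float, grid: np.ndarray) -> np.ndarray:
    """Standardized density of ``M = N - x*E`` after reweighting."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rw = reweight(hist, beta, mu)
    n = np.arange(hist.n_max + 1, dtype=float)
    e = hist.e_centers()
    m = n[:, None] - x * e[None, :]
    w = rw.counts
    tot = w.sum()
    mbar = (w * m).sum() / tot
    var = (w * (m - mbar) ** 2).sum() / tot
    sd = np.sqrt(var)
    if sd == 0:
        raise ValueError("degenerate order-parameter distribution")
    z = (m - mbar) / sd
    edges = np.concatenate([[grid[0] - (grid[1] - grid[0]) / 2],
                            (grid[1:] + grid[:-1]) / 2,
                            [grid[-1] + (grid[-1] - grid[-2]) / 2]])
    dens, _ = np.histogram(z.ravel(), bins=edges, weights=w.ravel())
    dens = dens / (tot * np.diff(edges))
    return dens


def find_critical_point(hist: JointHistogram, reference=ising_reference_table,
                        x0: float = 0.0, beta_trust: float = 0.08,
                        mu_trust: float = 0.5, min_ess: float = 50.0
                        ) -> CriticalPoint:
    """Locate ``(beta_c, mu_c, x)`` by universal-distribution matching.

    Minimizes the L2 distance between the standardized density of
    ``N - xE`` and the 3D-Ising universal distribution over
    ``(beta, mu, x)``, starting from the histogram's own conditions.
    """
    grid = np.linspace(-3.2, 3.2, 33)
    ref = reference(grid)
    V, L = _hist_vl(hist)
    b0, m0 = hist.beta, hist.mu
    # sparse view of the histogram: only occupied (N, E) cells matter
    ii, jj = np.nonzero(hist.counts)
    cs = hist.counts[ii, jj]
    ns = ii.astype(float)
    es = hist.e_centers()[jj]
    h0 = hist.h_table()[ii]
    edges = np.concatenate([[grid[0] - (grid[1] - grid[0]) / 2],
                            (grid[1:] + grid[:-1]) / 2,
                            [grid[-1] + (grid[-1] - grid[-2]) / 2]])

    def sparse_density(beta, mu, x):
        logw = (np.log(cs) - (beta - b0) * es
                + (beta * mu - b0 * m0) * ns + b0 * h0)
        logw -= logw.max()
        w = np.exp(logw)
        tot = w.sum()
        m = ns - x * es
        mbar = (w @ m) / tot
        sd = np.sqrt((w @ (m - mbar) ** 2) / tot)
        if sd == 0:
            raise ValueError("degenerate order-parameter distribution")
        dens, _ = np.histogram((m - mbar) / sd, bins=edges, weights=w)
        return dens / (tot * np.diff(edges))

    def distance(p):
        beta, mu, x = p
        if abs(beta - b0) > beta_trust or abs(mu - m0) > mu_trust:
            return 1e3 + abs(beta - b0) + abs(mu - m0)
        try:
            dens = sparse_density(beta, mu, x)
        except ValueError:
            return 1e3
        return float(np.sum((dens - ref) ** 2) * (grid[1] - grid[0]))

    best = None
    for xs in (x0, -0.02, 0.02, -0.08, 0.08):
        res = minimize(distance, np.array([b0, m0, xs]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10,
                                "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    beta_c, mu_c, x = best.x
    if (abs(beta_c - b0) > 0.98 * beta_trust
            or abs(mu_c - m0) > 0.98 * mu_trust):
        raise OverlapError(
            "optimizer reached the edge of the reweighting trust region; "
            "run a new simulation closer to criticality "
            f"(got beta={beta_c:.4f}, mu={mu_c:.4f})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rw = reweight(hist, beta_c, mu_c)
    ess = rw.meta.get("ess", np.inf)
    if ess < min_ess:
        raise OverlapError(
            f"effective sample size {ess:.1f} at the matched critical point; "
            "run a new simulation closer to criticality")
    phi_c = rw.mean_n() * L / V
    return CriticalPoint(float(beta_c), float(mu_c), float(x), float(phi_c),
                         float(best.fun), meta={"ess": float(ess)})


def binder_cumulant(hist: JointHistogram, beta: float, mu: float,
                    x: float = 0.0) -> float:
    """<m^4>/<m^2>^2 of the centered order parameter ``N - xE``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rw = reweight(hist, beta, mu)
    n = np.arange(hist.n_max + 1, dtype=float)
    e = hist.e_centers()
    m = n[:, None] - x * e[None, :]
    w = rw.counts
    tot = w.sum()
    mbar = (w * m).sum() / tot
    m2 = (w * (m - mbar) ** 2).sum() / tot
    m4 = (w * (m - mbar) ** 4).sum() / tot
    return float(m4 / m2 ** 2)


# ---------------------------------------------------------------------------
# phase diagram containers

@dataclass
class PhaseDiagram:
    """Binodal rows plus the critical point for one sequence."""

    table: pd.DataFrame      # beta_eps, mu_star, phi_dilute, phi_dense, ...
    critical: CriticalPoint | None = None
    label: str = ""
    source: str = "mc"

    def __post_init__(self):
        t = self.table
        if len(t):
            self.table = t.sort_values("beta_eps").reset_index(drop=True)
            bad = self.table["phi_dilute"] >= self.table["phi_dense"]
            if bad.any():
                raise ValueError("phi_dilute must be below phi_dense")

    def save_csv(self, path) -> None:
        t = self.table.copy()
        t["source"] = self.source
        t["label"] = self.label
        t.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# critical-point search driver

@dataclass
class GceRunner:
    """Engine handle: repeated runs for one (lattice, sequence) system."""

    lattice: object
    sequence: object
    base: RunParams
    mixture: MoveMixture | None = None
    run_count: int = 0

    def run(self, beta: float, mu: float, steps: int,
            h: MulticanonicalWeight | None = None, n_init: int | None = None,
            traj_every: int = 0, config=None) -> GceResult:
        """One run; passing ``config`` continues from that microstate
        (warm start, no annealing stage)."""
        from dataclasses import replace
        self.run_count += 1
        params = replace(
            self.base, beta_eps=beta, mu_over_eps=mu, steps=int(steps),
            seed=self.base.seed + 7919 * self.run_count,
            n_init=self.base.n_init if n_init is None else n_init,
            traj_every=traj_every,
            anneal=[] if config is not None else self.base.anneal)
        return run_gce(self.lattice, self.sequence, params,
                       mixture=self.mixture, h=h, config=config)


def _true_logp(hist: JointHistogram, beta: float, mu: float) -> np.ndarray:
    """Unnormalized log P(N) at (beta, mu) with the run's h removed;
    -inf where N was never visited."""
    e = hist.e_centers()
    logf = (-(beta - hist.beta) * e[None, :]
            + (hist.beta * hist.h_table())[:, None])
    mask = hist.counts > 0
    logf = logf - (logf[mask].max() if mask.any() else 0.0)
    base = (hist.counts
            * np.where(mask, np.exp(np.minimum(logf, 500.0)), 0.0)
            ).sum(axis=1)
    n = np.arange(hist.n_max + 1, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(base > 0,
                        np.log(np.maximum(base, 1e-300))
                        + (beta * mu - hist.beta * hist.mu) * n, -np.inf)


def _fill_gaps(logp: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Linear interpolation of -inf entries inside [lo, hi]."""
    out = logp.copy()
    idx = np.arange(lo, hi + 1)
    vals = logp[lo:hi + 1]
    good = np.isfinite(vals)
    if good.sum() >= 2:
        out[lo:hi + 1] = np.interp(idx, idx[good], vals[good])
    return out


def upper_hull_barrier(filled: np.ndarray, n_lo: int, n_hi: int,
                       smooth: int = 5):
    """Double-well diagnosis of a log-probability profile.

    Computes the upper concave hull of ``filled`` on ``[n_lo, n_hi]``
    and the largest hull-to-curve gap, which is the depth (in units of
    kB*T) of the free-energy barrier separating two wells; the gap is
    invariant under any chemical-potential tilt.  The profile is boxcar
    smoothed over ``smooth`` bins first so that statistical wiggles of
    a fraction of kB*T do not masquerade as wells.  Returns
    ``(gap, i_left, i_right, i_bottom)`` with the hull contact points
    bracketing the barrier and the barrier-bottom index.
    """
    idx = np.arange(n_lo, n_hi + 1)
    f = filled[n_lo:n_hi + 1]
    if smooth > 1 and len(f) > smooth:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        fp = np.pad(f, pad, mode="edge")
        f = np.convolve(fp, kernel, mode="valid")[:len(idx)]
    hull = [0]
    for i in range(1, len(f)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = ((idx[i1] - idx[i0]) * (f[i] - f[i0])
                     - (f[i1] - f[i0]) * (idx[i] - idx[i0]))
            if cross >= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    hull_y = np.interp(idx, idx[hull], f[hull])
    gaps = hull_y - f
    j = int(np.argmax(gaps))
    gap = float(gaps[j])
    left = max(h for h in hull if h <= j)
    right = min(h for h in hull if h >= j)
    return gap, n_lo + left, n_lo + right, n_lo + j


def _wham_pn(runs, beta: float, mu_ref: float, n_size: int,
             n_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Combine P(N) counts from runs at one beta but different (mu, h).

    Standard self-consistent multihistogram estimate over biased
    ensembles: run ``i`` sampled N with weight
    ``exp(beta (mu_i - mu_ref) N - beta h_i(N))`` relative to the
    reference.  Returns the unnormalized log P(N) at ``(beta, mu_ref)``
    (-inf where never visited).
    """
    n = np.arange(n_size, dtype=float)
    c = np.array([r["pn"] for r in runs])                 # (R, N)
    logw = np.array([beta * (r["mu"] - mu_ref) * n - beta * r["h"]
                     for r in runs])
    m = np.array([r["pn"].sum() for r in runs])
    num = c.sum(axis=0)
    seen = num > 0
    f = np.zeros(len(runs))
    logp = None
    for _ in range(n_iter):
        a = logw + f[:, None] + np.log(np.maximum(m, 1e-300))[:, None]
        amax = a.max(axis=0)
        logden = amax + np.log(np.exp(a - amax).sum(axis=0))
        with np.errstate(divide="ignore"):
            logp = np.where(seen, np.log(np.maximum(num, 1e-300)) - logden,
                            -np.inf)
        logp = logp - logp[seen].max()
        b = np.where(np.isfinite(logp)[None, :], logw + logp[None, :],
                     -np.inf)
        bmax = b.max(axis=1)
        f_new = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        f_new = f_new - f_new[0]
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    return logp


def flatten_multicanonical(runner: GceRunner, beta: float, mu: float,
                           steps: int, phi_cap: float = 1.6,
                           max_iter: int = 8, n_refine: int = 2,
                           final_steps: int | None = None,
                           well_min_width: int = 15, edge_margin: int = 3,
                           ) -> tuple[JointHistogram, dict]:
    """Iterative multicanonical flattening at fixed ``(beta, mu)``.

    The classic recursion: run under the current weight ``h(N)``,
    replace ``h`` with ``(1/beta) log`` of the estimated true
    distribution (so the next run samples it flat), extend ``h`` past
    the coverage edges with the local slope to push exploration
    outward, and warm-start each run from the previous microstate.
    Iterates until coverage spans the density range up to ``phi_cap``
    (plus ``n_refine`` full-coverage refinement passes), then takes one
    longer production run.  Only the final run enters the analysis, so
    transients from earlier, badly-weighted passes cannot contaminate
    the result.

    Returns the final histogram and a barrier diagnosis ``info`` (hull
    gap of log P(N), well positions, coverage, log-profile).  The hull
    gap is invariant under chemical-potential tilts, so ``mu`` only
    needs to be close enough for the run to cover both density wells.
    """
    V, L = runner.lattice.V, runner.sequence.L
    n_full = (runner.base.max_polymers or (2 * V) // L)
    n_cap = min(int(phi_cap * V / L), n_full)
    n_dilute = max(2, int(0.01 * V / L))
    h_tab = np.zeros(n_full + 1)      # current multicanonical weight
    ever_lo, ever_hi = None, None
    cfg = None
    hist = None
    info: dict = {}
    runs: list[dict] = []             # (pn, h table) per completed pass
    stage = 0            # completed full-coverage passes
    for it in range(max_iter + n_refine):
        n_steps = steps
        if final_steps is not None and stage >= n_refine:
            n_steps = final_steps
        h = MulticanonicalWeight(0, n_full, h_tab - h_tab.max(), beta)
        res = runner.run(beta, mu, n_steps, h=h, config=cfg,
                         n_init=2 if cfg is None else None)
        cfg = res.config
        hist = res.histogram
        pn = res.diagnostics["p_n"][:n_full + 1]
        if pn.sum() == 0:
            continue
        vis = np.flatnonzero(pn > 0)
        n_lo, n_hi = int(vis.min()), int(vis.max())
        ever_lo = n_lo if ever_lo is None else min(ever_lo, n_lo)
        ever_hi = n_hi if ever_hi is None else max(ever_hi, n_hi)
        runs.append({"pn": pn.copy(), "h": h.table(n_full), "mu": mu})
        # multihistogram estimate of log P over every pass so far; the
        # first pass is dropped once later data exists (its cold start
        # carries condensation transients)
        use = runs[1:] if len(runs) > 2 else runs
        use = use[-10:]
        logp = _wham_pn(use, beta, mu, n_full + 1)
        eh = min(ever_hi, n_cap)
        if eh - ever_lo >= 4:
            filled = _fill_gaps(logp, ever_lo, eh)
            filled[:ever_lo] = -np.inf
            filled[eh + 1:] = -np.inf
            gap, i_l, i_r, i_b = upper_hull_barrier(filled, ever_lo, eh)
        else:
            # degenerate coverage (e.g. transiently stuck above the cap)
            filled = logp
            gap, i_l, i_r, i_b = 0.0, ever_lo, eh, ever_lo
        well_gap = gap if (i_r - i_l >= well_min_width
                           and i_r <= eh - edge_margin) else 0.0
        info = {"gap": gap, "well_gap": well_gap, "i_left": i_l,
                "i_right": i_r, "i_bottom": i_b, "n_lo": ever_lo,
                "n_hi": eh, "n_cap": n_cap, "logp": filled.copy(),
                "mu": mu, "beta": beta, "run_lo": n_lo, "run_hi": n_hi}
        covered = ever_hi >= n_cap and ever_lo <= n_dilute
        if covered:
            stage += 1
        if stage > n_refine:
            break
        # next weight: flatten the combined estimate, extended past the
        # ever-visited range with the local slope so the next run keeps
        # exploring outward
        h_tab = np.zeros(n_full + 1)
        seg = _fill_gaps(logp, ever_lo, ever_hi)[ever_lo:ever_hi + 1]
        h_tab[ever_lo:ever_hi + 1] = seg / beta
        k = min(8, (ever_hi - ever_lo) // 2)
        if k >= 2:
            if ever_hi < n_full:
                slope = (h_tab[ever_hi] - h_tab[ever_hi - k]) / k
                idx = np.arange(ever_hi + 1, n_full + 1)
                h_tab[idx] = h_tab[ever_hi] + slope * (idx - ever_hi)
            if ever_lo > 0:
                slope = (h_tab[ever_lo + k] - h_tab[ever_lo]) / k
                idx = np.arange(0, ever_lo)
                h_tab[idx] = h_tab[ever_lo] - slope * (ever_lo - idx)
        # wall above the cap: h rises steeply so the sampler stays below
        if n_cap < n_full:
            idx = np.arange(n_cap + 1, n_full + 1)
            h_tab[idx] = np.maximum(h_tab[idx],
                                    h_tab[n_cap] + 8.0 * (idx - n_cap)
                                    / beta)
    return hist, info


def _equal_weight_from_logp(logp: np.ndarray, beta: float, mu_ref: float,
                            V: int, L: int, **kw) -> EqualWeightResult:
    """Equal-weight analysis of a bare log P(N) profile."""
    counts = np.zeros((len(logp), 1))
    finite = np.isfinite(logp)
    counts[finite, 0] = np.exp(logp[finite] - logp[finite].max())
    fake = JointHistogram(counts, e_min=-1.0, e_bin=1.0, beta=beta,
                          mu=mu_ref, total_sweeps=1.0,
                          meta={"sequence": "x" * L, "V": V})
    return equal_weight_mu(fake, beta, **kw)


def dilute_mu_guess(sequence, beta: float, phi: float, gs=None,
                    seed: int = 0) -> float:
    """Ideal-dilute-solution chemical potential giving density ``phi``.

    Uses the single-polymer partition sum ``sum_s g(s) e^{beta s}``
    (estimated quickly if not supplied) and the engine's shifted-mu
    convention.
    """
    from .single_polymer import estimate_gs_mc
    if gs is None:
        gs = estimate_gs_mc(sequence, steps=60_000, seed=seed)
    L = sequence.L
    zc = (np.log((gs.g * np.exp(beta * gs.s)).sum())
          - (L - 1) * np.log(13.0))
    return (np.log(phi / L) - zc) / beta


def barrier_ladder(runner: GceRunner, betas, steps: int = 1_500_000,
                   final_steps: int = 3_000_000, phi_start: float = 0.04,
                   gs=None) -> pd.DataFrame:
    """Inter-phase barrier depth along a temperature ladder.

    For each beta, flattens the sampler over the full density range and
    records the hull-gap barrier of log P(N) (in kB*T), which rises
    from ~0 above the critical temperature and grows rapidly below it.
    """
    rows = []
    for beta in sorted(betas):
        mu = dilute_mu_guess(runner.sequence, beta, phi_start, gs=gs,
                             seed=runner.base.seed + 55)
        hist, info = flatten_multicanonical(runner, beta, mu, steps,
                                            final_steps=final_steps)
        rows.append({"beta_eps": beta, "barrier": info["well_gap"],
                     "raw_gap": info["gap"], "mu": mu,
                     "n_lo": info["n_lo"], "n_hi": info["n_hi"],
                     "info": info, "hist": hist})
    return pd.DataFrame(rows)


def _relaxed_phi(runner: GceRunner, beta: float, mu: float, steps: int,
                 phi_init: float) -> float:
    """Mean density of a run started at ``phi_init`` (post-thermalization)."""
    V, L = runner.lattice.V, runner.sequence.L
    n0 = int(phi_init * V / L)
    cap = runner.base.max_polymers or (2 * V) // L
    res = runner.run(beta, mu, steps, n_init=min(max(n0, 0), cap))
    return res.histogram.mean_n() * L / V


def hysteresis_width(runner: GceRunner, beta: float, mu_lo: float,
                     mu_hi: float, steps: int = 250_000,
                     phi_mid: float = 0.55, phi_dense_init: float = 1.1,
                     n_bisect: int = 8) -> float:
    """Width (in mu) of the bistable window at one temperature.

    ``mu_up``: the chemical potential at which a dilute-started run
    first relaxes above ``phi_mid`` within the run budget; ``mu_dn``:
    the potential at which a dense-started run first falls below it.
    Below the critical temperature the two stay separated
    (``mu_up > mu_dn``, a finite hysteresis loop); above it both
    relaxations agree and the width vanishes.  At a fixed run budget
    this yields a pseudo-critical estimator that is cheap, monotone in
    temperature, and directly comparable across sequences.
    """
    lo, hi = mu_lo, mu_hi
    if _relaxed_phi(runner, beta, lo, steps, 0.02) > phi_mid:
        # even the lowest mu condenses within the budget: deeply
        # subcritical, the loop is wide open
        return float("inf")
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if _relaxed_phi(runner, beta, mid, steps, 0.02) > phi_mid:
            hi = mid
        else:
            lo = mid
    mu_up = 0.5 * (lo + hi)
    lo, hi = mu_lo, mu_hi
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if _relaxed_phi(runner, beta, mid, steps, phi_dense_init) > phi_mid:
            hi = mid
        else:
            lo = mid
    mu_dn = 0.5 * (lo + hi)
    return float(mu_up - mu_dn)


def pseudo_tc_hysteresis(runner: GceRunner, betas, steps: int = 250_000,
                         gs=None, phi_start: float = 0.04,
                         mu_span: float = 3.5, width_open: float = 0.05
                         ) -> tuple[float, pd.DataFrame]:
    """Pseudo-critical temperature from the closing of the hysteresis
    loop: the loop width is measured on a beta ladder and the opening
    point (width crossing ``width_open``, which sits above the
    bisection resolution) is interpolated.  Returns
    ``(T_c_estimate, table)``.
    """
    rows = []
    for beta in sorted(betas):
        mu_g = dilute_mu_guess(runner.sequence, beta, phi_start, gs=gs,
                               seed=runner.base.seed + 55)
        w = hysteresis_width(runner, beta, mu_g - 1.0, mu_g + mu_span / beta,
                             steps=steps)
        rows.append({"beta_eps": beta, "width": w})
    table = pd.DataFrame(rows)
    b = table["beta_eps"].to_numpy()
    w = table["width"].to_numpy()
    open_ = w > width_open
    if not open_.any():
        raise AboveCriticalError(
            "hysteresis loop never opens on the beta ladder")
    j = int(np.argmax(open_))
    if j == 0:
        raise AboveCriticalError(
            "hysteresis loop already open at the hottest beta; start hotter")
    b1, b2 = b[j - 1], b[j]
    w1, w2 = w[j - 1], w[j]
    if np.isfinite(w2) and w2 != w1:
        beta_pc = b1 + (width_open - w1) * (b2 - b1) / (w2 - w1)
    else:
        beta_pc = 0.5 * (b1 + b2)
    return float(1.0 / beta_pc), table


def equal_weight_boundary(runner: GceRunner, beta: float, *,
                          steps: int = 2_000_000,
                          final_steps: int = 8_000_000,
                          phi_cap: float = 0.7, phi_jump: float = 0.3,
                          gs=None) -> EqualWeightResult:
    """Equal-weight phase boundary ``mu*`` at one temperature, from
    scratch.

    Three stages: (1) relaxation runs bracket the metastability window
    in ``mu`` (lowest mu where a dilute start condenses, highest where
    a dense start melts, within a fixed budget); (2) multicanonical
    flattening at the window midpoint produces a first two-phase
    profile, whose own equal-weight tilt re-centers ``mu``; (3) a
    longer flattened production at the re-centered ``mu`` feeds the
    final equal-weight construction.
    """
    from .single_polymer import estimate_gs_mc
    V, L = runner.lattice.V, runner.sequence.L
    if gs is None:
        gs = estimate_gs_mc(runner.sequence, steps=100_000,
                            seed=runner.base.seed + 55)
    mu_g = dilute_mu_guess(runner.sequence, beta, 0.02, gs=gs)
    lo, hi = mu_g - 4.0, mu_g + 3.0 / beta
    for _ in range(4):
        if _relaxed_phi(runner, beta, lo, steps // 5, 0.02) <= phi_jump:
            break
        lo -= 2.0
    lo0 = lo
    for _ in range(9):
        mid = 0.5 * (lo + hi)
        if _relaxed_phi(runner, beta, mid, steps // 5, 0.02) > phi_jump:
            hi = mid
        else:
            lo = mid
    mu_up = 0.5 * (lo + hi)
    lo, hi = lo0, mu_up + 0.5
    for _ in range(9):
        mid = 0.5 * (lo + hi)
        if _relaxed_phi(runner, beta, mid, steps // 5, 1.0) > phi_jump:
            hi = mid
        else:
            lo = mid
    mu_dn = 0.5 * (lo + hi)
    mu_mid = 0.5 * (mu_up + min(mu_dn, mu_up))

    hist, info = flatten_multicanonical(runner, beta, mu_mid, steps,
                                        phi_cap=phi_cap,
                                        final_steps=2 * steps)
    try:
        ew0 = _equal_weight_from_logp(info["logp"], beta, mu_mid, V, L,
                                      mu_window=1.5, min_separation=0.5,
                                      min_phi_gap=0.05)
        mu_hat = ew0.mu_star
    except AboveCriticalError:
        mu_hat = mu_mid
    hist, info = flatten_multicanonical(runner, beta, mu_hat, steps,
                                        phi_cap=phi_cap,
                                        final_steps=final_steps)
    # the accumulated flattening profile covers both wells even when the
    # final run alone does not; the equal-weight tilt error from its
    # residual roughness (a few kB*T) is ~ (roughness)/(beta * dN),
    # i.e. ~0.01 eps here
    return _equal_weight_from_logp(info["logp"], beta, info["mu"], V, L,
                                   mu_window=1.5, min_separation=0.5,
                                   min_phi_gap=0.05)


def mu_star_by_integration(runner: GceRunner, beta_target: float, *,
                           beta_hot: float, mu_lo: float, mu_hi: float,
                           d_mu: float = 0.1, d_beta: float = 0.0125,
                           steps: int = 400_000, phi_split: float = 0.45
                           ) -> tuple[float, dict]:
    """Equal grand-potential chemical potential by thermodynamic
    integration around the critical point.

    ``ln Xi`` obeys ``d ln Xi / d mu = beta <N>`` along an isotherm and
    ``d ln Xi / d beta = <-H + mu N>`` along an iso-mu path, so the
    dilute and dense branches can be connected without ever crossing
    the first-order line: the dilute branch is integrated directly at
    ``beta_target`` from a near-ideal anchor at ``mu_lo``; the dense
    branch is anchored through a supercritical detour (the isotherm at
    ``beta_hot`` from ``mu_lo`` to ``mu_hi``, then cooling at ``mu_hi``
    on the dense side).  The coexistence ``mu*`` is where the two
    branch grand potentials cross.  All runs are warm-started along
    each path; branches are truncated where they lose metastability
    (relaxed density crossing ``phi_split``).
    """
    V, L = runner.lattice.V, runner.sequence.L

    def leg_mu(beta, mu_values, cfg, stop_above=None, stop_below=None):
        """Integrate beta*<N> d mu along an isotherm; returns arrays of
        (mu, lnXi increments via trapezoid), the <N> samples, configs."""
        ns, mus_done = [], []
        for mu in mu_values:
            res = runner.run(beta, mu, steps, config=cfg,
                             n_init=2 if cfg is None else None)
            cfg = res.config
            n_mean = res.histogram.mean_n()
            phi = n_mean * L / V
            if stop_above is not None and phi > stop_above:
                break
            mus_done.append(mu)
            ns.append(n_mean)
            if stop_below is not None and phi < stop_below:
                break
        return np.array(mus_done), np.array(ns), cfg

    # dilute branch at the target temperature
    mus_up = np.arange(mu_lo, mu_hi + 1e-9, d_mu)
    mu_dil, n_dil, _ = leg_mu(beta_target, mus_up, None,
                              stop_above=phi_split)
    lnxi_dil = n_dil[0] + np.concatenate(
        [[0.0], np.cumsum(beta_target * 0.5 * (n_dil[1:] + n_dil[:-1])
                          * np.diff(mu_dil))])

    # supercritical isotherm out to the dense-side anchor
    mu_hot, n_hot, cfg = leg_mu(beta_hot, mus_up, None)
    if len(mu_hot) < len(mus_up):
        raise OverlapError(
            "hot isotherm did not reach mu_hi; beta_hot may not be "
            "supercritical")
    lnxi_hot_hi = n_hot[0] + np.trapezoid(beta_hot * n_hot, mu_hot)

    # cool at mu_hi on the dense side
    betas = np.arange(beta_hot, beta_target + 1e-9, d_beta)
    if betas[-1] < beta_target - 1e-9:
        betas = np.append(betas, beta_target)
    integrand = []
    for beta in betas:
        res = runner.run(beta, mu_hi, steps, config=cfg)
        cfg = res.config
        h = res.histogram
        integrand.append(-h.mean_e() + mu_hi * h.mean_n())
    integrand = np.array(integrand)
    lnxi_dense_hi = lnxi_hot_hi + np.trapezoid(integrand, betas)

    # dense branch back down at the target temperature
    mus_dn = np.arange(mu_hi, mu_lo - 1e-9, -d_mu)
    mu_den, n_den, _ = leg_mu(beta_target, mus_dn, cfg,
                              stop_below=phi_split)
    lnxi_den = lnxi_dense_hi + np.concatenate(
        [[0.0], np.cumsum(beta_target * 0.5 * (n_den[1:] + n_den[:-1])
                          * np.diff(mu_den))])

    # crossing of the two branch grand potentials
    overlap_lo = max(mu_dil.min(), mu_den.min())
    overlap_hi = min(mu_dil.max(), mu_den.max())
    if overlap_lo >= overlap_hi:
        raise OverlapError(
            "metastable branches do not overlap in mu; reduce d_mu or "
            "extend the window")
    grid = np.linspace(overlap_lo, overlap_hi, 400)
    f_dil = np.interp(grid, mu_dil, lnxi_dil)
    f_den = np.interp(grid, mu_den[::-1], lnxi_den[::-1])
    diff = f_den - f_dil
    sign = np.sign(diff)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if len(idx) == 0:
        raise OverlapError(
            "branch grand potentials do not cross inside the overlap "
            "window; mu* lies outside it")
    j = idx[0]
    mu_star = float(grid[j] - diff[j] * (grid[j + 1] - grid[j])
                    / (diff[j + 1] - diff[j]))
    details = {"mu_dilute": mu_dil, "n_dilute": n_dil,
               "lnxi_dilute": lnxi_dil, "mu_dense": mu_den,
               "n_dense": n_den, "lnxi_dense": lnxi_den,
               "betas_cool": betas, "integrand_cool": integrand}
    return mu_star, details


def condensation_onset(runner: GceRunner, betas, phi_ref: float = 0.03,
                       steps: int = 400_000, phi_jump: float = 0.4,
                       gs=None) -> tuple[float, float, pd.DataFrame]:
    """Condensation temperature along an ideal-dilute reference path.

    The system is cooled stepwise (warm starts) with the chemical
    potential held on each sequence's ideal-dilute line at reference
    density ``phi_ref``; the onset is the interpolated temperature at
    which the relaxed density jumps through ``phi_jump``.  This
    cloud-point style estimator is slightly cold-biased relative to the
    true critical temperature (nucleation delay at fixed run budget)
    but cheap and highly reproducible, which makes it the bracketing
    stage of the critical-point search and a fair way to compare
    sequences.

    Returns ``(beta_onset, mu_at_onset, table)``.
    """
    from .single_polymer import estimate_gs_mc
    if gs is None:
        gs = estimate_gs_mc(runner.sequence, steps=60_000,
                            seed=runner.base.seed + 55)
    V, L = runner.lattice.V, runner.sequence.L
    cfg = None
    rows = []
    crossed = None
    for beta in sorted(betas):
        mu = dilute_mu_guess(runner.sequence, beta, phi_ref, gs=gs)
        res = runner.run(beta, mu, steps, config=cfg, n_init=5)
        cfg = res.config
        phi = res.histogram.mean_n() * L / V
        rows.append({"beta_eps": beta, "mu": mu, "phi": phi})
        if len(rows) >= 2 and phi > phi_jump and crossed is None:
            crossed = len(rows) - 1
        if crossed is not None:
            break
    table = pd.DataFrame(rows)
    if crossed is None:
        raise AboveCriticalError(
            f"density never exceeded {phi_jump} along the cooling path; "
            "extend the beta window")
    if table["phi"].iloc[0] > phi_jump:
        raise AboveCriticalError(
            "already condensed at the hottest temperature; start hotter")
    b1, b2 = table["beta_eps"].iloc[crossed - 1], table["beta_eps"].iloc[crossed]
    p1, p2 = table["phi"].iloc[crossed - 1], table["phi"].iloc[crossed]
    frac = (phi_jump - p1) / (p2 - p1)
    beta_x = float(b1 + frac * (b2 - b1))
    mu_x = float(dilute_mu_guess(runner.sequence, beta_x, phi_ref, gs=gs))
    return beta_x, mu_x, table


def locate_critical_point(runner: GceRunner, beta_start: float,
                          beta_max: float, *, d_beta: float = 0.02,
                          onset_steps: int = 400_000,
                          pilot_steps: int = 1_000_000,
                          prod_steps: int = 5_000_000,
                          phi_ref: float = 0.03,
                          refine: bool = True) -> tuple[CriticalPoint,
                                                        JointHistogram]:
    """Search for the critical point of one sequence.

    Two stages: (1) a cloud-point cooling scan brackets the transition
    temperature cheaply and robustly; (2) multicanonical flattening at
    the onset temperature (where the inter-phase barrier is still
    small) yields a two-phase histogram, which is refined at the
    equal-weight chemical potential and finally matched against the
    universal 3D-Ising order-parameter distribution over
    ``(beta, mu, x)`` within the reweighting trust region.
    """
    V, L = runner.lattice.V, runner.sequence.L
    from .single_polymer import estimate_gs_mc
    gs = estimate_gs_mc(runner.sequence, steps=60_000,
                        seed=runner.base.seed + 55)
    betas = np.arange(beta_start, beta_max + 1e-9, d_beta)
    beta_x, mu_x, table = condensation_onset(runner, betas, phi_ref=phi_ref,
                                             steps=onset_steps, gs=gs)
    # flatten at the onset point; the onset mu sits inside the
    # coexistence window so the profile is numerically well conditioned
    hist, info = flatten_multicanonical(runner, beta_x, mu_x, pilot_steps,
                                        final_steps=prod_steps)
    if not refine:
        ew = _equal_weight_from_logp(info["logp"], beta_x, info["mu"], V, L,
                                     mu_window=2.0, min_separation=0.5,
                                     min_phi_gap=0.02)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            phi_c = reweight(hist, beta_x, ew.mu_star).mean_n() * L / V
        return CriticalPoint(beta_x, ew.mu_star, 0.0, phi_c, np.nan), hist
    cp = find_critical_point(hist, beta_trust=0.1, mu_trust=2.0)
    return cp, hist


def _mean_match_mu(hist: JointHistogram, beta: float, n_target: float,
                   window: float = 1.0) -> float:
    """mu at which the reweighted mean polymer number equals n_target."""

    def f(mu):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return reweight(hist, beta, mu).mean_n() - n_target

    lo, hi = hist.mu - window, hist.mu + window
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        return lo if abs(flo) < abs(fhi) else hi
    return float(brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# binodal descent

def trace_binodal(runner: GceRunner, critical: CriticalPoint,
                  start_hist: JointHistogram, beta_schedule,
                  steps_per_beta: int = 6_000_000,
                  traj_every: int = 0) -> PhaseDiagram:
    """Iterative descent along the phase boundary below ``T_c``.

    For each successive ``beta1 > beta_c``: reweight the previous
    histogram to ``beta1``, read off the equal-weight ``mu*`` and the
    barrier region between the peaks, build the multicanonical weight
    ``h(N) = log P~(N)/beta1`` there, run under ``H + h(N)``, remove
    ``h`` by reweighting, and record the coexistence densities.  Stops
    with a partial diagram if the reweighting bridge breaks down.
    """
    V = runner.lattice.V
    L = runner.sequence.L
    rows = []
    hist = start_hist
    diagnostics = []
    for beta1 in beta_schedule:
        try:
            ew = equal_weight_mu(hist, beta1, mu_window=1.0)
        except AboveCriticalError as err:
            diagnostics.append(f"stopped at beta={beta1:.4f}: {err}")
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ptilde = reweight(hist, beta1, ew.mu_star).p_of_n()
        n_lo = int(np.ceil(ew.mixture.mean[0]))
        n_hi = int(np.floor(ew.mixture.mean[1]))
        if n_hi <= n_lo + 1:
            diagnostics.append(
                f"stopped at beta={beta1:.4f}: peaks merged")
            break
        seg = ptilde[n_lo:n_hi + 1]
        if (seg <= 0).any():
            diagnostics.append(
                f"stopped at beta={beta1:.4f}: barrier region not covered")
            break
        h = build_multicanonical_weight(ptilde, beta1, n_lo, n_hi)
        res = runner.run(beta1, ew.mu_star, steps_per_beta, h=h,
                         traj_every=traj_every)
        hist = res.histogram
        try:
            # analyze the new run via its h-corrected log profile, which
            # tolerates partial single-run coverage
            logp = _true_logp(hist, beta1, ew.mu_star)
            ew2 = _equal_weight_from_logp(logp, beta1, ew.mu_star, V, L,
                                          mu_window=1.0,
                                          min_separation=1.0,
                                          min_phi_gap=0.02)
        except AboveCriticalError as err:
            diagnostics.append(f"stopped at beta={beta1:.4f}: {err}")
            break
        rows.append({"beta_eps": beta1, "mu_star": ew2.mu_star,
                     "phi_dilute": ew2.phi_dilute,
                     "phi_dense": ew2.phi_dense,
                     "w_dilute": ew2.weights[0], "w_dense": ew2.weights[1]})
    table = pd.DataFrame(
        rows, columns=["beta_eps", "mu_star", "phi_dilute", "phi_dense",
                       "w_dilute", "w_dense"])
    pd_ = PhaseDiagram(table, critical=critical,
                       label=getattr(runner.sequence, "label", ""),
                       source="mc")
    if diagnostics:
        pd_.table.attrs["diagnostics"] = diagnostics
    return pd_


# ---------------------------------------------------------------------------
# phase-slice statistics

class EmptySelectionError(RuntimeError):
    pass


def phase_slice_stats(trajectory: pd.DataFrame, phi_target: float,
                      V: int, L: int, tol: float = 0.01) -> dict:
    """Mean and SD of per-polymer observables near a target density.

    Filters trajectory snapshots to ``|phi - phi_target| <= tol`` and
    pools polymers across the selected snapshots.  Trans-bonds are
    counted per polymer (a bond between two polymers contributes to
    both).
    """
    t = trajectory
    phi = t["N"] * L / V
    sel = t[np.abs(phi - phi_target) <= tol]
    if len(sel) == 0:
        raise EmptySelectionError(
            f"no snapshots within {tol} of phi={phi_target}")
    n_poly = sel["N"].sum()
    if n_poly == 0:
        raise EmptySelectionError("selected snapshots contain no polymers")
    out = {"n_snapshots": int(len(sel)), "phi_mean": float(np.mean(
        sel["N"] * L / V)), "phi_sd": float(np.std(sel["N"] * L / V))}
    for name, s_col, sq_col in (("s", "s_sum", "s_sumsq"),
                                ("t", "t_sum", "t_sumsq"),
                                ("rg", "rg_sum", "rg_sumsq")):
        mean = float(sel[s_col].sum() / n_poly)
        var = float(sel[sq_col].sum() / n_poly) - mean ** 2
        out[f"{name}_mean"] = mean
        out[f"{name}_sd"] = float(np.sqrt(max(var, 0.0)))
    return out
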