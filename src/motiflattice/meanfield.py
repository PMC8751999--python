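"""Mean-field theory of motif-polymer phase separation.

The free energy density (units of kB*T per lattice site) of a state in
which each polymer carries ``s_bar`` self-bonds and ``t_bar``
trans-bonds on average is

    f(s,t) = f_steric + f_trans + beta*chi*phi^2
             - (phi/L) log sum_s g(s) e^{w s} + (phi/L) w s
             - (phi/L) beta*eps (s + t/2),

    f_steric = (phi/L) log(phi/L) + (1 - phi<l>/L) log(1 - phi<l>/L)
               + (phi/L)(<l> - 1),          <l> = L - s - t/2,

    f_trans  = (phi/L) [ y(a) + y(b) + (t/2) log(t/2)
                         + (t/2)(1 - log(phi/L)) ],
    y(x)     = (x - s - t/2) log(x - s - t/2) - (x - s) log(x - s),

where ``g(s)`` is the single-polymer density of states, ``a``/``b`` the
motif stoichiometry, and ``w`` the self-bond weight chosen so that the
tilted ensemble over ``g`` has mean ``s_bar`` (the following term is
the compensating Legendre transform).  ``f_steric`` counts the ways to
place polymers of effective footprint ``<l>`` without overlap and
``f_trans`` the pairing entropy of forming ``t_bar`` trans-bonds from a
mean-field background of independent motifs.

At each density the free energy is minimized over ``(s_bar, t_bar)``;
phase coexistence follows from the common-tangent construction on
``f(phi)`` and the critical point from the closing of the spinodal.

``chi`` is the full coefficient of the ``beta*chi*phi^2`` term (energy
per site volume, in units of eps); ``chi_from_j`` converts from the
nonspecific contact energy via ``chi = -J*z/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, fsolve, minimize

from .lattice import Z
from .phase_analysis import CriticalPoint, PhaseDiagram
from .single_polymer import DensityOfStates


def chi_from_j(J: float, z: int = Z) -> float:
    """Mean-field nonspecific parameter from the contact energy J."""
    return -J * z / 2.0


class BoundaryError(ValueError):
    """s_bar at or outside the support of g(s): w diverges."""


@dataclass
class MeanFieldParams:
    g: DensityOfStates
    L: int
    a: int
    b: int
    beta_eps: float
    chi: float = chi_from_j(0.05)
    w_range: float = 40.0

    def __post_init__(self):
        if self.a + self.b != self.L:
            raise ValueError("a + b must equal L")
        s_hi = self.g.s[self.g.g > 0].max() if (self.g.g > 0).any() else 0
        if s_hi > min(self.a, self.b):
            raise ValueError("g(s) support exceeds min(a, b)")
        self._build_legendre_tables()

    @classmethod
    def from_sequence(cls, sequence, g: DensityOfStates, beta_eps: float,
                      chi: float = chi_from_j(0.05)) -> "MeanFieldParams":
        return cls(g=g, L=sequence.L, a=sequence.a, b=sequence.b,
                   beta_eps=beta_eps, chi=chi)

    # -- Legendre tables: s_bar(w), A(s_bar) = logZ(w) - w*s_bar ----------

    def _build_legendre_tables(self):
        s = self.g.s[self.g.g > 0].astype(float)
        logg = np.log(self.g.g[self.g.g > 0])
        ws = np.linspace(-self.w_range, self.w_range, 4001)
        expo = logg[None, :] + np.outer(ws, s)
        mx = expo.max(axis=1)
        logz = mx + np.log(np.exp(expo - mx[:, None]).sum(axis=1))
        p = np.exp(expo - logz[:, None])
        sbar = p @ s
        self._s_support = (float(s.min()), float(s.max()))
        self._logg_edges = (float(logg[0]), float(logg[-1]))
        keep = np.concatenate([[True], np.diff(sbar) > 1e-13])
        self._tab_s = sbar[keep]
        self._tab_w = ws[keep]
        self._tab_a = (logz - ws * sbar)[keep]

    def legendre(self, s_bar):
        """Interpolated (w, logZ - w*s_bar) at mean self-bond count."""
        s_bar = np.asarray(s_bar, dtype=float)
        w = np.interp(s_bar, self._tab_s, self._tab_w)
        a = np.interp(s_bar, self._tab_s, self._tab_a)
        lo, hi = self._s_support
        a = np.where(s_bar <= self._tab_s[0], self._logg_edges[0], a)
        a = np.where(s_bar >= self._tab_s[-1], self._logg_edges[1], a)
        out_of_support = (s_bar < lo) | (s_bar > hi)
        a = np.where(out_of_support, -np.inf, a)
        return w, a


def solve_w(g: DensityOfStates, s_bar: float, tol: float = 1e-12) -> float:
    """The unique tilt w with <s>_w = s_bar, by bracketed root-finding.

    <s>_w = sum_s s g(s) e^{ws} / sum_s g(s) e^{ws} is strictly
    increasing in w, so the root is unique; s_bar at or outside the
    support of g makes w diverge (BoundaryError).
    """
    s = g.s[g.g > 0].astype(float)
    logg = np.log(g.g[g.g > 0])
    if len(s) < 2:
        raise BoundaryError("g(s) has single-point support; w is undefined")
    if not s.min() < s_bar < s.max():
        raise BoundaryError(
            f"s_bar={s_bar} is at or outside the open support interval "
            f"({s.min()}, {s.max()}); w diverges")

    def mean_s(w):
        expo = logg + w * s
        expo = expo - expo.max()
        p = np.exp(expo)
        return float((p @ s) / p.sum()) - s_bar

    lo, hi = -1.0, 1.0
    while mean_s(lo) > 0:
        lo *= 2
        if lo < -1e6:
            raise BoundaryError("w bracket exhausted (s_bar at support edge)")
    while mean_s(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise BoundaryError("w bracket exhausted (s_bar at support edge)")
    return float(brentq(mean_s, lo, hi, xtol=tol, rtol=8.9e-16))


@dataclass
class MeanFieldState:
    phi: float
    s_bar: float
    t_bar: float
    w: float
    mean_l: float
    f: float
    components: dict = field(default_factory=dict)


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x * np.log(np.maximum(x, 1e-300)), 0.0)


def free_energy_grid(phi: float, S, T, params: MeanFieldParams):
    """Vectorized f over arrays of (s_bar, t_bar); +inf where infeasible."""
    L, a, b = params.L, params.a, params.b
    beta = params.beta_eps
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    half_t = T / 2.0
    mean_l = L - S - half_t
    rho = phi / L
    feas = ((S >= -1e-12) & (T >= -1e-12)
            & (a - S - half_t >= -1e-12) & (b - S - half_t >= -1e-12)
            & (1.0 - phi * mean_l / L >= -1e-12))
    Sc = np.clip(S, 0.0, None)
    Tc = np.clip(T, 0.0, None)
    half_t = Tc / 2.0
    mean_l = L - Sc - half_t
    w, A = params.legendre(Sc)
    empty = np.clip(1.0 - phi * mean_l / L, 0.0, None)
    f_steric = _xlogx(rho) * np.ones_like(Sc) + _xlogx(empty) \
        + rho * (mean_l - 1.0)
    y_a = _xlogx(a - Sc - half_t) - _xlogx(a - Sc)
    y_b = _xlogx(b - Sc - half_t) - _xlogx(b - Sc)
    f_trans = rho * (y_a + y_b + _xlogx(half_t)
                     + half_t * (1.0 - np.log(max(rho, 1e-300))))
    f = (f_steric + f_trans + beta * params.chi * phi ** 2
         - rho * A - rho * beta * (Sc + half_t))
    return np.where(feas & np.isfinite(A), f, np.inf)


def free_energy(phi: float, s_bar: float, t_bar: float,
                params: MeanFieldParams, exact_w: bool = True):
    """f(s_bar, t_bar) at one density, with its component breakdown.

    Returns ``(f, components)``; infeasible inputs give ``(inf, {})``
    rather than raising.
    """
    if phi == 0:
        return 0.0, {"f_steric": 0.0, "f_trans": 0.0, "nonspecific": 0.0,
                     "self_bond": 0.0, "bond_energy": 0.0, "w": 0.0}
    L, a, b = params.L, params.a, params.b
    beta = params.beta_eps
    half_t = t_bar / 2.0
    mean_l = L - s_bar - half_t
    rho = phi / L
    if (s_bar < 0 or t_bar < 0 or min(a, b) - s_bar - half_t < -1e-12
            or 1.0 - phi * mean_l / L < -1e-12 or phi < 0):
        return np.inf, {}
    lo, hi = params._s_support
    if s_bar < lo or s_bar > hi:
        return np.inf, {}
    if exact_w and lo < s_bar < hi:
        w = solve_w(params.g, s_bar)
        s_arr = params.g.s[params.g.g > 0].astype(float)
        logg = np.log(params.g.g[params.g.g > 0])
        expo = logg + w * s_arr
        mx = expo.max()
        A = mx + np.log(np.exp(expo - mx).sum()) - w * s_bar
    else:
        w, A = params.legendre(s_bar)
        w, A = float(w), float(A)
    empty = max(1.0 - phi * mean_l / L, 0.0)
    f_steric = float(_xlogx(rho) + _xlogx(empty) + rho * (mean_l - 1.0))
    y_a = float(_xlogx(a - s_bar - half_t) - _xlogx(a - s_bar))
    y_b = float(_xlogx(b - s_bar - half_t) - _xlogx(b - s_bar))
    f_trans = float(rho * (y_a + y_b + _xlogx(half_t)
                           + half_t * (1.0 - np.log(rho))))
    nonspec = beta * params.chi * phi ** 2
    self_bond = -rho * A
    bond_energy = -rho * beta * (s_bar + half_t)
    f = f_steric + f_trans + nonspec + self_bond + bond_energy
    comps = {"f_steric": f_steric, "f_trans": f_trans, "nonspecific": nonspec,
             "self_bond": self_bond, "bond_energy": bond_energy, "w": w}
    return f, comps


def minimize_bonds(phi: float, params: MeanFieldParams,
                   n_grid: int = 41) -> MeanFieldState:
    """Global minimizer of f over the feasible (s_bar, t_bar) simplex.

    Coarse grid scan followed by Nelder-Mead refinement; deterministic.
    """
    if phi <= 0:
        return MeanFieldState(phi, 0.0, 0.0, 0.0, float(params.L), 0.0)
    mab = min(params.a, params.b)
    lo, hi = params._s_support
    s_grid = np.linspace(lo, min(hi, mab), n_grid)
    t_grid = np.linspace(0.0, 2.0 * mab, 2 * n_grid)
    S, T = np.meshgrid(s_grid, t_grid, indexing="ij")
    F = free_energy_grid(phi, S, T, params)
    i, j = np.unravel_index(np.argmin(F), F.shape)
    x0 = np.array([S[i, j], T[i, j]])

    def obj(x):
        return free_energy_grid(phi, x[0], x[1], params).item()

    res = minimize(obj, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 4000})
    s_bar, t_bar = res.x
    s_bar = float(np.clip(s_bar, lo, hi))
    t_bar = float(max(t_bar, 0.0))
    f, comps = free_energy(phi, s_bar, t_bar, params, exact_w=False)
    return MeanFieldState(phi, s_bar, t_bar, comps.get("w", 0.0),
                          params.L - s_bar - t_bar / 2, f, comps)


def f_curve(params: MeanFieldParams, phis: np.ndarray, refine: bool = True,
            n_s: int = 48, n_t: int = 96) -> np.ndarray:
    """Minimized f(phi) over a density grid.

    The (s_bar, t_bar) minimization is done on a shared broadcast grid
    for every density at once, then (optionally) polished per density
    with Nelder-Mead from the grid optimum.
    """
    phis = np.asarray(phis, dtype=float)
    mab = min(params.a, params.b)
    lo, hi = params._s_support
    s_grid = np.linspace(lo, min(hi, mab), n_s)
    t_grid = np.linspace(0.0, 2.0 * mab, n_t)
    S = s_grid[:, None]
    T = t_grid[None, :]
    L = params.L
    beta = params.beta_eps
    half_t = T / 2.0
    mean_l = L - S - half_t                          # (s, t)
    w, A = params.legendre(np.broadcast_to(S, (n_s, 1)))
    feas_st = ((params.a - S - half_t >= 0) & (params.b - S - half_t >= 0)
               & np.isfinite(A))
    y_a = _xlogx(params.a - S - half_t) - _xlogx(params.a - S)
    y_b = _xlogx(params.b - S - half_t) - _xlogx(params.b - S)
    out = np.empty(len(phis))
    base_bond = A + beta * (S + half_t)              # (s, t)
    chunk = max(1, int(4e6 / (n_s * n_t)))
    argmins = np.empty(len(phis), dtype=np.int64)
    for start in range(0, len(phis), chunk):
        ph = phis[start:start + chunk][:, None, None]
        rho = ph / L
        empty = 1.0 - ph * mean_l[None] / L
        feas = feas_st[None] & (empty >= 0)
        F = (_xlogx(rho) + _xlogx(np.clip(empty, 0, None))
             + rho * (mean_l[None] - 1.0)
             + rho * (y_a + y_b + _xlogx(half_t))[None]
             + rho * half_t[None] * (1.0 - np.log(rho))
             + beta * params.chi * ph ** 2
             - rho * base_bond[None])
        F = np.where(feas, F, np.inf)
        flat = F.reshape(F.shape[0], -1)
        idx = np.argmin(flat, axis=1)
        argmins[start:start + chunk] = idx
        out[start:start + chunk] = flat[np.arange(flat.shape[0]), idx]
    if not refine:
        return out
    # vectorized zoom refinement around the per-density grid optimum
    si, ti = np.unravel_index(argmins, (n_s, n_t))
    s_c = s_grid[si]
    t_c = t_grid[ti]
    ds = (s_grid[1] - s_grid[0]) if n_s > 1 else 0.1
    dt = (t_grid[1] - t_grid[0]) if n_t > 1 else 0.1
    offs = np.linspace(-1.0, 1.0, 13)
    s_hi = min(hi, mab)
    for _ in range(6):
        S = np.clip(s_c[:, None, None] + ds * offs[None, :, None], lo, s_hi)
        T = np.clip(t_c[:, None, None] + dt * offs[None, None, :], 0.0,
                    2.0 * mab)
        F = _f_broadcast(phis[:, None, None], S, T, params)
        flat = F.reshape(len(phis), -1)
        idx = np.argmin(flat, axis=1)
        vals = flat[np.arange(len(phis)), idx]
        ii, jj = np.unravel_index(idx, (13, 13))
        s_c = S[np.arange(len(phis)), ii, 0]
        t_c = T[np.arange(len(phis)), 0, jj]
        improved = vals < out
        out = np.where(improved, vals, out)
        ds *= 0.28
        dt *= 0.28
    return out


def _f_broadcast(ph, S, T, params: MeanFieldParams):
    """f over broadcast arrays of (phi, s_bar, t_bar); +inf infeasible."""
    L, a, b = params.L, params.a, params.b
    beta = params.beta_eps
    half_t = T / 2.0
    mean_l = L - S - half_t
    rho = ph / L
    w, A = params.legendre(S)
    empty = 1.0 - ph * mean_l / L
    feas = ((a - S - half_t >= 0) & (b - S - half_t >= 0) & (empty >= 0)
            & np.isfinite(A) & (T >= 0))
    F = (_xlogx(rho) + _xlogx(np.clip(empty, 0, None))
         + rho * (mean_l - 1.0)
         + rho * (_xlogx(a - S - half_t) - _xlogx(a - S)
                  + _xlogx(b - S - half_t) - _xlogx(b - S)
                  + _xlogx(half_t))
         + rho * half_t * (1.0 - np.log(rho))
         + beta * params.chi * ph ** 2
         - rho * (A + beta * (S + half_t)))
    return np.where(feas, F, np.inf)


def f_of_phi(params: MeanFieldParams, phis: np.ndarray,
             refine: bool = True) -> np.ndarray:
    return f_curve(params, phis, refine=refine)


def phi_grid(n: int = 2000, phi_max: float = 1.6) -> np.ndarray:
    """Density grid, logarithmically dense near zero."""
    return np.geomspace(1e-5, phi_max, n)


# ---------------------------------------------------------------------------
# coexistence and the phase diagram

def _common_tangent(phis, fs):
    """Endpoints of the common tangent via the lower convex hull.

    Returns (phi1, phi2, residual) or None when f is convex.
    """
    ok = np.isfinite(fs)
    p, f = phis[ok], fs[ok]
    if len(p) < 5:
        return None
    hull = [0]
    for i in range(1, len(p)):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = ((p[i1] - p[i0]) * (f[i] - f[i0])
                     - (f[i1] - f[i0]) * (p[i] - p[i0]))
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = [(hull[k], hull[k + 1]) for k in range(len(hull) - 1)
            if hull[k + 1] - hull[k] > 1]
    if not gaps:
        return None
    i0, i1 = max(gaps, key=lambda g: p[g[1]] - p[g[0]])
    if p[i1] - p[i0] < 3 * (p[min(i0 + 1, len(p) - 1)] - p[i0]):
        return None
    spline = CubicSpline(p, f)

    def eqs(x):
        a, b = x
        return [spline(a, 1) - spline(b, 1),
                (spline(b) - spline(a)) - spline(a, 1) * (b - a)]

    sol, info, ier, _ = fsolve(eqs, [p[i0], p[i1]], full_output=True)
    if ier != 1 or not (p[0] <= sol[0] < sol[1] <= p[-1]):
        sol = np.array([p[i0], p[i1]])
    resid = np.max(np.abs(eqs(sol)))
    return float(sol[0]), float(sol[1]), float(resid), float(spline(sol[0], 1))


def mf_binodal_at(params: MeanFieldParams, phis=None, refine: bool = True):
    if phis is None:
        phis = phi_grid()
    fs = f_curve(params, phis, refine=refine)
    return _common_tangent(phis, fs)


def mf_phase_diagram(g: DensityOfStates, L: int, a: int, b: int,
                     beta_grid, chi: float = chi_from_j(0.05),
                     phis: np.ndarray | None = None,
                     locate_critical: bool = True) -> PhaseDiagram:
    """Mean-field binodal over a beta grid plus the critical point.

    At each beta the coexistence densities follow from the common
    tangent on the minimized f(phi) (equal exchange chemical potential
    and osmotic pressure); the critical point is refined by bisection
    on beta to where the two-phase region closes.
    """
    if phis is None:
        phis = phi_grid()
    rows = []
    label = g.label

    def solve_at(beta, refine=True):
        params = MeanFieldParams(g=g, L=L, a=a, b=b, beta_eps=beta, chi=chi)
        return mf_binodal_at(params, phis, refine=refine)

    betas = sorted(float(b_) for b_ in beta_grid)
    seps = {}
    for beta in betas:
        out = solve_at(beta)
        seps[beta] = out
        if out is not None:
            phi1, phi2, resid, slope = out
            rows.append({"beta_eps": beta, "mu_star": slope,
                         "phi_dilute": phi1, "phi_dense": phi2,
                         "tangent_residual": resid})
    critical = None
    if locate_critical:
        phi_u = np.linspace(5e-3, 1.45, 150)

        def spinodal(beta):
            """(most negative curvature, its density) of f on a uniform
            grid; negative curvature means local instability."""
            params = MeanFieldParams(g=g, L=L, a=a, b=b, beta_eps=beta,
                                     chi=chi)
            f = f_curve(params, phi_u)
            ok = np.isfinite(f)
            d2 = np.full_like(f, np.inf)
            d2[1:-1] = f[2:] - 2 * f[1:-1] + f[:-2]
            d2[~ok] = np.inf
            d2[1:-1][~(ok[2:] & ok[:-2])] = np.inf
            i = int(np.argmin(d2))
            return float(d2[i]), float(phi_u[i])

        sep_betas = [b_ for b_ in betas if seps[b_] is not None]
        if not sep_betas:
            raise ValueError("no phase separation anywhere on the beta grid")
        hi = min(sep_betas)
        lo = hi * 0.75
        while spinodal(lo)[0] < 0 and lo > 1e-3:
            hi = lo
            lo *= 0.85
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            if spinodal(mid)[0] < 0:
                hi = mid
            else:
                lo = mid
        d2, phi_c = spinodal(hi)
        critical = CriticalPoint(beta_c=hi, mu_c=np.nan, x=0.0,
                                 phi_c=float(phi_c), residual=np.nan,
                                 meta={"source": "meanfield"})
    table = pd.DataFrame(rows, columns=["beta_eps", "mu_star", "phi_dilute",
                                        "phi_dense", "tangent_residual"])
    return PhaseDiagram(table, critical=critical, label=label,
                        source="meanfield")
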