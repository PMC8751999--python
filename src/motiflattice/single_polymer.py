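"""Single-polymer density of states g(s).

``g(s)`` counts the number of 3D conformations of one polymer with
exactly ``s`` self-bonds.  Conformations are counted modulo translation
(the first monomer is pinned at the origin; rotations count as
distinct), on open (non-periodic) coordinates -- a single chain of
length ``L`` cannot span more than ``L`` sites, so no wrap can occur.

Two estimators are provided:

* exact exhaustive enumeration (short chains; the search tree has at
  most ``13^(L-1)`` branches),
* canonical Monte Carlo over a grid of inverse temperatures combined by
  the multihistogram method and inverted, with the absolute scale fixed
  by a Rosenbluth (sequential importance sampling) estimate of the total
  number of conformations.

Because the measure here is purely conformational, single-polymer runs
use the bond energy only (``H = -eps*s``); the nonspecific J term plays
no role for an isolated chain's density of states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import NEIGHBOR_OFFSETS, FccLattice
from .montecarlo import RunParams, run_gce, single_polymer_mixture
from .sequences import MotifSequence

_OFFSETS = [tuple(o) for o in NEIGHBOR_OFFSETS]


@dataclass
class DensityOfStates:
    """Table s -> g(s) for one sequence.

    For the exact method the entries are integers; for the
    multihistogram estimate they are real and carry the absolute
    normalization described in the module docstring.
    """

    label: str
    s: np.ndarray
    g: np.ndarray
    method: str = "exact"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=int)
        self.g = np.asarray(self.g, dtype=float)
        if (self.g < 0).any():
            raise ValueError("g(s) must be nonnegative")

    @property
    def s_max(self) -> int:
        nz = self.s[self.g > 0]
        return int(nz.max()) if len(nz) else 0

    def as_dict(self) -> dict[int, float]:
        return {int(si): float(gi) for si, gi in zip(self.s, self.g)}

    def total(self) -> float:
        return float(self.g.sum())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# label={self.label}\n# method={self.method}\n")
            for k, v in self.meta.items():
                fh.write(f"# meta {k}={v}\n")
            fh.write("# s g\n")
            for si, gi in zip(self.s, self.g):
                fh.write(f"{si} {gi:.12g}\n")

    @classmethod
    def load(cls, path) -> "DensityOfStates":
        label, method, meta, rows = "", "exact", {}, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("label="):
                        label = body[6:]
                    elif body.startswith("method="):
                        method = body[7:]
                    elif body.startswith("meta "):
                        k, _, v = body[5:].partition("=")
                        meta[k] = v
                    continue
                a, b = line.split()
                rows.append((int(a), float(b)))
        s = np.array([r[0] for r in rows])
        g = np.array([r[1] for r in rows])
        return cls(label, s, g, method=method, meta=meta)


# ---------------------------------------------------------------------------
# exact enumeration

def enumerate_gs_exact(sequence: MotifSequence,
                       branch_budget: float = 1e7) -> DensityOfStates:
    """Exhaustive count of all conformations, binned by self-bond number.

    The first monomer is fixed at the origin.  Each subsequent monomer
    steps to one of the 12 neighbor sites, or stays on the current site
    when that forms a contiguous A-B bond; placements that would put two
    same-type monomers or three monomers on a site are pruned.
    """
    L = sequence.L
    if 13.0 ** (L - 1) > branch_budget:
        raise ValueError(
            f"exhaustive enumeration of L={L} needs 13^{L - 1} branches, "
            f"over the budget of {branch_budget:.2g}; use the Monte Carlo "
            "estimator instead")
    types = sequence.codes()
    smax = min(sequence.a, sequence.b)
    g = np.zeros(smax + 1, dtype=np.int64)
    occ: dict[tuple, list] = {(0, 0, 0): [int(types[0])]}
    path = [(0, 0, 0)]

    def feasible(site, t):
        res = occ.get(site)
        if res is None:
            return True
        return len(res) < 2 and t not in res

    def rec(k, nbonds):
        if k == L:
            g[nbonds] += 1
            return
        t = int(types[k])
        cur = path[-1]
        cands = [(cur[0] + o[0], cur[1] + o[1], cur[2] + o[2])
                 for o in _OFFSETS]
        cands.append(cur)
        for site in cands:
            if not feasible(site, t):
                continue
            res = occ.setdefault(site, [])
            res.append(t)
            bond = len(res) == 2
            path.append(site)
            rec(k + 1, nbonds + bond)
            path.pop()
            res.pop()
            if not res:
                del occ[site]

    rec(1, 0)
    return DensityOfStates(sequence.label or sequence.motifs,
                           np.arange(smax + 1), g, method="exact")


# ---------------------------------------------------------------------------
# Rosenbluth estimate of the total number of conformations

def rosenbluth_total(sequence: MotifSequence, n_samples: int = 4000,
                     seed: int = 0) -> tuple[float, float]:
    """Unbiased estimate of the total conformation count (mod translation).

    Chains are grown with configurational bias on open coordinates; the
    mean Rosenbluth weight ``E[prod W_k]`` equals the number of valid
    conformations exactly.  Returns (estimate, standard error).
    """
    rng = np.random.default_rng(seed)
    types = sequence.codes()
    L = sequence.L
    weights = np.empty(n_samples)
    for i in range(n_samples):
        occ = {(0, 0, 0): [int(types[0])]}
        cur = (0, 0, 0)
        R = 1.0
        for k in range(1, L):
            t = int(types[k])
            cands = []
            for o in _OFFSETS:
                site = (cur[0] + o[0], cur[1] + o[1], cur[2] + o[2])
                res = occ.get(site)
                if res is None or (len(res) < 2 and t not in res):
                    cands.append(site)
            res = occ.get(cur)
            if len(res) < 2 and t not in res:
                cands.append(cur)
            if not cands:
                R = 0.0
                break
            R *= len(cands)
            cur = cands[rng.integers(len(cands))]
            occ.setdefault(cur, []).append(t)
        weights[i] = R
    est = float(weights.mean())
    sem = float(weights.std(ddof=1) / np.sqrt(n_samples))
    return est, sem


# ---------------------------------------------------------------------------
# multihistogram Monte Carlo estimate

def _single_polymer_histograms(sequence: MotifSequence, betas, steps, seed,
                               sample_every):
    """Canonical single-chain runs; returns counts[i, s] per beta."""
    L = sequence.L
    dim = max(5, L + 2)
    lattice = FccLattice((dim, dim, dim))
    smax = min(sequence.a, sequence.b)
    counts = np.zeros((len(betas), smax + 1))
    mix = single_polymer_mixture()
    for i, beta in enumerate(betas):
        params = RunParams(
            beta_eps=float(beta), mu_over_eps=0.0, J_over_eps=0.0,
            steps=int(steps), seed=int(seed) + 977 * i, n_init=1,
            sample_every=sample_every, anneal=[], therm_fraction=0.2,
            max_polymers=1, e_bin=1.0)
        res = run_gce(lattice, sequence, params, mixture=mix)
        h = res.histogram
        # with J = 0 the energy is exactly -s: bin centers map to s
        e_centers = h.e_centers()
        row = h.counts[1]
        for j, c in enumerate(row):
            if c > 0:
                s = int(round(-(h.e_min + j * h.e_bin)))
                if 0 <= s <= smax:
                    counts[i, s] += c
    return counts


def multihistogram_gs(counts: np.ndarray, betas, tol: float = 1e-10,
                      max_iter: int = 100_000) -> np.ndarray:
    """Self-consistent multihistogram inversion.

    Solves ``g(s) = sum_i n_i(s) / sum_i N_i exp(beta_i s - f_i)`` with
    ``exp(f_i) = sum_s g(s) exp(beta_i s)`` iterated to ``tol`` on the
    free-energy shifts.  The result is normalized to ``sum_s g = 1``;
    callers rescale to absolute counts.
    """
    betas = np.asarray(betas, dtype=float)
    counts = np.asarray(counts, dtype=float)
    n_i = counts.sum(axis=1)
    smax = counts.shape[1] - 1
    s = np.arange(smax + 1)
    seen = counts.sum(axis=0) > 0
    for i in range(len(betas) - 1):
        a = np.flatnonzero(counts[i] > 0)
        b = np.flatnonzero(counts[i + 1] > 0)
        if len(a) and len(b) and (a.max() < b.min() or b.max() < a.min()):
            raise RuntimeError(
                f"histograms at beta={betas[i]:.4g} and beta="
                f"{betas[i + 1]:.4g} do not overlap in s; add intermediate "
                "temperatures")
    logw = np.outer(betas, s)                      # (i, s)
    f = np.zeros(len(betas))
    num = counts.sum(axis=0)
    for _ in range(max_iter):
        # log denominator per s
        a = logw - f[:, None] + np.log(n_i)[:, None]
        amax = a.max(axis=0)
        den = amax + np.log(np.exp(a - amax).sum(axis=0))
        with np.errstate(divide="ignore"):
            logg = np.where(seen, np.log(np.maximum(num, 1e-300)) - den,
                            -np.inf)
        # update free energies
        b = logw + logg[None, :]
        bmax = b.max(axis=1)
        f_new = bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1))
        f_new = f_new - f_new[0]
        if np.abs(f_new - f).max() < tol:
            f = f_new
            break
        f = f_new
    g = np.exp(logg - np.max(logg[np.isfinite(logg)]))
    g[~seen] = 0.0
    return g / g.sum()


def estimate_gs_mc(sequence: MotifSequence, betas=None,
                   steps: int = 400_000, seed: int = 0,
                   sample_every: int = 20,
                   n_rosenbluth: int = 4000) -> DensityOfStates:
    """Monte Carlo estimate of g(s) via the multihistogram method.

    Canonical single-polymer simulations (conformational moves only) are
    run at each beta of the grid, combined self-consistently, and
    anchored in absolute scale by a Rosenbluth estimate of the total
    number of conformations.
    """
    if betas is None:
        betas = np.geomspace(0.3, 2.4, 8)
    counts = _single_polymer_histograms(sequence, betas, steps, seed,
                                        sample_every)
    g_rel = multihistogram_gs(counts, betas)
    total, _ = rosenbluth_total(sequence, n_samples=n_rosenbluth,
                                seed=seed + 131)
    g = g_rel * total
    smax = min(sequence.a, sequence.b)
    return DensityOfStates(
        sequence.label or sequence.motifs, np.arange(smax + 1), g,
        method="multihistogram",
        meta={"betas": list(np.round(np.asarray(betas, dtype=float), 6)),
              "steps": steps, "seed": seed})
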