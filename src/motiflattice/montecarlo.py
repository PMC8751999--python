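"""Grand-canonical Monte Carlo engine for motif lattice polymers.

The engine samples configurations of A/B motif polymers on a periodic
FCC lattice at fixed ``(beta, mu)``.  Conformational moves (end, corner,
reptation, contraction/expansion, cluster translation) conserve polymer
number; configurational-bias insertion and deletion moves change it.

Conventions
-----------
* All energies are in units of the bond energy ``eps``; temperatures are
  specified as ``beta*eps`` and chemical potentials as ``mu/eps``.
* ``mu`` is the shifted chemical potential: the ideal-chain entropy
  ``log (z+1)^(L-1)`` is absorbed into the ``(z+1)^(L-1)`` factors of
  the insertion/deletion acceptance probabilities, so dilute phases are
  reachable without hugely negative ``mu``.
* Expansions are proposed at 12 times the rate of contractions: twelve
  expanded states map onto any one contracted state on a lattice with
  coordination number 12, so this asymmetry is what detailed balance
  requires when the proposals themselves are uniform.
* One Monte Carlo step is one elementary proposal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from .histograms import JointHistogram, MulticanonicalWeight
from .lattice import Z, FccLattice
from .sequences import MotifSequence
from .state import LatticeConfig

#: engine move order
MOVE_NAMES = ("end", "corner", "reptation", "contraction", "expansion",
              "cluster", "insert", "delete")


@dataclass(frozen=True)
class MoveMixture:
    """Proposal probabilities for the eight move types.

    The expansion probability is always pinned to 12x the contraction
    probability; the constructor normalizes whatever weights it is given
    under that constraint.
    """

    end: float = 0.18
    corner: float = 0.18
    reptation: float = 0.18
    contraction: float = 0.18 / 13.0
    expansion: float = 12 * 0.18 / 13.0
    cluster: float = 0.18
    insert: float = 0.05
    delete: float = 0.05

    def __post_init__(self):
        probs = self.as_array()
        if (probs < 0).any():
            raise ValueError("move probabilities must be nonnegative")
        total = probs.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            probs = probs / total
        if not math.isclose(probs[4], 12 * probs[3], rel_tol=1e-9):
            raise ValueError(
                "expansion probability must be 12x the contraction "
                "probability (12 expanded states feed one contracted state)")
        for name, p in zip(MOVE_NAMES, probs):
            object.__setattr__(self, name, float(p))

    @classmethod
    def from_blocks(cls, conformational: float = 0.9,
                    insert_delete: float = 0.1) -> "MoveMixture":
        """Equal weight to the end/corner/reptation/cluster/(con+exp)
        blocks within ``conformational``; insert and delete split
        ``insert_delete`` equally."""
        blk = conformational / 5.0
        return cls(end=blk, corner=blk, reptation=blk,
                   contraction=blk / 13.0, expansion=12 * blk / 13.0,
                   cluster=blk, insert=insert_delete / 2,
                   delete=insert_delete / 2)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in MOVE_NAMES], dtype=float)

    def cumulative(self) -> np.ndarray:
        c = np.cumsum(self.as_array())
        c[-1] = 1.0 + 1e-12
        return c


def single_polymer_mixture() -> MoveMixture:
    """Conformational moves only (no insert/delete, no cluster moves)."""
    blk = 1.0 / 4.0
    return MoveMixture(end=blk, corner=blk, reptation=blk,
                       contraction=blk / 13.0, expansion=12 * blk / 13.0,
                       cluster=0.0, insert=0.0, delete=0.0)


@dataclass
class RunParams:
    """Control parameters of one grand-canonical run."""

    beta_eps: float
    mu_over_eps: float
    J_over_eps: float = 0.05
    steps: int = 1_000_000
    anneal: list | None = None      # list of (beta_eps, steps); None = default
    anneal_fraction: float = 0.1    # used when anneal is None
    therm_fraction: float = 0.2     # discarded from the production phase
    seed: int = 0
    n_init: int = 100
    sample_every: int = 100
    traj_every: int = 0             # 0 disables trajectory recording
    max_polymers: int | None = None
    e_bin: float | None = None      # None: automatic
    max_traj_rows: int = 200_000
    cluster_cap: int = 64           # larger clusters are rejected outright

    def __post_init__(self):
        if self.steps <= 0:
            raise ValueError("steps must be positive")
        if not 0 <= self.therm_fraction < 1:
            raise ValueError("therm_fraction must be in [0, 1)")

    def anneal_schedule(self) -> list[tuple[float, int]]:
        """The annealing stages run before production.

        Default: a geometric ramp over 10 stages from 0.5*beta to beta,
        spending ``anneal_fraction`` of the total steps.
        """
        if self.anneal is not None:
            return [(float(b), int(s)) for b, s in self.anneal]
        n_stages = 10
        stage_steps = int(self.steps * self.anneal_fraction / n_stages)
        if stage_steps == 0:
            return []
        betas = self.beta_eps * 0.5 * (2.0 ** (np.arange(1, n_stages + 1)
                                               / n_stages))
        return [(float(b), stage_steps) for b in betas]


@dataclass
class GceResult:
    histogram: JointHistogram
    trajectory: pd.DataFrame
    diagnostics: dict
    config: LatticeConfig


# ---------------------------------------------------------------------------
# initialization

def initialize(lattice: FccLattice, sequence: MotifSequence, N0: int,
               seed: int, J: float = 0.05,
               max_polymers: int | None = None) -> LatticeConfig:
    """Place ``N0`` polymers as randomly oriented straight walks.

    Each polymer starts at a random site and extends along a random
    neighbor direction; if a placement would create a forbidden overlap,
    a new random direction is chosen for the rest of the chain.  Straight
    initial conformations cannot be knotted.
    """
    L = sequence.L
    if N0 * L > 2 * lattice.V:
        raise ValueError(f"cannot place {N0} polymers of length {L} on "
                         f"{lattice.V} sites (occupancy cap is 2 per site)")
    rng = np.random.default_rng(seed)
    cfg = LatticeConfig(lattice, sequence, J=J, max_polymers=max_polymers)
    types = sequence.codes()
    nbrt = lattice.neighbor_table
    budget = 200 * max(N0, 1)
    placed = 0
    while placed < N0:
        if budget <= 0:
            raise RuntimeError(
                f"initialization failed after retry budget: placed {placed} "
                f"of {N0} polymers; try a smaller N0")
        budget -= 1
        head = int(rng.integers(lattice.V))
        if not cfg.can_add(head, int(types[0])):
            continue
        sites = [head]
        direction = int(rng.integers(Z))
        ok = True
        for k in range(1, L):
            nxt = int(nbrt[sites[-1], direction])
            tries = 0
            while not cfg_can_add_path(cfg, sites, nxt, types, k):
                direction = int(rng.integers(Z))
                nxt = int(nbrt[sites[-1], direction])
                tries += 1
                if tries > 50:
                    ok = False
                    break
            if not ok:
                break
            sites.append(nxt)
        if ok:
            cfg.add_polymer(sites)
            placed += 1
    return cfg


def cfg_can_add_path(cfg: LatticeConfig, sites, nxt, types, k) -> bool:
    """Whether monomer ``k`` can be placed on ``nxt`` given the partially
    grown straight chain ``sites`` (which is not yet in the registry)."""
    t = int(types[k])
    if not cfg.can_add(nxt, t):
        return False
    n_here = sites.count(nxt)
    if n_here == 0:
        return True
    if n_here >= 2 or cfg.site_n[nxt] > 0:
        return False
    first = types[sites.index(nxt)]
    return first != t


# ---------------------------------------------------------------------------
# single-step reference operations (pure Python, used for small systems
# and for the proposal-enumeration tests)

@dataclass
class MoveProposal:
    move: str
    valid: bool
    delta_h: float = 0.0
    delta_n: int = 0
    proposal_ratio: float = 1.0
    detail: dict = field(default_factory=dict)


def corner_candidates(config: LatticeConfig, p: int, k: int) -> list[int]:
    """Candidate target sites of a corner move: common neighbors of the
    two flanking sites, the current site and the flank sites excluded."""
    L = config.sequence.L
    if not 0 < k < L - 1:
        raise ValueError("corner moves apply to interior monomers")
    u, u0, u1 = (int(config.pos[p, k]), int(config.pos[p, k - 1]),
                 int(config.pos[p, k + 1]))
    if u == u0 or u == u1:
        return []
    nbrt = config.lattice.neighbor_table
    out = []
    for w in nbrt[u0]:
        w = int(w)
        if w in (u, u1):
            continue
        if u0 == u1 or w in nbrt[u1]:
            out.append(w)
    return out


def expansion_targets(config: LatticeConfig, p: int, k: int) -> list[tuple]:
    """All (mover, target-site) states a contracted pair (k, k+1) can
    expand into.  For an isolated contracted dimer this enumerates the
    12 predecessor states of the contracted state per mover choice."""
    u = int(config.pos[p, k])
    if int(config.pos[p, k + 1]) != u:
        return []
    L = config.sequence.L
    nbrt = config.lattice.neighbor_table
    out = []
    for mover, other in ((k, k - 1), (k + 1, k + 2)):
        for v in nbrt[u]:
            v = int(v)
            if 0 <= other < L:
                uo = int(config.pos[p, other])
                if uo != v and v not in nbrt[uo]:
                    continue
            if _can_add_excluding(config, v, int(config.types[mover]),
                                  exclude=(p, mover)):
                out.append((mover, v))
    return out


def _can_add_excluding(config, site, t, exclude):
    n = int(config.site_n[site])
    na = int(config.site_na[site])
    for slot in range(n):
        if (int(config.occ_p[site, slot]), int(config.occ_m[site, slot])) == exclude:
            n -= 1
            na -= (int(config.types[exclude[1]]) == 0)
    if n >= 2:
        return False
    return (na == 0) if t == 0 else (n - na == 0)


def propose_local_move(config: LatticeConfig, mixture: MoveMixture,
                       rng: np.random.Generator) -> MoveProposal:
    """Draw one conformation-conserving local move and evaluate it.

    The configuration is left unchanged; the returned proposal carries
    the energy change and validity.  Rejected-at-proposal (no valid
    target) is reported as a null move.
    """
    local = np.array([mixture.end, mixture.corner, mixture.reptation,
                      mixture.contraction, mixture.expansion])
    local = local / local.sum()
    mv = MOVE_NAMES[rng.choice(5, p=local)]
    if config.N == 0:
        return MoveProposal(mv, False, detail={"reason": "empty system"})
    p = int(rng.integers(config.N))
    L = config.sequence.L

    def eval_single(mono, target):
        u = int(config.pos[p, mono])
        e0 = config.energy
        t = int(config.types[mono])
        config._remove_monomer(u, p, mono)
        if not config.can_add(target, t):
            config._add_monomer(u, p, mono)
            return None
        config._add_monomer(target, p, mono)
        dh = config.energy - e0
        config._remove_monomer(target, p, mono)
        config._add_monomer(u, p, mono)
        return dh

    if mv == "end":
        if L == 1:
            return MoveProposal(mv, False, detail={"reason": "L=1"})
        e = 0 if rng.random() < 0.5 else L - 1
        anchor = 1 if e == 0 else L - 2
        u, ua = int(config.pos[p, e]), int(config.pos[p, anchor])
        if u == ua:
            return MoveProposal(mv, False, detail={"reason": "contracted end"})
        v = int(config.lattice.neighbor_table[ua, rng.integers(Z)])
        if v == u:
            return MoveProposal(mv, False, detail={"reason": "same site"})
        dh = eval_single(e, v)
        if dh is None:
            return MoveProposal(mv, False, detail={"target": v})
        return MoveProposal(mv, True, dh, detail={"monomer": e, "target": v})

    if mv == "corner":
        if L < 3:
            return MoveProposal(mv, False, detail={"reason": "L<3"})
        k = int(rng.integers(1, L - 1))
        cands = corner_candidates(config, p, k)
        if not cands:
            return MoveProposal(mv, False, detail={"monomer": k})
        v = cands[int(rng.integers(len(cands)))]
        dh = eval_single(k, v)
        if dh is None:
            return MoveProposal(mv, False, detail={"target": v})
        return MoveProposal(mv, True, dh,
                            detail={"monomer": k, "target": v,
                                    "candidates": cands})

    if mv == "contraction":
        k = int(rng.integers(L - 1))
        if int(config.types[k]) == int(config.types[k + 1]):
            return MoveProposal(mv, False,
                                detail={"reason": "bond-incompatible pair",
                                        "pair": k})
        d = int(rng.integers(2))
        mover = k + 1 if d == 0 else k
        stay = k if d == 0 else k + 1
        u_m, u_s = int(config.pos[p, mover]), int(config.pos[p, stay])
        if u_m == u_s:
            return MoveProposal(mv, False, detail={"reason": "already contracted"})
        other = mover + 1 if mover > stay else mover - 1
        if 0 <= other < L:
            uo = int(config.pos[p, other])
            if uo != u_s and uo not in config.lattice.neighbor_table[u_s]:
                return MoveProposal(mv, False, detail={"reason": "chain break"})
        dh = eval_single(mover, u_s)
        if dh is None:
            return MoveProposal(mv, False, detail={"target": u_s})
        return MoveProposal(mv, True, dh, proposal_ratio=1.0,
                            detail={"pair": k, "mover": mover})

    if mv == "expansion":
        k = int(rng.integers(L - 1))
        u = int(config.pos[p, k])
        if int(config.pos[p, k + 1]) != u:
            return MoveProposal(mv, False, detail={"reason": "not contracted"})
        d = int(rng.integers(2))
        mover = k if d == 0 else k + 1
        v = int(config.lattice.neighbor_table[u, rng.integers(Z)])
        other = k - 1 if mover == k else k + 2
        if 0 <= other < L:
            uo = int(config.pos[p, other])
            if uo != v and v not in config.lattice.neighbor_table[uo]:
                return MoveProposal(mv, False, detail={"reason": "chain break"})
        dh = eval_single(mover, v)
        if dh is None:
            return MoveProposal(mv, False, detail={"target": v})
        return MoveProposal(mv, True, dh, proposal_ratio=1.0,
                            detail={"pair": k, "mover": mover, "target": v})

    # reptation
    toward_head = rng.random() < 0.5
    lead = 0 if toward_head else L - 1
    choice = int(rng.integers(13))
    ulead = int(config.pos[p, lead])
    tgt = int(config.lattice.neighbor_table[ulead, choice]) if choice < 12 \
        else ulead
    if toward_head:
        new_sites = [tgt] + [int(config.pos[p, k]) for k in range(L - 1)]
    else:
        new_sites = [int(config.pos[p, k]) for k in range(1, L)] + [tgt]
    old_sites = [int(config.pos[p, k]) for k in range(L)]
    e0 = config.energy
    for k in range(L):
        config._remove_monomer(old_sites[k], p, k)
    ok = True
    placed = 0
    for k in range(L):
        if config.can_add(new_sites[k], int(config.types[k])):
            config._add_monomer(new_sites[k], p, k)
            placed += 1
        else:
            ok = False
            break
    dh = config.energy - e0 if ok else 0.0
    for k in range(placed - 1, -1, -1):
        config._remove_monomer(new_sites[k], p, k)
    for k in range(L):
        config._add_monomer(old_sites[k], p, k)
    if not ok:
        return MoveProposal(mv, False, detail={"target": tgt})
    return MoveProposal(mv, True, dh,
                        detail={"toward_head": toward_head, "target": tgt})


def find_clusters(config: LatticeConfig) -> list[list[int]]:
    """Connected components of polymers sharing A-B bond sites."""
    n = config.N
    seen = [False] * n
    partners: dict[int, set[int]] = {i: set() for i in range(n)}
    for v in np.flatnonzero(np.asarray(config.site_n) == 2):
        p1, p2 = int(config.occ_p[v, 0]), int(config.occ_p[v, 1])
        if p1 != p2:
            partners[p1].add(p2)
            partners[p2].add(p1)
    out = []
    for i in range(n):
        if seen[i]:
            continue
        comp, stack = [], [i]
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for q in partners[j]:
                if not seen[q]:
                    seen[q] = True
                    stack.append(q)
        out.append(sorted(comp))
    return out


def propose_cluster_translate(config: LatticeConfig,
                              rng: np.random.Generator) -> MoveProposal:
    """One-site translation of a bond-connected polymer cluster.

    Null if any A-B bond would be created or destroyed or any forbidden
    overlap created, so the energy change involves only nonspecific J
    terms."""
    if config.N == 0:
        return MoveProposal("cluster", False, detail={"reason": "empty"})
    p0 = int(rng.integers(config.N))
    cluster = next(c for c in find_clusters(config) if p0 in c)
    direction = int(rng.integers(Z))
    nbrt = config.lattice.neighbor_table
    members = set(cluster)
    for i in cluster:
        for k in range(config.sequence.L):
            v = int(nbrt[int(config.pos[i, k]), direction])
            for slot in range(int(config.site_n[v])):
                if int(config.occ_p[v, slot]) not in members:
                    return MoveProposal("cluster", False,
                                        detail={"reason": "external occupant",
                                                "cluster": cluster})
    L = config.sequence.L
    e0, q0 = config.energy, config.Q
    olds = {(i, k): int(config.pos[i, k]) for i in cluster for k in range(L)}
    for (i, k), u in olds.items():
        config._remove_monomer(u, i, k)
    for (i, k), u in olds.items():
        config._add_monomer(int(nbrt[u, direction]), i, k)
    dh = config.energy - e0
    assert config.Q == q0, "cluster translation must conserve bonds"
    for (i, k), u in olds.items():
        config._remove_monomer(int(nbrt[u, direction]), i, k)
    for (i, k), u in olds.items():
        config._add_monomer(u, i, k)
    return MoveProposal("cluster", True, dh,
                        detail={"cluster": cluster, "direction": direction})


def cbmc_insert(config: LatticeConfig, rng: np.random.Generator):
    """Grow one trial polymer by configurational bias.

    Returns ``(sites, R)`` with the Rosenbluth weight ``R = prod W_k``,
    or ``None`` when the head site is incompatible or some ``W_k = 0``.
    The configuration is left unchanged.
    """
    L = config.sequence.L
    types = config.types
    head = int(rng.integers(config.lattice.V))
    if not config.can_add(head, int(types[0])):
        return None
    n = config.N
    if n >= config.max_polymers:
        return None
    config._add_monomer(head, n, 0)
    sites = [head]
    R = 1.0
    nbrt = config.lattice.neighbor_table
    try:
        for k in range(1, L):
            u = sites[-1]
            cands = [int(w) for w in nbrt[u]
                     if config.can_add(int(w), int(types[k]))]
            if config.can_add(u, int(types[k])):
                cands.append(u)
            if not cands:
                return None
            v = cands[int(rng.integers(len(cands)))]
            config._add_monomer(v, n, k)
            sites.append(v)
            R *= len(cands)
    finally:
        for k in range(len(sites) - 1, -1, -1):
            config._remove_monomer(sites[k], n, k)
    return sites, R


def deletion_rosenbluth(config: LatticeConfig, p: int) -> float:
    """Rosenbluth weight of an existing conformation, by retracing it.

    At each step the allowed continuations are counted in the
    configuration with the polymer's not-yet-placed tail removed; the
    occupied continuation itself is always among them, so ``R >= 1``.
    """
    L = config.sequence.L
    sites = [int(config.pos[p, k]) for k in range(L)]
    for k in range(L):
        config._remove_monomer(sites[k], p, k)
    R = 1.0
    nbrt = config.lattice.neighbor_table
    config._add_monomer(sites[0], p, 0)
    for k in range(1, L):
        u = sites[k - 1]
        nc = sum(1 for w in nbrt[u]
                 if config.can_add(int(w), int(config.types[k])))
        if config.can_add(u, int(config.types[k])):
            nc += 1
        R *= nc
        config._add_monomer(sites[k], p, k)
    return R


def acceptance_probability(delta_h: float, delta_n: int, R: float | None,
                           N: int, V: int, L: int, beta: float, mu: float,
                           h: MulticanonicalWeight | None = None,
                           proposal_ratio: float = 1.0) -> float:
    """Metropolis acceptance probability of a proposed move.

    ``delta_h`` excludes the multicanonical term; ``N`` is the polymer
    count before the move.  ``R`` is the Rosenbluth weight of the grown
    (inserted) or retraced (deleted) conformation and must be supplied
    when ``delta_n != 0``.
    """
    if not np.isfinite(delta_h):
        raise ValueError("delta_h must be finite")
    if delta_n not in (-1, 0, 1):
        raise ValueError("delta_n must be -1, 0 or +1")
    hfun = h if h is not None else (lambda n: 0.0)
    if delta_n == 0:
        x = proposal_ratio * math.exp(-beta * delta_h)
        return min(1.0, x)
    if R is None:
        raise ValueError("R required for insertion/deletion moves")
    zl = (Z + 1) ** (L - 1)
    if delta_n == +1:
        x = (V / (N + 1)) * (R / zl) * math.exp(
            -beta * (delta_h - mu) - beta * (hfun(N + 1) - hfun(N)))
    else:
        x = (N / V) * (zl / R) * math.exp(
            -beta * (delta_h + mu) - beta * (hfun(N - 1) - hfun(N)))
    return min(1.0, x)


# ---------------------------------------------------------------------------
# multicanonical weights

def build_multicanonical_weight(p_tilde: np.ndarray, beta: float,
                                n_lo: int, n_hi: int) -> MulticanonicalWeight:
    """Build ``h(N) = (1/beta) log P~(N)`` on the barrier range.

    ``p_tilde`` is the predicted distribution over N = 0..len-1 at
    ``beta`` (normalization is irrelevant).  Running with this weight
    flattens P~(N) between the two peaks; outside the range ``h``
    continues at its boundary values.
    """
    p_tilde = np.asarray(p_tilde, dtype=float)
    seg = p_tilde[n_lo:n_hi + 1]
    if (seg <= 0).any():
        raise ValueError(
            "P~(N) must be strictly positive on the barrier range")
    return MulticanonicalWeight(n_lo, n_hi, np.log(seg) / beta, beta)


# ---------------------------------------------------------------------------
# the production driver

def _auto_ebin(sequence: MotifSequence, n_max: int, J: float):
    e_per = min(sequence.a, sequence.b) + J * Z * sequence.L
    e_min = -e_per * n_max - 1.0
    width = max(0.25, -e_min / 8000.0)
    n_bins = int(np.ceil(-e_min / width)) + 2
    return e_min, width, n_bins


def run_gce(lattice: FccLattice, sequence: MotifSequence, params: RunParams,
            mixture: MoveMixture | None = None,
            h: MulticanonicalWeight | None = None,
            config: LatticeConfig | None = None) -> GceResult:
    """Run annealing then production; accumulate P(N, E).

    Fully reproducible from ``params.seed``.  Histograms cover the
    post-thermalization portion of the production phase only.
    """
    if mixture is None:
        mixture = MoveMixture()
    if config is None:
        config = initialize(lattice, sequence, params.n_init, params.seed,
                            J=params.J_over_eps,
                            max_polymers=params.max_polymers)
    n_max = config.max_polymers
    e_min, e_bin, n_ebins = _auto_ebin(sequence, n_max, params.J_over_eps)
    if params.e_bin is not None:
        e_bin = float(params.e_bin)
        n_ebins = int(np.ceil(-e_min / e_bin)) + 2

    pn = np.zeros(n_max + 1)
    hist2d = np.zeros((n_max + 1, n_ebins))
    acc = np.zeros((8, 2), dtype=np.int64)
    scal = np.array([config.n_polymers, config.Q, config.W], dtype=np.int64)
    h_tab = h.table(n_max) if h is not None else np.zeros(n_max + 1)
    move_cum = mixture.cumulative()
    dims = np.array(lattice.dims, dtype=np.int64)
    L = sequence.L
    in_cluster = np.zeros(n_max, dtype=np.bool_)
    stack = np.zeros(n_max, dtype=np.int64)
    new_sites = np.zeros(L, dtype=np.int32)
    old_sites = np.zeros(L, dtype=np.int32)
    s_work = np.zeros(n_max, dtype=np.int64)
    t_work = np.zeros(n_max, dtype=np.int64)
    n_traj = params.max_traj_rows if params.traj_every else 1
    traj = np.zeros((n_traj, 10))
    traj_len = np.zeros(1, dtype=np.int64)

    _engine._seed(params.seed % (2 ** 31))

    def advance(beta, steps, sampling):
        _engine.run_steps(
            config.pos, config.types, lattice.neighbor_table, dims,
            config.site_n, config.site_na, config.occ_p, config.occ_m, scal,
            beta, params.mu_over_eps, params.J_over_eps, h_tab, move_cum,
            steps, params.sample_every if sampling else 0,
            pn, hist2d, e_min, e_bin,
            params.traj_every if sampling else 0, traj, traj_len,
            acc, in_cluster, stack, new_sites, old_sites, s_work, t_work,
            params.cluster_cap)

    schedule = params.anneal_schedule()
    for beta, steps in schedule:
        advance(beta, steps, False)
    production = params.steps - sum(s for _, s in schedule)
    if production <= 0:
        raise ValueError("anneal schedule leaves no production steps")
    therm = int(production * params.therm_fraction)
    if therm:
        advance(params.beta_eps, therm, False)
    advance(params.beta_eps, production - therm, True)

    config.n_polymers = int(scal[0])
    config.Q = int(scal[1])
    config.W = int(scal[2])

    hist = JointHistogram(
        hist2d, e_min, e_bin, params.beta_eps, params.mu_over_eps, h=h,
        total_sweeps=float(pn.sum()),
        meta={"seed": params.seed, "J": params.J_over_eps,
              "sequence": sequence.motifs, "V": lattice.V,
              "steps": params.steps})
    rates = {name: (acc[i, 1] / acc[i, 0] if acc[i, 0] else np.nan)
             for i, name in enumerate(MOVE_NAMES)}
    trajectory = pd.DataFrame(
        traj[:traj_len[0]],
        columns=["step", "N", "E", "s_sum", "s_sumsq", "t_sum", "t_sumsq",
                 "t_total", "rg_sum", "rg_sumsq"])
    diag = {"acceptance": rates, "proposals": acc[:, 0].copy(),
            "accepted": acc[:, 1].copy(), "p_n": pn}
    return GceResult(hist, trajectory, diag, config)
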