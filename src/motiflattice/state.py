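"""Microstate representation and the Hamiltonian with its observables.

A microstate holds ``N`` polymers of one sequence on a periodic FCC
lattice.  Each lattice site may host at most two monomers, and never two
A's or two B's.  A site holding exactly one A and one B carries a
specific bond (occupancy ``q_i = 1``) of energy ``-eps``; monomers on
adjacent sites interact nonspecifically with energy ``-J`` per pair of
resident monomers:

    H = -eps * sum_i q_i - J * sum_{adjacent site pairs} r_i r_j ,

where ``r_i`` is the number of monomers on site ``i``.  All adjacent
site pairs contribute to the J term, including pairs formed by
consecutive monomers of one chain.  Energies are reported in units of
``eps`` throughout.

Consecutive monomers of a chain either occupy adjacent sites or
co-reside on one site (a contiguous A-B bond).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .lattice import FccLattice
from .sequences import MotifSequence


class IntegrityError(RuntimeError):
    """A microstate violated an occupancy or connectivity invariant."""


@dataclass
class Observables:
    """Per-snapshot observables of one microstate."""

    N: int
    E: float                     # total energy, units of eps
    s_per_polymer: np.ndarray    # self-bond count of each polymer
    t_total: int                 # trans-bonds, each counted once
    phi: float                   # monomer volume fraction N*L/V
    Rg_per_polymer: np.ndarray   # radius of gyration, lattice units


class LatticeConfig:
    """Full microstate: conformations, occupancy registry, cached energy.

    The registry arrays are laid out so the Monte Carlo engine can use
    them directly:

    - ``pos[n, k]`` -- flat site index of monomer ``k`` of polymer ``n``
    - ``site_n[v]``, ``site_na[v]`` -- monomer count / A count on site ``v``
    - ``occ_p[v, slot]``, ``occ_m[v, slot]`` -- occupant registry
      (polymer id, monomer index), slots filled from 0
    - ``Q`` -- number of bonded sites, ``W`` -- sum of ``r_i r_j`` over
      adjacent site pairs, so the cached energy is ``-Q - J*W``.
    """

    def __init__(self, lattice: FccLattice, sequence: MotifSequence,
                 J: float = 0.05, max_polymers: int | None = None):
        self.lattice = lattice
        self.sequence = sequence
        self.J = float(J)
        L = sequence.L
        if max_polymers is None:
            max_polymers = max(4, (2 * lattice.V) // L)
        self.max_polymers = int(max_polymers)
        self.types = sequence.codes()          # 0 = A, 1 = B
        self.pos = np.full((self.max_polymers, L), -1, dtype=np.int32)
        self.n_polymers = 0
        V = lattice.V
        self.site_n = np.zeros(V, dtype=np.int8)
        self.site_na = np.zeros(V, dtype=np.int8)
        self.occ_p = np.full((V, 2), -1, dtype=np.int32)
        self.occ_m = np.full((V, 2), -1, dtype=np.int16)
        self.Q = 0
        self.W = 0

    # -- basic properties --------------------------------------------------

    @property
    def N(self) -> int:
        return self.n_polymers

    @property
    def phi(self) -> float:
        return self.n_polymers * self.sequence.L / self.lattice.V

    @property
    def energy(self) -> float:
        """Cached total energy in units of eps."""
        return -float(self.Q) - self.J * float(self.W)

    def polymers(self) -> list[np.ndarray]:
        return [self.pos[n].copy() for n in range(self.n_polymers)]

    # -- incremental registry updates --------------------------------------

    def can_add(self, site: int, motif_type: int) -> bool:
        if self.site_n[site] >= 2:
            return False
        n_same = self.site_na[site] if motif_type == 0 else (
            self.site_n[site] - self.site_na[site])
        return n_same == 0

    def _add_monomer(self, site: int, poly: int, mono: int) -> None:
        t = self.types[mono]
        if not self.can_add(site, t):
            raise IntegrityError(
                f"cannot place monomer type {'AB'[t]} on site {site}")
        self.W += int(self.site_n[self.lattice.neighbor_table[site]].sum())
        slot = self.site_n[site]
        self.occ_p[site, slot] = poly
        self.occ_m[site, slot] = mono
        self.site_n[site] += 1
        self.site_na[site] += (t == 0)
        if self.site_n[site] == 2:       # one A and one B: a bond forms
            self.Q += 1
        self.pos[poly, mono] = site

    def _remove_monomer(self, site: int, poly: int, mono: int) -> None:
        if self.site_n[site] == 2:
            self.Q -= 1
        if self.occ_p[site, 0] == poly and self.occ_m[site, 0] == mono:
            self.occ_p[site, 0] = self.occ_p[site, 1]
            self.occ_m[site, 0] = self.occ_m[site, 1]
        elif not (self.occ_p[site, 1] == poly and self.occ_m[site, 1] == mono):
            raise IntegrityError("occupant registry out of sync")
        self.occ_p[site, 1] = -1
        self.occ_m[site, 1] = -1
        self.site_n[site] -= 1
        self.site_na[site] -= (self.types[mono] == 0)
        self.W -= int(self.site_n[self.lattice.neighbor_table[site]].sum())
        self.pos[poly, mono] = -1

    # -- construction ------------------------------------------------------

    def add_polymer(self, sites) -> int:
        """Append one polymer with the given conformation; returns its id."""
        sites = np.asarray(sites, dtype=np.int64)
        L = self.sequence.L
        if sites.shape != (L,):
            raise ValueError(f"conformation must list {L} sites")
        self._check_backbone(sites)
        if self.n_polymers >= self.max_polymers:
            raise IntegrityError("polymer capacity exhausted")
        n = self.n_polymers
        placed = []
        try:
            for k in range(L):
                self._add_monomer(int(sites[k]), n, k)
                placed.append(k)
        except IntegrityError:
            for k in reversed(placed):
                self._remove_monomer(int(sites[k]), n, k)
            raise
        self.n_polymers += 1
        return n

    def remove_polymer(self, n: int) -> np.ndarray:
        """Delete polymer ``n`` (the last polymer is swapped into its slot)."""
        if not 0 <= n < self.n_polymers:
            raise IndexError(n)
        L = self.sequence.L
        sites = self.pos[n, :].copy()
        for k in range(L):
            self._remove_monomer(int(sites[k]), n, k)
        last = self.n_polymers - 1
        if n != last:
            for k in range(L):
                s = int(self.pos[last, k])
                for slot in range(2):
                    if self.occ_p[s, slot] == last and self.occ_m[s, slot] == k:
                        self.occ_p[s, slot] = n
                        break
            self.pos[n, :] = self.pos[last, :]
        self.pos[last, :] = -1
        self.n_polymers -= 1
        return sites

    def _check_backbone(self, sites) -> None:
        nbrt = self.lattice.neighbor_table
        for k in range(len(sites) - 1):
            s1, s2 = int(sites[k]), int(sites[k + 1])
            if s1 == s2:
                if self.types[k] == self.types[k + 1]:
                    raise IntegrityError(
                        "consecutive same-type monomers cannot co-reside")
            elif s2 not in nbrt[s1]:
                raise IntegrityError(
                    f"monomers {k},{k + 1} neither adjacent nor co-resident")

    @classmethod
    def from_polymers(cls, lattice, sequence, conformations, J: float = 0.05,
                      max_polymers: int | None = None) -> "LatticeConfig":
        cfg = cls(lattice, sequence, J=J, max_polymers=max_polymers)
        for sites in conformations:
            cfg.add_polymer(sites)
        return cfg

    # -- validation and from-scratch observables ---------------------------

    def validate(self) -> None:
        """Recheck every invariant; raise IntegrityError on violation."""
        V = self.lattice.V
        site_n = np.zeros(V, dtype=np.int64)
        site_na = np.zeros(V, dtype=np.int64)
        for n in range(self.n_polymers):
            self._check_backbone(self.pos[n])
            for k in range(self.sequence.L):
                s = int(self.pos[n, k])
                site_n[s] += 1
                site_na[s] += (self.types[k] == 0)
        site_nb = site_n - site_na
        if (site_n > 2).any() or (site_na > 1).any() or (site_nb > 1).any():
            raise IntegrityError("occupancy cap or same-type overlap violated")
        if not (np.array_equal(site_n, self.site_n) and
                np.array_equal(site_na, self.site_na)):
            raise IntegrityError("occupancy registry out of sync")
        Q = int((site_na * site_nb).sum())
        r = site_n
        W = int((r * r[self.lattice.neighbor_table].sum(axis=1)).sum()) // 2
        if Q != self.Q or W != self.W:
            raise IntegrityError(
                f"energy cache out of sync: Q {self.Q}!={Q}, W {self.W}!={W}")


def total_energy(config: LatticeConfig) -> float:
    """Total energy recomputed from scratch, in units of eps."""
    config.validate()
    return config.energy


def count_bonds(config: LatticeConfig) -> tuple[np.ndarray, int]:
    """Classify each bonded site as a self-bond or a trans-bond.

    Returns ``(s_per_polymer, t_total)`` with each bonded site counted
    once; ``sum(s) + t == Q``.
    """
    s = np.zeros(config.n_polymers, dtype=np.int64)
    t = 0
    bonded = np.flatnonzero(np.asarray(config.site_n) == 2)
    for v in bonded:
        p1, p2 = int(config.occ_p[v, 0]), int(config.occ_p[v, 1])
        if p1 == p2:
            s[p1] += 1
        else:
            t += 1
    return s, t


def unwrap_conformation(sites, lattice: FccLattice) -> np.ndarray:
    """Primitive coordinates of a chain, unwrapped along the backbone."""
    coords = lattice.unravel(np.asarray(sites)).astype(np.int64)
    dims = np.array(lattice.dims)
    out = np.empty_like(coords)
    out[0] = coords[0]
    for k in range(1, len(coords)):
        d = coords[k] - coords[k - 1]
        d = (d + dims // 2) % dims - dims // 2
        out[k] = out[k - 1] + d
    extent = out.max(axis=0) - out.min(axis=0)
    if (extent > dims // 2).any():
        warnings.warn(
            "chain spans more than half the box after unwrapping; "
            "periodic image assignment is ambiguous", stacklevel=2)
    return out


def radius_of_gyration(sites, lattice: FccLattice) -> float:
    """Radius of gyration in Cartesian coordinates (lattice units)."""
    xyz = lattice.cartesian(unwrap_conformation(sites, lattice))
    centered = xyz - xyz.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def observables(config: LatticeConfig) -> Observables:
    s, t = count_bonds(config)
    rg = np.array([
        radius_of_gyration(config.pos[n], config.lattice)
        for n in range(config.n_polymers)
    ])
    return Observables(N=config.N, E=config.energy, s_per_polymer=s,
                       t_total=t, phi=config.phi, Rg_per_polymer=rg)


# -- snapshot persistence (JSON-lines) -------------------------------------

def write_snapshot(fh, step: int, config: LatticeConfig) -> None:
    rec = {
        "step": int(step),
        "N": int(config.N),
        "E": config.energy,
        "polymers": [[int(s) for s in config.pos[n]]
                     for n in range(config.n_polymers)],
    }
    fh.write(json.dumps(rec) + "\n")


def read_snapshots(path):
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)
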