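"""Joint (N, E) histograms and their text serialization.

A :class:`JointHistogram` stores weighted counts over polymer number
``N`` and binned total energy ``E`` together with the conditions
``(beta, mu, h)`` under which they were collected, which is everything
histogram reweighting needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MulticanonicalWeight:
    """Tabulated multicanonical weight ``h(N)``.

    The simulation runs under the modified Hamiltonian ``H + h(N)``.
    ``h`` is defined on ``[n_lo, n_hi]`` (the barrier region between the
    two phases) and continues flat at its boundary values outside.
    """

    n_lo: int
    n_hi: int
    values: np.ndarray  # h(N) for N in [n_lo, n_hi], units of eps
    beta: float         # the beta at which this weight applies

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_hi - self.n_lo + 1,):
            raise ValueError("values must cover n_lo..n_hi inclusive")
        if not np.isfinite(self.values).all():
            raise ValueError("h(N) must be finite on its range")

    def __call__(self, N):
        n = np.clip(np.asarray(N), self.n_lo, self.n_hi) - self.n_lo
        out = self.values[n]
        return float(out) if np.isscalar(N) else out

    def table(self, n_max: int) -> np.ndarray:
        """Dense table h(0..n_max) with flat boundary extension."""
        return self(np.arange(n_max + 1)).astype(float)

    @classmethod
    def zero(cls, beta: float = 1.0) -> "MulticanonicalWeight":
        return cls(0, 0, np.zeros(1), beta)

    def save(self, path) -> None:
        ns = np.arange(self.n_lo, self.n_hi + 1)
        np.savetxt(path, np.column_stack([ns, self.values]),
                   header=f"beta={self.beta}\nN h", fmt="%d %.12g")

    @classmethod
    def load(cls, path, beta: float) -> "MulticanonicalWeight":
        data = np.loadtxt(path, ndmin=2)
        ns = data[:, 0].astype(int)
        return cls(int(ns[0]), int(ns[-1]), data[:, 1], beta)


@dataclass
class JointHistogram:
    """Weighted counts over (N, E-bin) with collection metadata."""

    counts: np.ndarray          # (n_max+1, n_ebins)
    e_min: float                # left edge of the first energy bin
    e_bin: float                # energy bin width, units of eps
    beta: float                 # beta*eps of collection
    mu: float                   # mu/eps of collection
    h: MulticanonicalWeight | None = None
    total_sweeps: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be nonnegative")

    @property
    def n_max(self) -> int:
        return self.counts.shape[0] - 1

    def e_centers(self) -> np.ndarray:
        return self.e_min + (np.arange(self.counts.shape[1]) + 0.5) * self.e_bin

    def p_of_n(self) -> np.ndarray:
        """Normalized marginal distribution P(N)."""
        p = self.counts.sum(axis=1)
        tot = p.sum()
        return p / tot if tot > 0 else p

    def mean_n(self) -> float:
        p = self.p_of_n()
        return float(p @ np.arange(len(p)))

    def mean_e(self) -> float:
        tot = self.counts.sum()
        return float((self.counts * self.e_centers()[None, :]).sum() / tot)

    def h_table(self) -> np.ndarray:
        if self.h is None:
            return np.zeros(self.n_max + 1)
        return self.h.table(self.n_max)

    # -- persistence: three-column text (N, E-bin, count) ------------------

    def save(self, path) -> None:
        nz = np.argwhere(self.counts > 0)
        with open(path, "w") as fh:
            fh.write(f"# beta={self.beta!r} mu={self.mu!r} "
                     f"e_min={self.e_min!r} e_bin={self.e_bin!r} "
                     f"n_max={self.n_max} n_ebins={self.counts.shape[1]} "
                     f"total_sweeps={self.total_sweeps!r}\n")
            for k, v in self.meta.items():
                fh.write(f"# meta {k}={v}\n")
            fh.write("# N E_bin count\n")
            for i, j in nz:
                fh.write(f"{i} {j} {self.counts[i, j]:.12g}\n")

    @classmethod
    def load(cls, path, h: MulticanonicalWeight | None = None) -> "JointHistogram":
        meta: dict = {}
        header: dict = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line[1:].strip()
                    if body.startswith("meta "):
                        k, _, v = body[5:].partition("=")
                        meta[k] = v
                    elif "=" in body:
                        for tok in body.split():
                            if "=" in tok:
                                k, _, v = tok.partition("=")
                                header[k] = v
                    continue
                rows.append(line.split())
        counts = np.zeros((int(header["n_max"]) + 1, int(header["n_ebins"])))
        for i, j, c in rows:
            counts[int(i), int(j)] = float(c)
        return cls(counts, float(header["e_min"]), float(header["e_bin"]),
                   float(header["beta"]), float(header["mu"]), h=h,
                   total_sweeps=float(header["total_sweeps"]), meta=meta)
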