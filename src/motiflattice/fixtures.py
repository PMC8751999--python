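"""Deterministic small inputs for tests and demos."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .histograms import JointHistogram
from .lattice import FccLattice
from .montecarlo import initialize
from .sequences import MotifSequence, make_block_sequence, write_sequences
from .state import write_snapshot

KINDS = ("tiny-lattice", "toy-trajectory", "toy-histogram", "block-sequences")


def make_fixtures(kind: str, seed: int, outdir) -> list[Path]:
    """Write one family of deterministic fixture files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny-lattice":
        return [_tiny_lattice(seed, outdir)]
    if kind == "toy-trajectory":
        return [_toy_trajectory(seed, outdir)]
    if kind == "toy-histogram":
        return [_toy_histogram(seed, outdir)]
    if kind == "block-sequences":
        return [_block_sequences(outdir)]
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {KINDS}")


def _tiny_lattice(seed: int, outdir: Path) -> Path:
    lattice = FccLattice((4, 4, 4))
    seq = MotifSequence("AABB", label="tiny")
    cfg = initialize(lattice, seq, N0=3, seed=seed)
    path = outdir / "tiny_lattice.jsonl"
    with open(path, "w") as fh:
        fh.write(json.dumps({"dims": list(lattice.dims),
                             "sequence": seq.motifs, "seed": seed}) + "\n")
        write_snapshot(fh, 0, cfg)
    return path


#: planted per-polymer moments of the toy trajectory
TOY_TRAJ_MOMENTS = {"s_mean": 3.0, "s_sd": 1.2, "t_mean": 4.0, "t_sd": 1.5,
                    "rg_mean": 2.5, "rg_sd": 0.4}


def toy_trajectory_frame(seed: int, n_snapshots: int = 400,
                         n_poly: int = 50, V: int = 4096,
                         L: int = 12) -> pd.DataFrame:
    """Synthetic trajectory with known per-polymer (s, t, Rg) moments.

    Snapshots carry aggregate sums/sumsqs in the engine's trajectory
    schema, drawn from Gaussians with the planted moments
    (``TOY_TRAJ_MOMENTS``); the density is constant at ``n_poly*L/V``.
    """
    rng = np.random.default_rng(seed)
    m = TOY_TRAJ_MOMENTS
    rows = []
    for i in range(n_snapshots):
        s = rng.normal(m["s_mean"], m["s_sd"], n_poly)
        t = rng.normal(m["t_mean"], m["t_sd"], n_poly)
        rg = rng.normal(m["rg_mean"], m["rg_sd"], n_poly)
        rows.append({
            "step": (i + 1) * 1000, "N": n_poly,
            "E": -float(s.sum()) - 0.5 * float(t.sum()),
            "s_sum": float(s.sum()), "s_sumsq": float((s ** 2).sum()),
            "t_sum": float(t.sum()), "t_sumsq": float((t ** 2).sum()),
            "t_total": float(t.sum()) / 2.0,
            "rg_sum": float(rg.sum()), "rg_sumsq": float((rg ** 2).sum())})
    return pd.DataFrame(rows)


def _toy_trajectory(seed: int, outdir: Path) -> Path:
    path = outdir / "toy_trajectory.csv"
    toy_trajectory_frame(seed).to_csv(path, index=False)
    return path


def toy_bimodal_histogram(seed: int, n1: float = 40.0, n2: float = 160.0,
                          sd: float = 12.0, w1: float = 0.5,
                          beta: float = 1.0, mu: float = -5.0,
                          V: int = 4096, L: int = 12) -> JointHistogram:
    """Symmetric-weight double-Gaussian P(N) with a trivial E ridge."""
    n_max = 300
    n = np.arange(n_max + 1)
    p = (w1 * np.exp(-0.5 * ((n - n1) / sd) ** 2)
         + (1 - w1) * np.exp(-0.5 * ((n - n2) / sd) ** 2))
    counts = np.zeros((n_max + 1, 64))
    e_min, e_bin = -3000.0, 50.0
    for i in range(n_max + 1):
        eb = int((-10.0 * i - e_min) / e_bin)
        counts[i, min(max(eb, 0), 63)] = p[i]
    h = JointHistogram(counts * 1e5, e_min, e_bin, beta, mu,
                       total_sweeps=1e5,
                       meta={"sequence": "AB" * (L // 2), "V": V,
                             "synthetic": True, "seed": seed})
    return h


def _toy_histogram(seed: int, outdir: Path) -> Path:
    path = outdir / "toy_histogram.txt"
    toy_bimodal_histogram(seed).save(path)
    return path


def _block_sequences(outdir: Path) -> Path:
    path = outdir / "block_sequences.txt"
    seqs = [make_block_sequence(24, ell) for ell in (1, 2, 3, 4, 6, 12)]
    write_sequences(path, seqs)
    return path
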