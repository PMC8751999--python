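"""Condensation parameter and dense-phase material-property estimators.

The condensation parameter collapses a sequence's propensity to phase
separate into one number,

    Psi = -log[ (1 / (r_A^b * r_B^a)) * sum_s g(s) (4 <P_corr>)^{s/2} ],

where ``r_A = a/L`` and ``r_B = b/L`` are the motif fractions, ``g(s)``
the single-polymer density of states, and ``<P_corr>`` a trans-bond
correlation metric of the dense phase.  Large Psi (low self-bond
entropy, balanced stoichiometry, strong dense-phase correlations) means
a high critical temperature; a linear fit of Psi to known T_c values
for reference sequences turns Psi into a T_c estimate for arbitrary
sequences without further simulation.

With ``P_corr = 1/4`` the correlation factor drops out ("uncorrected
Psi"), which is the default when no dense-phase trajectory is
available.

Dense-phase transport is estimated by treating the droplet as a
reversibly cross-linked polymer melt: the viscosity scales as

    eta ~ G * tau = (kB T phi / (m^3 L)) * tau_b * t_bar^2,
    tau_b = tau_0 exp(beta*eps),

with ``t_bar`` the trans-bonds per polymer, and the polymer diffusivity
scales as ``1/t_bar``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import MotifSequence, make_scrambled_sequence
from .single_polymer import DensityOfStates, rosenbluth_total
from .state import LatticeConfig


@dataclass
class PsiInputs:
    g: DensityOfStates
    a: int
    b: int
    p_corr: float = 0.25     # neutral default: the factor 4*P_corr becomes 1

    def __post_init__(self):
        if self.p_corr <= 0:
            raise ValueError("P_corr must be positive")

    @property
    def L(self) -> int:
        return self.a + self.b

    @classmethod
    def from_sequence(cls, sequence: MotifSequence, g: DensityOfStates,
                      p_corr: float = 0.25) -> "PsiInputs":
        return cls(g=g, a=sequence.a, b=sequence.b, p_corr=p_corr)


def psi(inputs: PsiInputs) -> float:
    """The condensation parameter (dimensionless)."""
    a, b, L = inputs.a, inputs.b, inputs.L
    if a == 0 or b == 0:
        raise ValueError(
            "Psi diverges for single-motif-type sequences (r_A or r_B = 0)")
    r_a, r_b = a / L, b / L
    g = inputs.g
    if len(g.s) == 0 or g.g.sum() == 0:
        raise ValueError("g(s) is empty")
    terms = g.g * (4.0 * inputs.p_corr) ** (g.s / 2.0)
    log_pref = -(b * np.log(r_a) + a * np.log(r_b))
    return float(-(log_pref + np.log(terms.sum())))


# ---------------------------------------------------------------------------
# trans-bond correlation metric

def pcorr_config(config: LatticeConfig) -> float:
    """Fraction of trans-bonded motifs whose chain neighbor is also
    trans-bonded to the same partner polymer (one snapshot)."""
    L = config.sequence.L
    site_n = np.asarray(config.site_n)
    # partner polymer of each trans-bonded monomer
    partner: dict[tuple[int, int], int] = {}
    for v in np.flatnonzero(site_n == 2):
        p1, m1 = int(config.occ_p[v, 0]), int(config.occ_m[v, 0])
        p2, m2 = int(config.occ_p[v, 1]), int(config.occ_m[v, 1])
        if p1 != p2:
            partner[(p1, m1)] = p2
            partner[(p2, m2)] = p1
    if not partner:
        raise ValueError("configuration has no trans-bonds")
    hits = 0
    for (p, m), q in partner.items():
        for mn in (m - 1, m + 1):
            if 0 <= mn < L and partner.get((p, mn)) == q:
                hits += 1
                break
    return hits / len(partner)


def estimate_pcorr(configs) -> float:
    """<P_corr> averaged over snapshots (trans-bond weighted)."""
    num = 0.0
    den = 0
    for cfg in configs:
        L = cfg.sequence.L
        try:
            frac = pcorr_config(cfg)
        except ValueError:
            continue
        site_n = np.asarray(cfg.site_n)
        n_motifs = 0
        for v in np.flatnonzero(site_n == 2):
            if cfg.occ_p[v, 0] != cfg.occ_p[v, 1]:
                n_motifs += 2
        num += frac * n_motifs
        den += n_motifs
    if den == 0:
        raise ValueError("trajectory has no trans-bonds")
    return num / den


# ---------------------------------------------------------------------------
# Psi -> T_c map

@dataclass
class PsiTcFit:
    alpha: float     # slope
    gamma: float     # intercept
    residuals: np.ndarray

    def predict(self, psi_values):
        return self.alpha * np.asarray(psi_values, dtype=float) + self.gamma


def fit_tc_vs_psi(pairs) -> PsiTcFit:
    """Least-squares line T_c = alpha*Psi + gamma."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two (Psi, T_c) points")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate fit: all Psi values coincide")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return PsiTcFit(float(coef[0]), float(coef[1]), resid)


# ---------------------------------------------------------------------------
# fast approximate g(s) (pluggable alternative to the MC estimator)

def approx_gs_combinatorial(sequence: MotifSequence,
                            contact_amp: float = 0.32,
                            contact_exp: float = 1.5,
                            n_rosenbluth: int = 400,
                            seed: int = 0) -> DensityOfStates:
    """Closed-form g(s) approximation for sequence scans.

    Treats self-bonds as independent A-B contacts: pair (i, j) carries
    an effective return weight ``contact_amp * |i-j|^(-contact_exp)``
    (the 3D random-walk loop-closure scaling), and s bonds contribute
    the s-th power of the summed pair weight divided by s!.  The
    absolute scale is set by a small Rosenbluth estimate of the total
    conformation count.  The amplitude is calibrated against exact
    enumerations of short chains; this is a speed-over-accuracy stub,
    validated only against the exact oracle.
    """
    codes = sequence.codes()
    a_pos = np.flatnonzero(codes == 0)
    b_pos = np.flatnonzero(codes == 1)
    smax = min(len(a_pos), len(b_pos))
    dist = np.abs(a_pos[:, None] - b_pos[None, :]).astype(float)
    omega = contact_amp * dist ** (-contact_exp)
    total_w = omega.sum()
    s = np.arange(smax + 1)
    from scipy.special import gammaln
    log_terms = s * np.log(max(total_w, 1e-300)) - gammaln(s + 1)
    rel = np.exp(log_terms - log_terms.max())
    tot, _ = rosenbluth_total(sequence, n_samples=n_rosenbluth, seed=seed)
    g = rel / rel.sum() * tot
    return DensityOfStates(sequence.label or sequence.motifs, s, g,
                           method="combinatorial-approx")


# ---------------------------------------------------------------------------
# random-sequence scan

def scan_random_sequences(n: int, L: int, a: int, seed: int,
                          g_estimator=None, fit: PsiTcFit | None = None,
                          p_corr: float = 0.25) -> pd.DataFrame:
    """Psi (and mapped T_c) for ``n`` random sequences of fixed (L, a).

    ``g_estimator`` maps a sequence to a DensityOfStates; the default
    is a short multihistogram Monte Carlo estimate.
    """
    if g_estimator is None:
        from .single_polymer import estimate_gs_mc

        def g_estimator(seq, i):
            return estimate_gs_mc(
                seq, betas=np.geomspace(0.3, 1.8, 5), steps=40_000,
                seed=seed + 7 * i + 3, sample_every=10, n_rosenbluth=400)

    rows = []
    for i in range(n):
        seq = make_scrambled_sequence(L, a, seed + 1000 + i)
        g = g_estimator(seq, i)
        val = psi(PsiInputs.from_sequence(seq, g, p_corr=p_corr))
        row = {"sequence": seq.motifs, "a": seq.a, "b": seq.b, "psi": val,
               "p_corr": p_corr}
        if fit is not None:
            row["t_c_estimate"] = float(fit.predict(val))
        rows.append(row)
    cols = ["sequence", "a", "b", "psi", "p_corr"]
    if fit is not None:
        cols.append("t_c_estimate")
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# material properties

@dataclass
class ViscosityInputs:
    t_bar: float        # trans-bonds per polymer
    phi_dense: float
    beta_eps: float
    L: int
    tau0: float = 1.0   # microscopic time (arbitrary units)
    m: float = 1.0      # monomer length

    def __post_init__(self):
        for name in ("t_bar", "phi_dense", "beta_eps", "tau0", "m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def viscosity(inputs: ViscosityInputs) -> float:
    """Dense-phase viscosity estimate, units kB*T*tau0/m^3.

    eta = (phi / (m^3 L)) * tau0 * exp(beta*eps) * t_bar^2: the elastic
    modulus of the melt times the reversible-crosslink relaxation time.
    """
    return (inputs.phi_dense / (inputs.m ** 3 * inputs.L)
            * inputs.tau0 * np.exp(inputs.beta_eps) * inputs.t_bar ** 2)


def diffusivity_proxy(t_bar: float) -> float:
    """Relative polymer diffusivity, ~ 1/t_bar (comparisons only)."""
    if t_bar <= 0:
        raise ValueError(
            "diffusivity proxy undefined at t_bar = 0: diffusion is "
            "unhindered by trans-bonds")
    return 1.0 / t_bar
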