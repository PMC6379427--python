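"""Methyl-axis order parameters from intra-methyl cross-correlated relaxation.

Triple-quantum-filtered ("forbidden") and single-quantum-filtered ("allowed")
intensities build up with relaxation delay T as

    I_tq/I_sq = (3/4) * eta * tanh(sqrt(eta^2 + delta^2) T)
                / (sqrt(eta^2 + delta^2) - delta * tanh(sqrt(eta^2 + delta^2) T))

where eta is the intra-methyl 1H-1H dipolar cross-correlated relaxation rate
and delta absorbs couplings to external protons.  For a methyl group rotating
about its symmetry axis,

    eta ~= (9/10) (mu0/4pi)^2 [P2(cos theta_HH)]^2 O2 gammaH^4 hbar^2 tau_c
           / r_HH^6

so the axis order parameter O2 follows linearly from eta once the overall
tumbling time tau_c is known (here from dynamic light scattering through the
Stokes-Einstein relation).

Covariation of O2 across ligation states is summarized as a Pearson
correlation network over methyl pairs: each methyl's O2 profile across the
ordered state series is a vector, pairs with coefficient above a cutoff
(default 0.9) are edges.  Profiles are ordered series; correlating them is
meaningful only when every methyl uses the same state order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import DEFAULT_METHYL_CONSTANTS, K_BOLTZMANN, MethylConstants
from .data_io import IntensityDecaySet, MethylId
from .errors import FitError, ValidationError

__all__ = [
    "CrossCorrelation", "OrderParameter", "O2Network", "tq_sq_ratio",
    "fit_eta", "fit_decay_set", "eta_coefficient", "order_parameter",
    "forward_eta", "tau_c_from_dls", "delta_o2", "o2_covariance",
]


@dataclass
class CrossCorrelation:
    """Fitted cross-correlation rate for one methyl."""

    eta: float              # s^-1
    eta_sd: float
    delta_ext: float        # s^-1, external-proton coupling constant
    delta_sd: float
    converged: bool = True
    at_bound: bool = False
    residual_rms: float = float("nan")

    @property
    def usable(self) -> bool:
        return self.converged and not self.at_bound and self.eta > 0


@dataclass
class OrderParameter:
    o2: float               # clipped to [0, 1]
    o2_raw: float           # as inverted, may exceed 1 slightly
    o2_sd: float
    tau_c_ns: float
    plausible: bool = True  # False when raw value > 1.2


def tq_sq_ratio(eta, delta_ext, T):
    """Forbidden/allowed intensity ratio at relaxation delay T (s)."""
    eta = np.asarray(eta, dtype=float)
    T = np.asarray(T, dtype=float)
    lam = np.sqrt(eta ** 2 + delta_ext ** 2)
    th = np.tanh(lam * T)
    return 0.75 * eta * th / (lam - delta_ext * th)


def fit_eta(delays_s: np.ndarray, ratio: np.ndarray,
            ratio_sd: np.ndarray | None = None, n_mc: int = 500,
            seed: int | None = None) -> CrossCorrelation:
    """Nonlinear least-squares fit of (eta, delta_ext) to a TQ/SQ ratio decay.

    delta_ext is bounded below at 0.  Uncertainties come from Monte-Carlo
    resampling of the ratios with their per-point standard deviations.
    """
    delays_s = np.asarray(delays_s, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if len(delays_s) < 5:
        raise ValidationError("need >= 5 delay points to fit eta")
    if ratio_sd is None:
        ratio_sd = np.full_like(ratio, max(1e-3, 0.01 * np.max(np.abs(ratio))))
    ratio_sd = np.asarray(ratio_sd, dtype=float)

    def _solve(y):
        def resid(p):
            return tq_sq_ratio(p[0], p[1], delays_s) - y
        # slope at the origin of the ratio curve is ~(3/4) eta T
        eta0 = max(4.0 / 3.0 * y[0] / delays_s[0], 1.0)
        sol = least_squares(resid, x0=[eta0, 1.0],
                            bounds=([1e-12, 0.0], [1e4, 1e4]), max_nfev=2000)
        return sol

    sol = _solve(ratio)
    eta_hat, delta_hat = sol.x
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    converged = bool(sol.success) and rms < 10.0 * np.mean(ratio_sd) + 1e-9
    # degenerate (T-independent) data pins eta at a bound or leaves a large
    # residual; flag rather than report a rate
    at_bound = bool(eta_hat <= 2e-12 or eta_hat >= 9.99e3)
    if np.ptp(ratio) < 1e-12:
        converged = False

    eta_sd = delta_sd = float("nan")
    if converged and not at_bound and n_mc > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_mc):
            y = ratio + rng.normal(0.0, ratio_sd)
            try:
                s = _solve(y)
                if s.success:
                    draws.append(s.x)
            except Exception:
                continue
        if len(draws) >= max(10, n_mc // 4):
            draws = np.asarray(draws)
            eta_sd, delta_sd = draws.std(axis=0, ddof=1)
    return CrossCorrelation(eta=float(eta_hat), eta_sd=float(eta_sd),
                            delta_ext=float(delta_hat), delta_sd=float(delta_sd),
                            converged=converged, at_bound=at_bound,
                            residual_rms=rms)


def fit_decay_set(decays: IntensityDecaySet, tau_c_ns: float,
                  n_mc: int = 500, seed: int = 0,
                  constants: MethylConstants = DEFAULT_METHYL_CONSTANTS
                  ) -> pd.DataFrame:
    """Fit every methyl in a decay set and convert eta to O2.

    Returns one row per methyl with fit diagnostics; unusable fits (flagged
    non-converged or at a parameter bound) carry NaN order parameters.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for mid, grp in decays.groupby_methyl():
        t = grp["delay_s"].to_numpy()
        ratio = grp["I_tq"].to_numpy() / grp["I_sq"].to_numpy()
        # first-order error propagation on the ratio
        sd = np.abs(ratio) * np.sqrt(
            (grp["err_tq"].to_numpy() / grp["I_tq"].to_numpy()) ** 2
            + (grp["err_sq"].to_numpy() / grp["I_sq"].to_numpy()) ** 2)
        sd = np.where(sd > 0, sd, 1e-4)
        cc = fit_eta(t, ratio, sd, n_mc=n_mc, seed=int(rng.integers(2 ** 31)))
        if cc.usable:
            op = order_parameter(cc.eta, tau_c_ns, eta_sd=cc.eta_sd,
                                 constants=constants)
            o2, o2_raw, o2_sd, plaus = op.o2, op.o2_raw, op.o2_sd, op.plausible
        else:
            o2 = o2_raw = o2_sd = float("nan")
            plaus = False
        rows.append({"residue": mid.residue_number, "restype": mid.residue_type,
                     "methyl": mid.methyl_label, "eta": cc.eta,
                     "eta_sd": cc.eta_sd, "delta_ext": cc.delta_ext,
                     "O2": o2, "O2_raw": o2_raw, "O2_sd": o2_sd,
                     "usable": cc.usable, "plausible": plaus})
    return pd.DataFrame(rows)


def eta_coefficient(tau_c_ns: float,
                    constants: MethylConstants = DEFAULT_METHYL_CONSTANTS
                    ) -> float:
    """eta per unit O2 (s^-1) at the given tumbling time."""
    p2 = 0.5 * (3.0 * np.cos(np.deg2rad(constants.theta_hh_deg)) ** 2 - 1.0)
    return (0.9 * constants.mu0_over_4pi ** 2 * p2 ** 2
            * constants.gamma_h ** 4 * constants.hbar ** 2
            * (tau_c_ns * 1e-9) / constants.r_hh_m ** 6)


def forward_eta(o2: float, tau_c_ns: float,
                constants: MethylConstants = DEFAULT_METHYL_CONSTANTS) -> float:
    """Cross-correlation rate predicted for a given order parameter."""
    return o2 * eta_coefficient(tau_c_ns, constants)


def order_parameter(eta: float, tau_c_ns: float, eta_sd: float = float("nan"),
                    constants: MethylConstants = DEFAULT_METHYL_CONSTANTS
                    ) -> OrderParameter:
    """Invert the eta(O2, tau_c) relation.  Raw values above 1.2 are flagged
    physically implausible; the reported O2 is clipped to [0, 1]."""
    if eta <= 0 or tau_c_ns <= 0:
        raise ValidationError("eta and tau_c must be > 0")
    coeff = eta_coefficient(tau_c_ns, constants)
    raw = eta / coeff
    return OrderParameter(o2=float(np.clip(raw, 0.0, 1.0)), o2_raw=float(raw),
                          o2_sd=float(eta_sd / coeff), tau_c_ns=tau_c_ns,
                          plausible=bool(raw <= 1.2))


def tau_c_from_dls(hydrodynamic_radius_nm: float, T: float = 300.0,
                   viscosity_Pa_s: float = 0.851e-3) -> float:
    """Rotational correlation time (ns) from the Stokes-Einstein relation,
    tau_c = 4 pi eta_visc r^3 / (3 kB T).  Default viscosity is water at
    300 K."""
    if hydrodynamic_radius_nm <= 0:
        raise ValidationError("radius must be > 0")
    r = hydrodynamic_radius_nm * 1e-9
    tau_s = 4.0 * np.pi * viscosity_Pa_s * r ** 3 / (3.0 * K_BOLTZMANN * T)
    return tau_s * 1e9


def delta_o2(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-methyl O2(b) - O2(a) on the shared methyls, with propagated sd.

    Sign convention: a positive value means the later state (b) is more
    rigid.  Compose two calls for a ddO2 between transitions.
    """
    key = ["residue", "restype", "methyl"]
    merged = table_a.merge(table_b, on=key, suffixes=("_a", "_b"))
    if merged.empty:
        raise ValidationError("no shared methyls between the two tables")
    merged["dO2"] = merged["O2_b"] - merged["O2_a"]
    merged["dO2_sd"] = np.hypot(merged.get("O2_sd_a", 0.0),
                                merged.get("O2_sd_b", 0.0))
    return merged[key + ["dO2", "dO2_sd"]]


@dataclass
class O2Network:
    """Pearson-correlation network of order-parameter profiles."""

    methyls: list[MethylId]
    pearson: np.ndarray             # symmetric, unit diagonal, NaN where masked
    cutoff: float
    edges: list[tuple[MethylId, MethylId, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        labels = [f"{m.residue_type}{m.residue_number}-{m.methyl_label}"
                  for m in self.methyls]
        return pd.DataFrame(self.pearson, index=labels, columns=labels)


def o2_covariance(state_tables: dict[str, pd.DataFrame],
                  cutoff: float = 0.9, min_states: int = 4) -> O2Network:
    """Pearson correlation of O2 state-profiles for every methyl pair.

    ``state_tables`` maps state name -> per-methyl O2 table (columns residue,
    restype, methyl, O2) in cycle order.  Methyls present in fewer than
    ``min_states`` states are dropped; zero-variance profiles are masked
    (their pair coefficients are NaN and form no edges).
    """
    states = list(state_tables)
    if len(states) < min_states:
        raise ValidationError(f"need >= {min_states} states, got {len(states)}")
    profiles: dict[MethylId, list[float]] = {}
    for st in states:
        tab = state_tables[st]
        for _, row in tab.iterrows():
            mid = MethylId(int(row["residue"]), str(row["restype"]),
                           str(row["methyl"]))
            profiles.setdefault(mid, []).append(float(row["O2"]))
    keep = [m for m, v in profiles.items()
            if len(v) == len(states) and np.all(np.isfinite(v))]
    if len(keep) < 2:
        raise ValidationError("fewer than 2 methyls with complete profiles")
    mat = np.asarray([profiles[m] for m in keep])
    sd = mat.std(axis=1)
    n = len(keep)
    pear = np.full((n, n), np.nan)
    np.fill_diagonal(pear, 1.0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(mat[ok])
        idx = np.flatnonzero(ok)
        pear[np.ix_(idx, idx)] = sub
        np.fill_diagonal(pear, 1.0)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            rij = pear[i, j]
            if np.isfinite(rij) and rij > cutoff:
                edges.append((keep[i], keep[j], float(rij)))
    return O2Network(methyls=keep, pearson=pear, cutoff=cutoff, edges=edges)
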