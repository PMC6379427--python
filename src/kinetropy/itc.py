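"""Wiseman-isotherm fitting and binding thermodynamics for 1:1 ITC data.

The differential heat per mole of injectant for a single-site binding model is

    dQ/d[X_tot] = dH * V0 * [ 1/2 + (1 - (1+r)/2 - Rm/2)
                              / sqrt(Rm^2 - 2 Rm (1-r) + (1+r)^2) ]

with r = Kd / M_tot (inverse c-value) and Rm = X_tot / M_tot the molar ratio.
Per-injection heats integrate this differential between the pre- and
post-injection ligand concentrations (midpoint rule) with the standard
perfusion-cell displacement algebra: each injection of volume v displaces a
fraction v/V0 of the cell contents, diluting both species.

Derived quantities follow the thermodynamic identities
dG = R T ln(Kd[M]), T dS = dH - dG, and the K-type cooperativity coefficient
sigma = Kd(apo) / Kd(nucleotide-saturated); sigma > 1 is positive
cooperativity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_KCAL
from .data_io import Isotherm
from .errors import FitError

__all__ = [
    "BindingThermo", "CooperativityResult", "wiseman_differential",
    "predict_heats", "fit_isotherm", "free_energy", "entropy_term",
    "cooperativity", "ddg_ladder",
]


@dataclass
class BindingThermo:
    """Fitted binding thermodynamics for one titration."""

    kd_uM: float
    kd_sd_uM: float
    dH_kcal: float
    dH_sd_kcal: float
    dG_kcal: float
    TdS_kcal: float
    dG_sd_kcal: float = float("nan")
    TdS_sd_kcal: float = float("nan")
    temperature_K: float = 300.0
    heat_offset_ucal: float = 0.0
    kd_identifiable: bool = True

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "Kd_uM": self.kd_uM, "Kd_sd_uM": self.kd_sd_uM,
            "dG_kcal_mol": self.dG_kcal, "dG_sd_kcal_mol": self.dG_sd_kcal,
            "dH_kcal_mol": self.dH_kcal, "dH_sd_kcal_mol": self.dH_sd_kcal,
            "TdS_kcal_mol": self.TdS_kcal, "TdS_sd_kcal_mol": self.TdS_sd_kcal,
            "temperature_K": self.temperature_K,
        }])


@dataclass
class CooperativityResult:
    sigma: float
    kd_apo_uM: float
    kd_nucleotide_uM: float


def wiseman_differential(Rm, r, dH_kcal: float, V0_mL: float):
    """Differential heat per mole of injected ligand, kcal (mol/L)^-1 scaled
    by the cell volume: dH * V0 * d[MX]/d[X_tot].

    Rm is the running molar ratio X_tot/M_tot and r = Kd/M_tot.  The
    discriminant Rm^2 - 2Rm(1-r) + (1+r)^2 is non-negative for r >= 0; the
    tight-binding corner Rm=1, r=0 is a removable 0/0 handled by its limit.
    """
    Rm = np.asarray(Rm, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(Rm < 0):
        raise ValueError("Rm and r must be non-negative")
    disc = Rm ** 2 - 2.0 * Rm * (1.0 - r) + (1.0 + r) ** 2
    assert np.all(disc >= -1e-12), "negative discriminant for r >= 0"
    disc = np.maximum(disc, 0.0)
    num = 1.0 - (1.0 + r) / 2.0 - Rm / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(disc > 0, num / np.sqrt(disc), 0.0)
    return dH_kcal * V0_mL * (0.5 + frac)


def predict_heats(kd_uM: float, dH_kcal: float, iso: Isotherm,
                  offset_ucal: float = 0.0) -> np.ndarray:
    """Per-injection heats (microcal) for a 1:1 Wiseman model.

    Integrates the differential isotherm over each injection's ligand
    increment by the midpoint rule, with displaced-volume dilution applied to
    both the macromolecule and the previously injected ligand.
    """
    kd_M = kd_uM * 1e-6
    v0_L = iso.cell_volume_mL * 1e-3
    vols_L = iso.volumes_uL * 1e-6

    heats = np.empty(iso.n_injections)
    m_tot = iso.cell_conc_M
    x_tot = 0.0
    for i, v in enumerate(vols_L):
        f = v / v0_L                      # displaced fraction
        m_new = m_tot * (1.0 - f)
        x_after_disp = x_tot * (1.0 - f)
        x_new = x_after_disp + iso.syringe_conc_M * f
        # ligand increment actually added to the cell, mol/L
        dx = x_new - x_after_disp
        m_mid = 0.5 * (m_tot + m_new)
        rm_mid = 0.5 * (x_after_disp + x_new) / m_mid
        r_mid = kd_M / m_mid
        # dH [kcal/mol] * V0 [L] * dQ/dXtot [-] * dx [mol/L] -> kcal; to ucal
        dq = wiseman_differential(rm_mid, r_mid, dH_kcal, v0_L) * dx
        heats[i] = dq * 1e9 + offset_ucal
        m_tot, x_tot = m_new, x_new
    return heats


def fit_isotherm(iso: Isotherm, fit_offset: bool = True) -> BindingThermo:
    """Least-squares fit of (Kd, dH, heat-of-dilution offset) to an isotherm.

    The stoichiometry is fixed at 1:1.  Parameter uncertainties come from the
    Jacobian-based covariance at the optimum; dG and TdS uncertainties by
    first-order propagation.
    """
    q = iso.heats_ucal
    scale = np.max(np.abs(q))
    if scale == 0 or np.ptp(q) < 1e-12 * max(scale, 1.0):
        return BindingThermo(
            kd_uM=float("nan"), kd_sd_uM=float("nan"),
            dH_kcal=0.0, dH_sd_kcal=0.0, dG_kcal=float("nan"),
            TdS_kcal=float("nan"), temperature_K=iso.temperature_K,
            kd_identifiable=False)

    # crude dH seed from the first-injection heat assuming full binding
    v1_L = iso.volumes_uL[0] * 1e-6
    dx1 = iso.syringe_conc_M * v1_L / (iso.cell_volume_mL * 1e-3)
    dh0 = (q[0] * 1e-9) / (dx1 * iso.cell_volume_mL * 1e-3)
    kd0 = iso.cell_conc_M * 0.1 * 1e6  # c-value ~10 start

    def resid(p):
        log_kd, dh = p[0], p[1]
        off = p[2] if fit_offset else 0.0
        return predict_heats(np.exp(log_kd), dh, iso, off) - q

    best = None
    for kd_try in (kd0 * 0.1, kd0, kd0 * 10.0):
        x0 = [np.log(kd_try), dh0] + ([0.0] if fit_offset else [])
        try:
            sol = least_squares(resid, x0=x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("isotherm fit failed to converge")

    log_kd, dh = best.x[0], best.x[1]
    off = best.x[2] if fit_offset else 0.0
    kd_uM = float(np.exp(log_kd))

    # covariance from the Jacobian
    dof = max(len(q) - len(best.x), 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        sd_logkd, sd_dh = np.sqrt(np.abs(np.diag(cov)))[:2]
    except np.linalg.LinAlgError:
        sd_logkd = sd_dh = float("nan")
    kd_sd = kd_uM * sd_logkd

    T = iso.temperature_K
    c_value = iso.cell_conc_M / (kd_uM * 1e-6)
    if c_value > 1000:
        warnings.warn(f"c-value {c_value:.3g} > 1000: Kd is ill-conditioned",
                      stacklevel=2)
    dG = free_energy(kd_uM, T)
    TdS = entropy_term(dh, dG)
    dG_sd = R_KCAL * T * sd_logkd                 # d(dG)/d(ln Kd) = RT
    TdS_sd = float(np.hypot(sd_dh, dG_sd))
    return BindingThermo(
        kd_uM=kd_uM, kd_sd_uM=float(kd_sd), dH_kcal=float(dh),
        dH_sd_kcal=float(sd_dh), dG_kcal=dG, TdS_kcal=TdS,
        dG_sd_kcal=float(dG_sd), TdS_sd_kcal=TdS_sd,
        temperature_K=T, heat_offset_ucal=float(off))


def free_energy(kd_uM: float, T: float = 300.0,
                gas_constant: float = R_KCAL) -> float:
    """Binding free energy dG = R T ln(Kd in molar units), kcal mol^-1.
    Negative for sub-molar dissociation constants."""
    if kd_uM <= 0:
        raise ValueError("Kd must be > 0")
    return gas_constant * T * np.log(kd_uM * 1e-6)


def entropy_term(dH_kcal: float, dG_kcal: float) -> float:
    """T dS = dH - dG (all kcal mol^-1)."""
    return dH_kcal - dG_kcal


def cooperativity(kd_apo_uM: float, kd_nucleotide_uM: float) -> CooperativityResult:
    """K-type cooperativity sigma = Kd(apo)/Kd(nucleotide-bound).
    sigma > 1: nucleotide binding tightens substrate binding (positive)."""
    if kd_apo_uM <= 0 or kd_nucleotide_uM <= 0:
        raise ValueError("Kd values must be > 0")
    return CooperativityResult(sigma=kd_apo_uM / kd_nucleotide_uM,
                               kd_apo_uM=kd_apo_uM,
                               kd_nucleotide_uM=kd_nucleotide_uM)


def ddg_ladder(step_dG: list[float], labels: list[str] | None = None,
               reference: str = "reference") -> dict[str, float]:
    """Cumulative binding free-energy changes along a ligation cycle,
    relative to the reference (first) state.  Returns {state: ddG}."""
    labels = labels if labels is not None else [f"step{i+1}"
                                                for i in range(len(step_dG))]
    if len(labels) != len(step_dG):
        raise ValueError("labels and steps must have equal length")
    out = {reference: 0.0}
    total = 0.0
    for lab, dg in zip(labels, step_dG):
        total += dg
        out[lab] = total
    return out
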