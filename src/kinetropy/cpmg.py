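"""Methyl single-quantum CPMG relaxation dispersion: R2,eff extraction,
two-state Carver-Richards fitting, and a numerical Bloch-McConnell oracle.

Constant-time CPMG intensities convert to effective transverse rates as
R2,eff = -(1/T_cp) ln(I/I0).  Dispersion curves are fit to the closed-form
Carver-Richards expression for two-state exchange A <-> B (populations
p_A > p_B, exchange rate k_ex = k_AB + k_BA, shift difference dw in rad/s):

    R2(1/tau_cp) = R2_0 + 1/2 [ k_ex - (1/tau_cp) acosh(D+ cosh(eta+)
                                                        - D- cos(eta-)) ]
    D+-   = 1/2 [ +-1 + (psi + 2 dw^2) / sqrt(psi^2 + xi^2) ]
    eta+- = (tau_cp / sqrt(2)) sqrt( +-psi + sqrt(psi^2 + xi^2) )
    psi   = k_ex^2 - dw^2,   xi = -2 dw k_ex (p_A - p_B)

with tau_cp = 1/(2 nu_CPMG) the spacing between refocusing pulses.  This is
the standard closed form; at dw = 0 it reduces exactly to R2_0.

The independent oracle propagates two-state transverse magnetization through
the echo train numerically (free precession with exchange between pulses,
ideal 180-degree pulses as complex conjugation) and never shares code with
the closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .constants import DEFAULT_METHYL_CONSTANTS
from .data_io import DispersionSet, MethylId
from .errors import FitError, ValidationError

__all__ = [
    "ExchangeFit", "r2eff_from_intensities", "dispersion_curves",
    "dw_ppm_to_rad", "carver_richards", "bloch_mcconnell_r2eff",
    "fit_dispersion", "rex",
]

GAMMA_RATIO_CH = DEFAULT_METHYL_CONSTANTS.gamma_ratio_c_h


@dataclass
class ExchangeFit:
    """Two-state exchange parameters for one methyl, shared across fields."""

    p_b: float
    k_ex: float                      # s^-1
    dw_ppm: float                    # |dw| on the 13C scale
    r2_0: dict[float, float]         # intrinsic rate per field, s^-1
    chi2: float = float("nan")
    n_points: int = 0
    exchange_detected: bool = True
    single_field: bool = False
    p_b_sd: float = float("nan")
    k_ex_sd: float = float("nan")
    dw_ppm_sd: float = float("nan")

    @property
    def p_a(self) -> float:
        return 1.0 - self.p_b

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_b <= 0.5):
            raise ValidationError(f"p_B must lie in [0, 0.5], got {self.p_b}")
        if self.k_ex < 0:
            raise ValidationError("k_ex must be >= 0")


def r2eff_from_intensities(intensity, ref_intensity, t_cp: float = 0.040):
    """R2,eff = -(1/T_cp) ln(I/I0).  Intensities at or above I0*e (which
    would imply R2,eff <= -1/T_cp) are flagged as NaN."""
    I = np.asarray(intensity, dtype=float)
    I0 = np.asarray(ref_intensity, dtype=float)
    if np.any(I <= 0) or np.any(I0 <= 0):
        raise ValidationError("intensities must be positive")
    r = -np.log(I / I0) / t_cp
    bad = I >= I0 * np.e
    if np.any(bad):
        r = np.where(bad, np.nan, r)
    return r if r.ndim else float(r)


def dispersion_curves(disp: DispersionSet) -> dict[MethylId, pd.DataFrame]:
    """Convert a raw dispersion table to per-methyl R2,eff curves.

    Replicate points (same field and nu_CPMG) are all retained; the pooled
    replicate spread sets the per-point uncertainty for every point at that
    field (the usual treatment when only a few frequencies are duplicated).
    """
    out: dict[MethylId, pd.DataFrame] = {}
    for mid, grp in disp.groupby_methyl():
        g = grp.copy()
        g["r2eff"] = r2eff_from_intensities(g["intensity"].to_numpy(),
                                            g["ref_intensity"].to_numpy(),
                                            disp.t_cp)
        parts = []
        for fld, gf in g.groupby("field_MHz"):
            reps = gf.groupby("nu_cpmg_hz")["r2eff"]
            spread = reps.std(ddof=1).dropna()
            sd = float(spread.mean()) if len(spread) else float("nan")
            if not np.isfinite(sd) or sd <= 0:
                sd = 0.02 * float(np.nanmedian(np.abs(gf["r2eff"]))) or 0.1
            gf = gf.assign(r2eff_sd=sd)
            parts.append(gf)
        out[mid] = pd.concat(parts)[["field_MHz", "nu_cpmg_hz",
                                     "r2eff", "r2eff_sd"]].reset_index(drop=True)
    return out


def dw_ppm_to_rad(dw_ppm: float, field_MHz: float) -> float:
    """13C chemical-shift difference, ppm -> rad/s, at a spectrometer whose
    1H frequency is field_MHz."""
    return dw_ppm * field_MHz * GAMMA_RATIO_CH * 2.0 * np.pi


def carver_richards(nu_cpmg, r2_0: float, p_b: float, k_ex: float,
                    dw_rad: float):
    """Closed-form two-state R2,eff at the given refocusing frequencies."""
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValidationError("nu_CPMG must be > 0")
    if dw_rad == 0.0 or p_b == 0.0 or k_ex == 0.0:
        return np.full_like(nu, float(r2_0)) if nu.ndim else float(r2_0)
    p_a = 1.0 - p_b
    tau = 1.0 / (2.0 * nu)
    dw2 = dw_rad ** 2
    psi = k_ex ** 2 - dw2
    xi = -2.0 * dw_rad * k_ex * (p_a - p_b)
    root = np.sqrt(psi ** 2 + xi ** 2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw2) / root)
    eta_plus = tau / np.sqrt(2.0) * np.sqrt(np.maximum(psi + root, 0.0))
    eta_minus = tau / np.sqrt(2.0) * np.sqrt(np.maximum(root - psi, 0.0))
    # cosh overflows around 710; in that regime acosh(D+ cosh x) ~ x + ln(D+)
    with np.errstate(over="ignore"):
        safe = eta_plus < 350.0
        arg = np.where(safe,
                       d_plus * np.cosh(np.where(safe, eta_plus, 0.0))
                       - d_minus * np.cos(eta_minus), np.inf)
    acosh = np.where(safe, np.arccosh(np.maximum(arg, 1.0)),
                     eta_plus + np.log(np.maximum(d_plus, 1e-300)))
    r2 = r2_0 + 0.5 * (k_ex - acosh / tau)
    return r2 if r2.ndim else float(r2)


def bloch_mcconnell_r2eff(nu_cpmg, r2_0: float, p_b: float, k_ex: float,
                          dw_rad: float, t_cp: float = 0.040):
    """Numerical two-state CPMG propagation (independent oracle).

    Transverse magnetization of states A and B evolves under exchange,
    relaxation (equal intrinsic rates) and a frequency offset dw on state B;
    ideal 180-degree pulses conjugate the complex magnetization.  The
    effective rate is taken from the decay of the observed (state A)
    magnetization over one constant-time period in the established echo
    train, R2,eff = -(1/T_cp) ln(|M_A(2 T_cp)| / |M_A(T_cp)|): the first
    T_cp of evolution carries a duration-independent amplitude transient
    (the initial condition is not an eigenvector of the echo propagator)
    that is not part of the dispersion rate the closed form describes.
    The number of echo periods is rounded to the nearest integer; a warning
    reports the actually simulated frequency if it differs by more than 0.1%.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    p_a = 1.0 - p_b
    k_ab = p_b * k_ex
    k_ba = p_a * k_ex
    out = np.empty_like(nu)
    for i, v in enumerate(nu):
        n_echo = max(1, int(round(2.0 * v * t_cp)))
        v_actual = n_echo / (2.0 * t_cp)
        if abs(v_actual - v) > 1e-3 * v:
            warnings.warn(f"nu_CPMG {v} Hz not commensurate with T_cp; "
                          f"simulating {v_actual} Hz", stacklevel=2)
        tau = t_cp / n_echo
        L = np.array([[-r2_0 - k_ab, k_ba],
                      [k_ab, -r2_0 - k_ba - 1j * dw_rad]], dtype=complex)
        e_half = expm(L * (tau / 2.0))
        m = np.array([p_a, p_b], dtype=complex)
        for _ in range(n_echo):
            m = e_half @ np.conj(e_half @ m)
        m_t = m
        for _ in range(n_echo):
            m = e_half @ np.conj(e_half @ m)
        out[i] = -np.log(abs(m[0]) / abs(m_t[0])) / t_cp
    return out if np.ndim(nu_cpmg) else float(out[0])


_KEX_GRID = (100.0, 300.0, 1000.0, 3000.0)
_PB_GRID = (0.01, 0.05, 0.15)


def fit_dispersion(curve: pd.DataFrame, n_mc: int = 0, seed: int = 0,
                   f_test_alpha: float = 0.01,
                   min_rex: float = 0.5) -> ExchangeFit:
    """Joint Carver-Richards fit of one methyl's dispersion curves.

    ``curve`` has columns field_MHz, nu_cpmg_hz, r2eff, r2eff_sd; one or two
    fields.  (p_B, k_ex, dw_ppm) are shared across fields, R2_0 is per field.
    The chi-square surface is multimodal, so local fits are restarted from a
    log-spaced k_ex x p_B grid.  Exchange is declared detected when the
    exchange model beats a flat (R2_0-only) model by an F-test at
    ``f_test_alpha`` and the fitted dispersion amplitude exceeds ``min_rex``.
    Monte-Carlo resampling (n_mc > 0) supplies parameter uncertainties.
    """
    fields = sorted(curve["field_MHz"].unique())
    if not fields:
        raise ValidationError("empty dispersion curve")
    for fld in fields:
        if (curve["field_MHz"] == fld).sum() < 8:
            raise ValidationError(f"need >= 8 nu_CPMG points per field "
                                  f"(field {fld} MHz)")
    nu = curve["nu_cpmg_hz"].to_numpy()
    y = curve["r2eff"].to_numpy()
    sd = curve["r2eff_sd"].to_numpy()
    fld_arr = curve["field_MHz"].to_numpy()
    n = len(y)

    # flat model: per-field weighted mean
    chi2_flat = 0.0
    flat_r20 = {}
    for fld in fields:
        m = fld_arr == fld
        w = 1.0 / sd[m] ** 2
        mu = float(np.sum(w * y[m]) / np.sum(w))
        flat_r20[fld] = mu
        chi2_flat += float(np.sum(((y[m] - mu) / sd[m]) ** 2))

    def model(theta):
        pb, log_kex, dw_ppm = theta[:3]
        r20s = theta[3:]
        kex = np.exp(log_kex)
        out = np.empty(n)
        for k, fld in enumerate(fields):
            m = fld_arr == fld
            dw_rad = dw_ppm_to_rad(dw_ppm, fld)
            out[m] = carver_richards(nu[m], r20s[k], pb, kex, dw_rad)
        return out

    def resid(theta):
        return (model(theta) - y) / sd

    r20_init = [float(np.min(y[fld_arr == fld])) for fld in fields]
    lo = [1e-6, np.log(1.0), 0.0] + [0.0] * len(fields)
    hi = [0.5, np.log(1e6), 20.0] + [1e4] * len(fields)
    best = None
    for kex0 in _KEX_GRID:
        for pb0 in _PB_GRID:
            x0 = [pb0, np.log(kex0), 1.5] + r20_init
            try:
                sol = least_squares(resid, x0=x0, bounds=(lo, hi),
                                    max_nfev=3000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("dispersion fit failed from every restart")

    pb_hat = float(best.x[0])
    kex_hat = float(np.exp(best.x[1]))
    dw_hat = float(abs(best.x[2]))
    r20_hat = {fld: float(best.x[3 + k]) for k, fld in enumerate(fields)}
    chi2_ex = float(2.0 * best.cost)

    # F-test: exchange adds 3 parameters over the flat model
    dof_ex = n - (3 + len(fields))
    detected = False
    if dof_ex > 0 and chi2_ex < chi2_flat:
        fstat = ((chi2_flat - chi2_ex) / 3.0) / max(chi2_ex / dof_ex, 1e-30)
        pval = float(f_dist.sf(fstat, 3, dof_ex))
        amp = max(
            rex_amplitude(pb_hat, kex_hat, dw_hat, fld, float(np.min(nu)))
            for fld in fields)
        detected = (pval < f_test_alpha) and (amp > min_rex)
    if not detected:
        fit = ExchangeFit(p_b=0.0, k_ex=0.0, dw_ppm=0.0, r2_0=flat_r20,
                          chi2=chi2_flat, n_points=n, exchange_detected=False,
                          single_field=len(fields) == 1)
        return fit

    sds = (float("nan"),) * 3
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_mc):
            y_mc = y + rng.normal(0.0, sd)
            def resid_mc(theta, y_mc=y_mc):
                return (model(theta) - y_mc) / sd
            try:
                s = least_squares(resid_mc, x0=best.x, bounds=(lo, hi),
                                  max_nfev=1500)
                draws.append([s.x[0], np.exp(s.x[1]), abs(s.x[2])])
            except Exception:
                continue
        if len(draws) >= max(5, n_mc // 4):
            d = np.asarray(draws)
            sds = tuple(d.std(axis=0, ddof=1))

    return ExchangeFit(p_b=pb_hat, k_ex=kex_hat, dw_ppm=dw_hat,
                       r2_0=r20_hat, chi2=chi2_ex, n_points=n,
                       exchange_detected=True,
                       single_field=len(fields) == 1,
                       p_b_sd=float(sds[0]), k_ex_sd=float(sds[1]),
                       dw_ppm_sd=float(sds[2]))


def rex_amplitude(p_b: float, k_ex: float, dw_ppm: float, field_MHz: float,
                  nu_min: float = 50.0) -> float:
    """Dispersion amplitude R2,eff(nu_min) - R2_0 (the nu -> infinity limit
    of the Carver-Richards curve is R2_0)."""
    if dw_ppm == 0.0 or p_b == 0.0 or k_ex == 0.0:
        return 0.0
    dw_rad = dw_ppm_to_rad(dw_ppm, field_MHz)
    return float(carver_richards(np.asarray([nu_min]), 0.0, p_b, k_ex,
                                 dw_rad)[0])


def rex(fit: ExchangeFit, field_MHz: float, nu_min: float = 50.0) -> float:
    """Exchange contribution for a fitted methyl at one field."""
    if not fit.exchange_detected:
        return 0.0
    return rex_amplitude(fit.p_b, fit.k_ex, fit.dw_ppm, field_MHz, nu_min)
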