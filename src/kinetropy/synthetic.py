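"""Ground-truth synthetic data for every pipeline input.

Each generator draws from the forward model the corresponding analysis stage
assumes -- population-weighted fast-exchange shifts, the TQ/SQ build-up
ratio, Carver-Richards (or Bloch-McConnell) dispersion, the Wiseman
isotherm, latent-factor-correlated order parameters, multivariate Gaussian
coordinates -- and returns the dataset together with a TruthRecord holding
the generating parameters, so recovery tests can compare fitted values
against known truth.

Noise conventions: multiplicative Gaussian on peak intensities, additive
Gaussian (microcal) on injection heats, additive (ppm) on chemical shifts.
Seeds are mandatory, explicit arguments; no generator touches global
random state.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpmg as _cpmg
from . import itc as _itc
from .data_io import (DispersionSet, IntensityDecaySet, Isotherm, MethylId,
                      StateShiftTable)
from .entropy import EntropySamples
from .errors import ValidationError
from .fast_dynamics import tq_sq_ratio

__all__ = ["TruthRecord", "gen_shift_titration", "gen_tq_sq_decays",
           "gen_dispersion", "gen_isotherm", "gen_correlated_order_params",
           "gen_coordinate_samples", "DELAY_GRID_S",
           "NU_CPMG_GRID_HZ", "REPLICATE_NUS_HZ"]

#: TQ/SQ relaxation-delay grid, s (3-35 ms)
DELAY_GRID_S = np.array([3, 6, 9, 12, 15, 20, 25, 30, 35]) * 1e-3

#: CPMG refocusing-frequency grid, Hz
NU_CPMG_GRID_HZ = np.array([50, 100, 150, 200, 250, 300, 400, 500,
                                  600, 800, 1000], dtype=float)

#: frequencies acquired in replicate
REPLICATE_NUS_HZ = (50.0, 200.0, 1000.0)

#: default 12-point titration (two-state closed-state fractions)
DEFAULT_POPULATIONS = tuple(np.round(np.linspace(0.0, 1.0, 12), 6))


@dataclass
class TruthRecord:
    """Generating parameters serialized alongside every synthetic dataset."""

    kind: str
    seed: int
    params: dict = dc_field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "seed": self.seed,
                       "params": self.params}, fh, indent=1,
                      default=_jsonify)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], seed=d["seed"], params=d["params"])


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, MethylId):
        return list(obj)
    return str(obj)


def _default_methyls(n: int, rng: np.random.Generator) -> list[MethylId]:
    types = rng.choice(["I", "L", "V"], size=n)
    labels = {"I": "d1", "L": "d1", "V": "g1"}
    return [MethylId(i + 1, str(t), labels[str(t)])
            for i, t in enumerate(types)]


# ---------------------------------------------------------------------------
# shift titrations
# ---------------------------------------------------------------------------

def gen_shift_titration(n_methyls: int = 100,
                        states: list[str] | None = None,
                        populations=DEFAULT_POPULATIONS,
                        linear_fraction: float = 0.6,
                        noise_ppm: float = 0.0,
                        seed: int = 0) -> tuple[StateShiftTable, TruthRecord]:
    """Two-state fast-exchange shift titration with linear responders and
    non-linear decoys.

    A linear methyl's shift in a state with closed-state fraction p is
    (1-p) * open + p * closed (+ noise); its endpoint separation is drawn so
    the combined perturbation lies in 0.1-0.5 ppm.  A decoy gets an
    independent isotropic perturbation in every state instead, emulating a
    methyl that senses local environment changes rather than the global
    equilibrium.  Endpoint shifts fall in realistic ILV ranges
    (dC 10-27 ppm, dH -0.5-1.5 ppm).
    """
    populations = np.asarray(populations, dtype=float)
    if np.any(populations < 0) or np.any(populations > 1):
        raise ValidationError("populations must lie in [0, 1]")
    if not 0.0 <= linear_fraction <= 1.0:
        raise ValidationError("linear_fraction must lie in [0, 1]")
    if states is None:
        states = [f"state{i:02d}" for i in range(len(populations))]
    if len(states) != len(populations):
        raise ValidationError("states and populations must have equal length")

    rng = np.random.default_rng(seed)
    methyls = _default_methyls(n_methyls, rng)
    n_linear = int(round(linear_fraction * n_methyls))
    is_linear = np.zeros(n_methyls, dtype=bool)
    is_linear[rng.permutation(n_methyls)[:n_linear]] = True

    shifts: dict[tuple[MethylId, str], tuple[float, float]] = {}
    truth_rows = []
    for i, mid in enumerate(methyls):
        dh0 = rng.uniform(-0.5, 1.5)
        dc0 = rng.uniform(10.0, 27.0)
        # endpoint separation with combined-CSP magnitude in [0.1, 0.5] ppm
        mag = rng.uniform(0.1, 0.5)
        ang = rng.uniform(0.0, 2.0 * np.pi)
        ddh = mag * np.sin(ang)
        ddc = mag * np.cos(ang) / 0.5      # CSP weights dC by sqrt(0.25)
        for st, p in zip(states, populations):
            if is_linear[i]:
                h = dh0 + p * ddh
                c = dc0 + p * ddc
            else:
                h = dh0 + rng.normal(0.0, 0.15)
                c = dc0 + rng.normal(0.0, 0.6)
            if noise_ppm > 0:
                h += rng.normal(0.0, noise_ppm)
                c += rng.normal(0.0, 2.0 * noise_ppm)
            shifts[(mid, st)] = (float(h), float(c))
        truth_rows.append({"methyl": list(mid), "linear": bool(is_linear[i]),
                           "open": [dh0, dc0], "delta": [ddh, ddc]})
    table = StateShiftTable(states=list(states), shifts=shifts)
    truth = TruthRecord(kind="shift_titration", seed=seed, params={
        "states": list(states), "populations": populations.tolist(),
        "linear_fraction": linear_fraction, "noise_ppm": noise_ppm,
        "methyls": truth_rows})
    return table, truth


def gen_response_groups(n_per_group: int = 12,
                        states: list[str] | None = None,
                        factors: np.ndarray | None = None,
                        noise_ppm: float = 0.0,
                        seed: int = 0) -> tuple[StateShiftTable, TruthRecord]:
    """Shift table with two groups of methyls responding to orthogonal
    state factors (the block-structure truth for covariance analysis).

    Every methyl in group g moves along a fixed (dH, dC) direction scaled by
    that group's factor f_g(state); the two factors are orthogonalized, so
    between-group response vectors are uncorrelated while within-group pairs
    correlate perfectly (before noise).
    """
    if states is None:
        states = [f"state{i:02d}" for i in range(6)]
    n_states = len(states)
    rng = np.random.default_rng(seed)
    if factors is None:
        f1 = rng.normal(0.0, 1.0, n_states)
        f2 = rng.normal(0.0, 1.0, n_states)
    else:
        f1, f2 = (np.asarray(f, dtype=float) for f in factors)
    f1 = f1 - f1.mean()
    f2 = f2 - f2.mean()
    f2 = f2 - (f2 @ f1) / (f1 @ f1) * f1          # orthogonalize
    f1 = f1 / np.abs(f1).max()
    f2 = f2 / np.abs(f2).max()

    n = 2 * n_per_group
    methyls = _default_methyls(n, rng)
    shifts: dict[tuple[MethylId, str], tuple[float, float]] = {}
    groups = []
    # one response direction per group: correlated residues move along a
    # common (dH, dC) direction, with per-methyl amplitude
    group_ang = rng.uniform(0.0, 2.0 * np.pi, size=2)
    for i, mid in enumerate(methyls):
        group = 0 if i < n_per_group else 1
        groups.append(group)
        f = f1 if group == 0 else f2
        dh0 = rng.uniform(-0.5, 1.5)
        dc0 = rng.uniform(10.0, 27.0)
        amp = rng.uniform(0.15, 0.4)
        ang = group_ang[group]
        ddh = amp * np.sin(ang)
        ddc = amp * np.cos(ang) / 0.5
        for st, fk in zip(states, f):
            h = dh0 + fk * ddh
            c = dc0 + fk * ddc
            if noise_ppm > 0:
                h += rng.normal(0.0, noise_ppm)
                c += rng.normal(0.0, 2.0 * noise_ppm)
            shifts[(mid, st)] = (float(h), float(c))
    table = StateShiftTable(states=list(states), shifts=shifts)
    truth = TruthRecord(kind="response_groups", seed=seed, params={
        "states": list(states), "factors": [f1.tolist(), f2.tolist()],
        "groups": groups, "methyls": [list(m) for m in methyls],
        "noise_ppm": noise_ppm})
    return table, truth


# ---------------------------------------------------------------------------
# TQ/SQ decays
# ---------------------------------------------------------------------------

def gen_tq_sq_decays(eta_delta: dict[MethylId, tuple[float, float]],
                     delays_s=DELAY_GRID_S,
                     noise_frac: float = 0.0,
                     seed: int = 0,
                     sq_rate: float = 20.0
                     ) -> tuple[IntensityDecaySet, TruthRecord]:
    """Forbidden/allowed intensity decays whose ratio follows the TQ/SQ
    build-up curve exactly before noise.

    The single-quantum channel decays monoexponentially at ``sq_rate`` (an
    arbitrary overall envelope; only the ratio is fitted downstream) and the
    triple-quantum channel is ratio * I_sq.  Multiplicative Gaussian noise is
    applied per point; the quoted per-point errors match the noise level.
    """
    delays_s = np.asarray(delays_s, dtype=float)
    if np.any(delays_s <= 0):
        raise ValidationError("delays must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for mid, (eta, delta) in eta_delta.items():
        if eta <= 0:
            raise ValidationError(f"eta must be > 0 for {mid}")
        i_sq = 1e6 * np.exp(-sq_rate * delays_s)
        i_tq = tq_sq_ratio(eta, delta, delays_s) * i_sq
        if noise_frac > 0:
            i_sq = i_sq * (1.0 + rng.normal(0.0, noise_frac, i_sq.shape))
            i_tq = i_tq * (1.0 + rng.normal(0.0, noise_frac, i_tq.shape))
        err = max(noise_frac, 1e-4)
        for t, a, b in zip(delays_s, i_tq, i_sq):
            rows.append({"residue": mid.residue_number,
                         "restype": mid.residue_type,
                         "methyl": mid.methyl_label, "delay_s": t,
                         "I_tq": a, "I_sq": b,
                         "err_tq": err * abs(a), "err_sq": err * abs(b)})
    decays = IntensityDecaySet(pd.DataFrame(rows))
    truth = TruthRecord(kind="tq_sq_decays", seed=seed, params={
        "eta_delta": {m.label: list(v) for m, v in eta_delta.items()},
        "delays_s": delays_s.tolist(), "noise_frac": noise_frac,
        "sq_rate": sq_rate})
    return decays, truth


# ---------------------------------------------------------------------------
# CPMG dispersion
# ---------------------------------------------------------------------------

def gen_dispersion(truth_params: dict[MethylId, tuple[float, float, float, float]],
                   fields_MHz=(700.0, 850.0),
                   nu_grid_hz=NU_CPMG_GRID_HZ,
                   noise_frac: float = 0.0,
                   seed: int = 0,
                   oracle: bool = False,
                   t_cp: float = 0.040,
                   replicate_nus=REPLICATE_NUS_HZ
                   ) -> tuple[DispersionSet, TruthRecord]:
    """Two-state dispersion profiles from (p_B, k_ex, dw_ppm, R2_0) truth.

    With ``oracle`` set the curves come from the numerical Bloch-McConnell
    propagator instead of the closed form.  Intensities are
    I0 * exp(-R2eff * T_cp) with multiplicative Gaussian noise; frequencies in
    ``replicate_nus`` are acquired twice (replicate_id 0 and 1).
    """
    nu_grid_hz = np.asarray(nu_grid_hz, dtype=float)
    if np.any(nu_grid_hz <= 0):
        raise ValidationError("nu_CPMG grid must be positive")
    rng = np.random.default_rng(seed)
    i0 = 1e6
    rows = []
    for mid, (pb, kex, dw_ppm, r20) in truth_params.items():
        if not 0.0 <= pb < 0.5:
            raise ValidationError(f"p_B must lie in [0, 0.5) for {mid}")
        for fld in fields_MHz:
            dw_rad = _cpmg.dw_ppm_to_rad(dw_ppm, fld)
            if oracle:
                r2 = _cpmg.bloch_mcconnell_r2eff(nu_grid_hz, r20, pb, kex,
                                                 dw_rad, t_cp)
            else:
                r2 = _cpmg.carver_richards(nu_grid_hz, r20, pb, kex, dw_rad)
            for nu, rate in zip(nu_grid_hz, r2):
                n_rep = 2 if nu in replicate_nus else 1
                for rep in range(n_rep):
                    inten = i0 * np.exp(-rate * t_cp)
                    if noise_frac > 0:
                        inten *= 1.0 + rng.normal(0.0, noise_frac)
                    rows.append({"residue": mid.residue_number,
                                 "restype": mid.residue_type,
                                 "methyl": mid.methyl_label,
                                 "field_MHz": fld, "nu_cpmg_hz": nu,
                                 "intensity": inten, "ref_intensity": i0,
                                 "replicate_id": rep})
    disp = DispersionSet(pd.DataFrame(rows), t_cp=t_cp)
    truth = TruthRecord(kind="dispersion", seed=seed, params={
        "truth": {m.label: list(v) for m, v in truth_params.items()},
        "fields_MHz": list(fields_MHz), "nu_grid_hz": nu_grid_hz.tolist(),
        "noise_frac": noise_frac, "oracle": oracle, "t_cp": t_cp})
    return disp, truth


# ---------------------------------------------------------------------------
# ITC isotherms
# ---------------------------------------------------------------------------

def gen_isotherm(kd_uM: float = 0.8, dH_kcal: float = -19.1,
                 cell_conc_M: float = 13e-6, syringe_conc_M: float = 200e-6,
                 cell_volume_mL: float = 1.4, n_injections: int = 28,
                 injection_volume_uL: float = 10.0,
                 noise_frac: float = 0.0, seed: int = 0,
                 temperature_K: float = 300.0
                 ) -> tuple[Isotherm, TruthRecord]:
    """Wiseman 1:1 isotherm.  Additive Gaussian noise (microcal) with
    standard deviation noise_frac times the mean absolute injection heat --
    the per-injection baseline-integration noise of a calorimeter is
    roughly constant across a run and is naturally quoted relative to the
    typical signal.  Warns (does not fail) when the titration never reaches
    molar ratio 1.5."""
    if min(kd_uM, cell_conc_M, syringe_conc_M, cell_volume_mL,
           injection_volume_uL) <= 0:
        raise ValidationError("concentrations, volumes and Kd must be > 0")
    vols = np.full(n_injections, injection_volume_uL)
    iso = Isotherm(heats_ucal=np.zeros(n_injections), volumes_uL=vols,
                   cell_conc_M=cell_conc_M, syringe_conc_M=syringe_conc_M,
                   cell_volume_mL=cell_volume_mL, temperature_K=temperature_K)
    heats = _itc.predict_heats(kd_uM, dH_kcal, iso)
    rm_max = (syringe_conc_M * vols.sum() * 1e-6
              / (cell_volume_mL * 1e-3)) / cell_conc_M
    if rm_max < 1.5:
        warnings.warn(f"titration reaches molar ratio {rm_max:.2f} < 1.5; "
                      "saturation incomplete", stacklevel=2)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_frac * np.mean(np.abs(heats)),
                                   heats.shape)
    iso.heats_ucal = heats
    truth = TruthRecord(kind="isotherm", seed=seed, params={
        "kd_uM": kd_uM, "dH_kcal": dH_kcal, "cell_conc_M": cell_conc_M,
        "syringe_conc_M": syringe_conc_M, "cell_volume_mL": cell_volume_mL,
        "n_injections": n_injections,
        "injection_volume_uL": injection_volume_uL,
        "noise_frac": noise_frac, "temperature_K": temperature_K})
    return iso, truth


# ---------------------------------------------------------------------------
# correlated order parameters
# ---------------------------------------------------------------------------

def gen_correlated_order_params(n_methyls: int = 40,
                                states: list[str] | None = None,
                                latent_loadings=None,
                                latent_factor=None,
                                noise_sd: float = 0.0,
                                seed: int = 0
                                ) -> tuple[dict[str, pd.DataFrame], TruthRecord]:
    """Order-parameter tables across states with a shared latent factor.

    Methyl i's O2 in each state is baseline_i + loading_i * f(state) + noise,
    clipped to [0, 1].  The default latent factor is a zero-mean state series
    of amplitude ~0.08 (a realistic binding-induced O2 modulation); default
    loadings put half the methyls on the factor (+1) and leave half unloaded.
    """
    rng = np.random.default_rng(seed)
    if states is None:
        states = ["apo", "binary", "ternary", "exit", "adp"]
    n_states = len(states)
    if latent_factor is None:
        f = rng.normal(0.0, 0.08, n_states)
        f -= f.mean()
    else:
        f = np.asarray(latent_factor, dtype=float)
        if len(f) != n_states:
            raise ValidationError("latent_factor length must match states")
    if latent_loadings is None:
        loadings = np.zeros(n_methyls)
        loadings[: n_methyls // 2] = 1.0
    else:
        loadings = np.asarray(latent_loadings, dtype=float)
        if len(loadings) != n_methyls:
            raise ValidationError("latent_loadings length must match n_methyls")

    methyls = _default_methyls(n_methyls, rng)
    baselines = rng.uniform(0.45, 0.75, n_methyls)
    tables: dict[str, pd.DataFrame] = {}
    for k, st in enumerate(states):
        o2 = baselines + loadings * f[k]
        if noise_sd > 0:
            o2 = o2 + rng.normal(0.0, noise_sd, n_methyls)
        o2 = np.clip(o2, 0.0, 1.0)
        tables[st] = pd.DataFrame({
            "residue": [m.residue_number for m in methyls],
            "restype": [m.residue_type for m in methyls],
            "methyl": [m.methyl_label for m in methyls],
            "O2": o2})
    truth = TruthRecord(kind="order_params", seed=seed, params={
        "states": list(states), "latent_factor": f.tolist(),
        "loadings": loadings.tolist(), "noise_sd": noise_sd,
        "methyls": [list(m) for m in methyls],
        "baselines": baselines.tolist()})
    return tables, truth


# ---------------------------------------------------------------------------
# coordinate samples
# ---------------------------------------------------------------------------

def gen_coordinate_samples(n_residues: int, covariance, n_frames: int,
                           seed: int = 0, roles=("CA",), axes=("x", "y")
                           ) -> tuple[EntropySamples, TruthRecord]:
    """Multivariate Gaussian positional samples with analytic entropy truth.

    ``covariance`` is a k x k matrix over each residue's degrees of freedom
    (k = len(roles) * len(axes)), shared across residues, or a list of one
    matrix per residue.  Residues are mutually independent.  The truth record
    carries each residue's differential entropy (1/2) ln((2 pi e)^k det(Sigma))
    and the pairwise Gaussian mutual informations.
    """
    k = len(roles) * len(axes)
    if isinstance(covariance, (int, float)):
        covs = [np.eye(k) * float(covariance)] * n_residues
    elif isinstance(covariance, np.ndarray) and covariance.ndim == 2:
        covs = [np.asarray(covariance, dtype=float)] * n_residues
    else:
        covs = [np.asarray(c, dtype=float) for c in covariance]
        if len(covs) != n_residues:
            raise ValidationError("need one covariance per residue")
    rng = np.random.default_rng(seed)
    data: dict[tuple[int, str, str], np.ndarray] = {}
    entropies = []
    mis = []
    dof_names = [(role, ax) for role in roles for ax in axes]
    for res in range(1, n_residues + 1):
        cov = covs[res - 1]
        if cov.shape != (k, k):
            raise ValidationError(f"covariance must be {k}x{k}")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
        if eig.min() < -1e-10 * max(eig.max(), 1.0):
            raise ValidationError("covariance must be positive semi-definite")
        x = rng.multivariate_normal(np.zeros(k), cov, size=n_frames,
                                    method="svd")
        for d, (role, ax) in enumerate(dof_names):
            data[(res, role, ax)] = x[:, d]
        sign, logdet = np.linalg.slogdet(cov)
        h = 0.5 * (k * np.log(2.0 * np.pi * np.e) + logdet) \
            if sign > 0 else float("-inf")
        entropies.append(h)
        res_mi = {}
        for a in range(k):
            for b in range(a + 1, k):
                denom = cov[a, a] * cov[b, b]
                rho2 = cov[a, b] ** 2 / denom if denom > 0 else 1.0
                res_mi[f"{a}-{b}"] = (float("inf") if rho2 >= 1.0
                                      else -0.5 * np.log(1.0 - rho2))
        mis.append(res_mi)
    samples = EntropySamples(data)
    truth = TruthRecord(kind="coordinate_samples", seed=seed, params={
        "n_residues": n_residues, "n_frames": n_frames,
        "roles": list(roles), "axes": list(axes),
        "entropy_nats": entropies, "pairwise_mi_nats": mis,
        "covariances": [c.tolist() for c in covs]})
    return samples, truth
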