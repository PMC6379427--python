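#!/usr/bin/env python
"""Generate every synthetic input the downstream stages consume.

Writes the four CSV dialects plus a truth.json sidecar per dataset under
results/data/.  Conditions mirror the study: a 1:1 substrate titration
(Kd 0.8 uM, dH -19.1 kcal/mol, triplicate), TQ/SQ decays on the 3-35 ms
delay grid, two-field (700/850 MHz) dispersion profiles on the standard
nu_CPMG grid, a 12-point two-state shift titration, latent-factor
order-parameter tables and Gaussian coordinate samples.
"""

from pathlib import Path

import numpy as np

from kinetropy import synthetic as syn
from kinetropy.data_io import (MethylId, write_decay_table,
                               write_dispersion_table, write_isotherm,
                               write_shift_table)

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    # --- ITC triplicate ---------------------------------------------------
    for rep in range(3):
        iso, truth = syn.gen_isotherm(noise_frac=0.02,
                                      seed=int(rng.integers(2 ** 31)))
        write_isotherm(iso, OUT / f"itc_rep{rep + 1}.csv")
        truth.to_json(OUT / f"itc_rep{rep + 1}.truth.json")
    print(f"wrote 3 replicate isotherms (Kd 0.8 uM, dH -19.1 kcal/mol)")

    # --- TQ/SQ decays per ligation state ----------------------------------
    methyls = [MethylId(i + 1, t, "d1" if t != "V" else "g1")
               for i, t in enumerate("ILVILVILVILV")]
    # two states sharing a rigidity pattern: binding rigidifies (O2 up)
    for state, scale, tau_c in (("binary", 1.0, 29.6), ("ternary", 0.9, 25.3)):
        eta_delta = {}
        for k, m in enumerate(methyls):
            o2 = np.clip(0.45 + 0.04 * k, 0.0, 0.95) * scale + (0.1 if scale < 1 else 0.0)
            from kinetropy.fast_dynamics import forward_eta
            eta_delta[m] = (forward_eta(o2, tau_c), 5.0)
        dec, truth = syn.gen_tq_sq_decays(eta_delta, noise_frac=0.01,
                                          seed=int(rng.integers(2 ** 31)))
        write_decay_table(dec, OUT / f"decays_{state}.csv")
        truth.to_json(OUT / f"decays_{state}.truth.json")
    print("wrote TQ/SQ decays for 2 states x 12 methyls (1% noise)")

    # --- order-parameter tables across the 5-state cycle -------------------
    tables, truth = syn.gen_correlated_order_params(
        n_methyls=30, noise_sd=0.01, seed=int(rng.integers(2 ** 31)))
    import pandas as pd
    for st, tab in tables.items():
        tab.to_csv(OUT / f"o2_{st}.csv", index=False)
    truth.to_json(OUT / "o2_states.truth.json")
    print("wrote order-parameter tables for 5 ligation states")

    # --- CPMG dispersion: two synchrony clusters ---------------------------
    truth_params = {}
    for i in range(5):  # cluster 1: fast, synchronized
        truth_params[MethylId(100 + i, "I", "d1")] = (
            0.05 * (1 + 0.01 * rng.normal()),
            1200.0 * (1 + 0.01 * rng.normal()), 2.0, 10.0)
    for i in range(5):  # cluster 2: slower exchange elsewhere
        truth_params[MethylId(200 + i, "L", "d1")] = (
            0.25 * (1 + 0.01 * rng.normal()),
            250.0 * (1 + 0.01 * rng.normal()), 1.5, 12.0)
    disp, truth = syn.gen_dispersion(truth_params, noise_frac=0.02,
                                     seed=int(rng.integers(2 ** 31)))
    write_dispersion_table(disp, OUT / "dispersion.csv")
    truth.to_json(OUT / "dispersion.truth.json")
    print("wrote two-field dispersion profiles for 10 methyls (2% noise)")

    # --- shift titration ----------------------------------------------------
    table, truth = syn.gen_shift_titration(n_methyls=80, linear_fraction=0.7,
                                           noise_ppm=0.002,
                                           seed=int(rng.integers(2 ** 31)))
    write_shift_table(table, OUT / "shifts_titration.csv")
    truth.to_json(OUT / "shifts_titration.truth.json")
    table2, truth2 = syn.gen_response_groups(n_per_group=15, noise_ppm=0.002,
                                             seed=int(rng.integers(2 ** 31)))
    write_shift_table(table2, OUT / "shifts_groups.csv")
    truth2.to_json(OUT / "shifts_groups.truth.json")
    print("wrote shift titration (80 methyls, 12 states) and response groups")

    # --- coordinate samples -------------------------------------------------
    cov = np.array([[1.0, 0.6], [0.6, 1.0]])
    samples, truth = syn.gen_coordinate_samples(4, cov, 50_000,
                                                seed=int(rng.integers(2 ** 31)))
    samples.to_frame().to_csv(OUT / "coords.csv", index=False)
    truth.to_json(OUT / "coords.truth.json")
    print("wrote Gaussian coordinate samples (4 residues, 50k frames)")


if __name__ == "__main__":
    main()
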