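#!/usr/bin/env python
"""Histogram-based configurational entropy with mutual-information
correction on the Gaussian coordinate samples.

Reads the stage-01 long-format coordinate table, estimates per-residue
entropies (first-order minus pairwise MI) and compares them with the
analytic Gaussian values carried by the truth record.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kinetropy import entropy as ent
from kinetropy.data_io import write_report
from kinetropy.synthetic import TruthRecord

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = pd.read_csv(DATA / "coords.csv")
    samples = ent.EntropySamples.from_frame(df)
    truth = TruthRecord.from_json(DATA / "coords.truth.json")
    est = ent.entropy_expansion(samples, n_bins=24, n_null=10, seed=5)

    true_h = truth.params["entropy_nats"]
    tab = est.per_residue.copy()
    tab["S_true_nats"] = true_h
    tab["rel_err"] = (tab["S_nats"] - tab["S_true_nats"]) / tab["S_true_nats"]
    print(tab[["residue", "S1_nats", "MI_nats", "S_nats", "S_true_nats"]]
          .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"total: {est.total_nats:.3f} nats "
          f"({est.total_cal_mol_K:.2f} cal/mol/K); "
          f"analytic {sum(true_h):.3f} nats; "
          f"max relative error {np.abs(tab['rel_err']).max() * 100:.1f}%")
    write_report(tab, OUT / "entropy.csv",
                 metadata={"n_bins": est.n_bins, "n_frames": est.n_frames})


if __name__ == "__main__":
    main()
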