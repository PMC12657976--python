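#!/usr/bin/env python
"""Noiseless parameter recovery with the true habitat map.

For each patient of the recovery cohort, fits the habitat-parameterized
model (one proliferation rate per true region plus one global drug efficacy)
to the V1 -> V2 cellularity maps with Levenberg-Marquardt, then compares the
fitted values against the generator's.  On noiseless data the inverse
problem is exactly self-consistent, so the errors measure optimizer quality
alone.

Writes results/recovery.csv.
"""

import sys
from pathlib import Path

import numpy as np

from tumorhab import pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed=7):
    OUT.mkdir(exist_ok=True)
    cfg = pipeline.recovery_study_config(seed=seed)
    table = pipeline.run_recovery_experiment(cfg)
    table.to_csv(OUT / "recovery.csv", index=False)
    k_errs = 100 * np.concatenate([table[f"k{j}_rel_err"] for j in (1, 2, 3)])
    print(f"cohort: {len(table)} patients, habitat scheme with true region "
          "map, noiseless data")
    print(f"median |k_h error|: {np.median(k_errs):.2e} %  "
          f"(max {k_errs.max():.2e} %)")
    print(f"median |alpha error|: "
          f"{100 * table.alpha_rel_err.median():.2e} %")
    print(f"wrote {OUT / 'recovery.csv'}")


if __name__ == "__main__":
    main(*map(int, sys.argv[1:]))
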