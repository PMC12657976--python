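#!/usr/bin/env python
"""Habitat-count selection, scheme tests, response ROC, and the summary.

Re-runs the comparison study (served from the cache written by script 04),
selects the optimal habitat count by the Kolmogorov-Smirnov procedure,
tests all scheme pairs on each error metric, and evaluates how well the
predicted V3 tumor burden classifies treatment response, with DeLong
comparisons between predictors.

Writes the full report bundle (scheme_tests.csv, roc.csv, delong.csv,
optimal_h.json, summary.md) under results/.
"""

import importlib.util
import sys
from pathlib import Path

from tumorhab import pipeline

HERE = Path(__file__).resolve().parent
OUT = HERE.parent / "results"

spec = importlib.util.spec_from_file_location(
    "scheme_comparison", HERE / "04_scheme_comparison.py")
scheme_comparison = importlib.util.module_from_spec(spec)
spec.loader.exec_module(scheme_comparison)


def main(seed=7):
    OUT.mkdir(exist_ok=True)
    report = pipeline.run_study(scheme_comparison.study_config(seed))
    pipeline.write_report(report, OUT)

    h = report.optimal_h["msi"]
    print(f"optimal habitat count (ADC+MSI): {h.H}"
          f"{'' if h.qualified else ' (no H qualified)'}")
    sig = report.scheme_tests[report.scheme_tests.p < 0.05]
    print(f"significant scheme differences (KS, 5%): {len(sig)} of "
          f"{len(report.scheme_tests)} comparisons")
    if len(report.roc):
        print("\nROC for predicting response from V3 tumor burden:")
        print(report.roc.round(3).to_string(index=False))
    print(f"\nwrote report bundle under {OUT}/")


if __name__ == "__main__":
    main(*map(int, sys.argv[1:]))
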