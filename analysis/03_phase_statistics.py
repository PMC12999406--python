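#!/usr/bin/env python
"""Phase-level statistics: descriptives, normality routing, test battery.

Aggregates the signal summaries into the cohort table, computes the
study-table-shaped descriptives (t-based mean CIs, bootstrap median CIs) and
runs the Friedman / mixed-ANOVA battery with paired post hoc comparisons.
"""

import shutil
from pathlib import Path

import pandas as pd

from cprstress import RunConfig
from cprstress.pipeline import analyze_stage

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "study_run"
RESULTS = ROOT / "results"


def main() -> None:
    if not (RUN_DIR / "summaries").exists():
        raise SystemExit("run analysis/02_process_signals.py first")
    out = analyze_stage(RunConfig(seed=42), RUN_DIR)
    RESULTS.mkdir(exist_ok=True)
    for name in ("descriptives.csv", "tests.csv", "correlations.csv"):
        shutil.copy(out / name, RESULTS / name)

    desc = pd.read_csv(out / "descriptives.csv")
    show = desc[desc.metric.isin(["hr", "rmssd", "tonic_eda"])]
    print("descriptives (mean [95% CI] / median [bootstrap 95% CI]):")
    for _, r in show.iterrows():
        print(f"  {r.metric:>9} {r.phase:<4} mean {r['mean']:8.3f} "
              f"[{r.ci95_mean_lo:7.3f}, {r.ci95_mean_hi:7.3f}]  "
              f"median {r['median']:7.3f} "
              f"[{r.ci95_median_lo:6.3f}, {r.ci95_median_hi:6.3f}]")

    tests = pd.read_csv(out / "tests.csv")
    omni = tests[tests.test.isin(["friedman"]) |
                 tests.test.str.startswith("mixed-anova phase")]
    print("\nomnibus phase effects:")
    for _, r in omni.iterrows():
        sel = " (selected route)" if r.selected else ""
        print(f"  {r.metric:>9} {r.test:<18} stat {r.statistic:7.3f} "
              f"p {r.pvalue:.4g}{sel}")
    print(f"\nfull tables copied to {RESULTS}")


if __name__ == "__main__":
    main()
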