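#!/usr/bin/env python
"""Performance models on the dyad feature table.

Linear baseline, concave quadratic in dyad-mean SD1 (with the optimal-SD1
vertex), and the binomial logistic model of high performance (> 7.5) on
the sympathetic predictors.
"""

import shutil
from pathlib import Path

from cprstress import RunConfig
from cprstress.pipeline import make_report, model_stage

ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = ROOT / "scratch" / "study_run"
RESULTS = ROOT / "results"


def main() -> None:
    if not (RUN_DIR / "analysis" / "cohort_table.csv").exists():
        raise SystemExit("run analysis/03_phase_statistics.py first")
    out = model_stage(RunConfig(seed=42), RUN_DIR)
    make_report(RUN_DIR)
    RESULTS.mkdir(exist_ok=True)
    for name in ("quadratic_fit.json", "logistic_fit.json", "model_report.md"):
        shutil.copy(out / name, RESULTS / name)
    print((out / "model_report.md").read_text())
    import json

    qf = json.loads((out / "quadratic_fit.json").read_text())
    if qf.get("vertex_x") is None and "a" in qf:
        print(
            "note: the calibrated cohort sits almost entirely on the falling\n"
            "limb of the performance parabola (scenario-phase SD1 ~0.04 s vs\n"
            "the 0.0201 s optimum), so at 15 dyads the curvature is not\n"
            "identified and the fitted trend is effectively linear; the vertex\n"
            "worked example and the parameter-recovery tests cover the\n"
            "concave regime."
        )
    print(f"model artifacts copied to {RESULTS}; full run report at "
          f"{RUN_DIR / 'report.md'}")


if __name__ == "__main__":
    main()
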