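"""End-to-end orchestration: simulate -> process -> analyze -> model -> report.

Each stage reads and writes plain CSV/JSON under a run directory:

```
run/
  raw/                 wristband-dialect cohort (or user-supplied recordings)
  summaries/           eda_summary.csv, scr_events.csv, hrv_summary.csv
  analysis/            cohort_table.csv, descriptives.csv, tests.csv,
                       correlations.csv, routing.json
  models/              logistic_fit.json, quadratic_fit.json, model_report.md
  report.md
  run_manifest.json    config hash, seed, stage inventory
```

Every stochastic stage draws from the run seed; rerunning with an identical
configuration reproduces every file byte for byte.  The manifest carries
the configuration hash and seed for all outputs (CSV files stay strictly
RFC-4180, so stamping lives in the manifest rather than in comment lines).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import design, inference, models
from .eda import DetectorParams, classify_arousal, clean_eda, detect_scr, scr_per_minute, tonic_summary
from .errors import PipelineError, ValidationError
from .hrv import summarize_hrv
from .io import read_eda_csv, read_ibi_csv, read_table, session_dirs
from .synth import PHASES, GeneratorConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "simulate_stage", "process_stage",
           "analyze_stage", "model_stage", "make_report"]

_METRICS = ["hr", "rmssd", "sd1", "tonic_eda", "scr_rate"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    generator: Optional[GeneratorConfig] = None   # None => recorded-data mode
    detector: DetectorParams = field(default_factory=DetectorParams)
    alpha: float = 0.05
    bootstrap_reps: int = 10_000
    posthoc: str = "durbin-conover"
    sides: str = "two"
    sd1_window: float = 10.0
    sd1_span: float = 90.0

    def __post_init__(self):
        if not 0 < self.alpha < 0.5:
            raise ValidationError("alpha must lie in (0, 0.5)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        det = raw.pop("detector", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig.from_dict(gen)
        if det is not None:
            cfg.detector = DetectorParams(**det)
        return cfg

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in dataclasses.asdict(self).items()
            if k not in ("generator", "detector")
        }
        d["generator"] = self.generator.to_dict() if self.generator else None
        d["detector"] = dataclasses.asdict(self.detector)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\r\n", float_format="%.10g")


def simulate_stage(config: RunConfig, run_dir: Path) -> Path:
    if config.generator is None:
        raise PipelineError("simulate", "no generator configuration supplied")
    gen = dataclasses.replace(config.generator, seed=config.seed)
    data = generate_cohort(gen)
    raw = run_dir / "raw"
    write_cohort(data, raw)
    return raw


def process_stage(config: RunConfig, raw_dir: Path, run_dir: Path) -> Path:
    """Per-session signal processing: EDA cleaning/detection and HRV metrics."""
    out = run_dir / "summaries"
    sessions = session_dirs(raw_dir)
    if not sessions:
        raise PipelineError("process", f"no participant sessions under {raw_dir}",
                            offending=str(raw_dir))
    eda_rows, ev_rows, hrv_rows = [], [], []
    for pid, phase, d in sessions:
        eda_path, ibi_path = d / "EDA.csv", d / "IBI.csv"
        trace = clean_eda(read_eda_csv(eda_path))
        events = detect_scr(trace, config.detector)
        rate, windowed = scr_per_minute(
            events, trace.duration, window=config.detector.window
        )
        t_mean, t_median = tonic_summary(trace, events)
        eda_rows.append({
            "participant_id": pid, "phase": phase,
            "tonic_mean": t_mean, "tonic_median": t_median,
            "scr_per_min": rate,
            "scr_per_min_windowed_mean": float(np.mean(windowed)),
            "band": classify_arousal(rate),
        })
        for e in events:
            ev_rows.append({
                "participant_id": pid, "phase": phase,
                "onset_s": e.onset_time, "peak_s": e.peak_time,
                "recovery_s": e.recovery_time, "amplitude_us": e.amplitude,
                "base_level_us": e.base_level,
            })
        s = summarize_hrv(read_ibi_csv(ibi_path),
                          window=config.sd1_window, span=config.sd1_span)
        hrv_rows.append({
            "participant_id": pid, "phase": phase,
            "hr_bpm": s.hr, "rmssd_ms": s.rmssd,
            "sd1_mean_s": s.sd1_mean, "n_windows": len(s.sd1_windows),
            "n_beats": s.n_beats,
        })
    _write_csv(pd.DataFrame(eda_rows), out / "eda_summary.csv")
    _write_csv(pd.DataFrame(ev_rows), out / "scr_events.csv")
    _write_csv(pd.DataFrame(hrv_rows), out / "hrv_summary.csv")
    return out


def _cohort_table(run_dir: Path) -> pd.DataFrame:
    eda = read_table(run_dir / "summaries" / "eda_summary.csv")
    hrv = read_table(run_dir / "summaries" / "hrv_summary.csv")
    participants = read_table(run_dir / "raw" / "participants.csv")
    eda_long = eda.rename(
        columns={"tonic_mean": "tonic_eda", "scr_per_min": "scr_rate"}
    ).melt(
        id_vars=["participant_id", "phase"],
        value_vars=["tonic_eda", "scr_rate"],
        var_name="metric", value_name="value",
    )
    hrv_long = hrv.rename(
        columns={"hr_bpm": "hr", "rmssd_ms": "rmssd", "sd1_mean_s": "sd1"}
    ).melt(
        id_vars=["participant_id", "phase"],
        value_vars=["hr", "rmssd", "sd1"],
        var_name="metric", value_name="value",
    )
    table, flagged = inference.aggregate_by_phase(
        [eda_long, hrv_long], participants=participants
    )
    if flagged:
        (run_dir / "analysis").mkdir(parents=True, exist_ok=True)
        (run_dir / "analysis" / "missing_cells.json").write_text(
            json.dumps([list(f) for f in flagged], indent=1)
        )
    return table.dropna(subset=["value"]).reset_index(drop=True)


def analyze_stage(config: RunConfig, run_dir: Path) -> Path:
    out = run_dir / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    table = _cohort_table(run_dir)
    _write_csv(table, out / "cohort_table.csv")
    desc = inference.descriptives(
        table, bootstrap_reps=config.bootstrap_reps, seed=config.seed
    )
    _write_csv(desc, out / "descriptives.csv")

    routing: dict = {}
    test_rows = []
    for metric in sorted(table.metric.unique()):
        sub = table[table.metric == metric]
        pre = sub[sub.phase == "pre"].value
        try:
            nd = inference.normality_screen(pre, alpha=config.alpha)
        except ValidationError:
            # tiny pilot cohorts: default to the distribution-free route
            nd = inference.NormalityDecision(
                np.nan, np.nan, "nonparametric",
                warning="too few observations for the normality screen",
            )
        routing[metric] = {
            "ks_stat": None if np.isnan(nd.statistic) else nd.statistic,
            "ks_p": None if np.isnan(nd.pvalue) else nd.pvalue,
            "route": nd.route, "warning": nd.warning,
        }
        try:
            fr = inference.friedman_test(table, metric, posthoc=config.posthoc)
            test_rows.append({
                "metric": metric, "test": "friedman", "statistic": fr.chi2,
                "df": fr.df, "pvalue": fr.pvalue,
                "selected": nd.route == "nonparametric",
                "flag": "degenerate" if fr.degenerate else "",
            })
            for _, r in fr.posthoc.iterrows():
                test_rows.append({
                    "metric": metric, "test": f"posthoc {r.a} vs {r.b}",
                    "statistic": r.statistic, "df": fr.n - 1,
                    "pvalue": r.pvalue,
                    "selected": nd.route == "nonparametric", "flag": "",
                })
        except ValidationError as exc:
            test_rows.append({"metric": metric, "test": "friedman",
                              "statistic": np.nan, "df": np.nan,
                              "pvalue": np.nan, "selected": False,
                              "flag": str(exc)})
        try:
            ma = inference.mixed_anova(table, metric)
            if ma.degenerate:
                test_rows.append({"metric": metric, "test": "mixed-anova",
                                  "statistic": np.nan, "df": np.nan,
                                  "pvalue": np.nan,
                                  "selected": nd.route == "parametric",
                                  "flag": ma.warning or "degenerate"})
            else:
                for _, r in ma.effects.iterrows():
                    test_rows.append({
                        "metric": metric, "test": f"mixed-anova {r.source}",
                        "statistic": r.F, "df": r.df1, "pvalue": r.pvalue,
                        "selected": nd.route == "parametric",
                        "flag": ma.warning,
                    })
                test_rows.append({
                    "metric": metric, "test": "bartlett",
                    "statistic": ma.bartlett_stat, "df": len(PHASES) - 1,
                    "pvalue": ma.bartlett_p, "selected": False, "flag": "",
                })
        except ValidationError as exc:
            test_rows.append({"metric": metric, "test": "mixed-anova",
                              "statistic": np.nan, "df": np.nan,
                              "pvalue": np.nan, "selected": False,
                              "flag": str(exc)})
        wide = sub.pivot(index="participant_id", columns="phase", values="value")
        for a, b in (("pre", "Sim"), ("Sim", "post"), ("pre", "post")):
            if a in wide.columns and b in wide.columns:
                pair = wide[[a, b]].dropna()
                if len(pair) >= 5:
                    pr = inference.paired_tests(
                        pair[a], pair[b], route=nd.route, sides=config.sides
                    )
                    test_rows.append({
                        "metric": metric, "test": f"{pr.test} {a} vs {b}",
                        "statistic": pr.statistic, "df": pr.n - 1,
                        "pvalue": pr.pvalue, "selected": True,
                        "flag": "degenerate" if pr.degenerate else "",
                    })
    _write_csv(pd.DataFrame(test_rows), out / "tests.csv")

    corr_rows = []
    try:
        dc = inference.dyadic_correlation(
            table, ("TL", "pre", "tonic_eda"), ("TM", "post", "scr_rate")
        )
        corr_rows.append({
            "x": "TL pre tonic_eda", "y": "TM post scr_rate",
            "r": dc.r, "n": dc.n, "pvalue": dc.pvalue, "flag": dc.flag,
        })
    except ValidationError as exc:
        corr_rows.append({"x": "TL pre tonic_eda", "y": "TM post scr_rate",
                          "r": np.nan, "n": 0, "pvalue": np.nan, "flag": str(exc)})
    _write_csv(pd.DataFrame(corr_rows), out / "correlations.csv")
    (out / "routing.json").write_text(json.dumps(routing, indent=1))
    return out


def model_stage(config: RunConfig, run_dir: Path) -> Path:
    out = run_dir / "models"
    out.mkdir(parents=True, exist_ok=True)
    table = read_table(run_dir / "analysis" / "cohort_table.csv")
    dyads = read_table(run_dir / "raw" / "dyads.csv")
    feats = models.build_dyad_features(table, dyads)
    _write_csv(feats, out / "dyad_features.csv")

    try:
        lf = models.fit_logistic(
            feats, ["tm_eda_pre", "tl_eda_pre", "tl_scr_pre"]
        )
        logistic = lf.to_dict()
    except ValidationError as exc:
        lf, logistic = None, {"error": str(exc)}
    (out / "logistic_fit.json").write_text(json.dumps(logistic, indent=1))

    try:
        qf = models.fit_quadratic(feats.dyad_sd1, feats.cpt_score)
        lin = models.fit_linear(feats.dyad_sd1, feats.cpt_score)
    except ValidationError as exc:
        (out / "quadratic_fit.json").write_text(json.dumps({"error": str(exc)}, indent=1))
        (out / "model_report.md").write_text(
            f"# Performance models\n\nNot fitted: {exc}\n"
        )
        return out
    (out / "quadratic_fit.json").write_text(json.dumps(qf.to_dict(), indent=1))

    lines = ["# Performance models", ""]
    lines.append(f"Dyads: {len(feats)}")
    lines.append("")
    lines.append("## Linear baseline (dyad SD1 -> CPT)")
    lines.append(
        f"slope = {lin.slope:.4g} (p = {lin.slope_pvalue:.3g}), "
        f"intercept = {lin.intercept:.4g}, R^2 = {lin.r2:.3f}"
    )
    lines.append("")
    lines.append("## Quadratic (inverted-U) model")
    lines.append(
        f"a = {qf.a:.6g} (p = {qf.pvalues.get('a', float('nan')):.3g}), "
        f"b = {qf.b:.6g} (p = {qf.pvalues.get('b', float('nan')):.3g}), "
        f"intercept = {qf.intercept:.4g}, R^2 = {qf.r2:.3f}"
    )
    if qf.vertex_x is not None:
        lines.append(
            f"Vertex: optimal SD1 = {qf.vertex_x:.4f} s, "
            f"peak predicted performance = {qf.vertex_y:.2f}"
        )
    else:
        lines.append("Parabola is not concave; no interior optimum.")
    lines.append("")
    lines.append("## Binomial logistic (high performance > 7.5)")
    if lf is None:
        lines.append(f"Not fitted: {logistic['error']}")
    else:
        lines.append(
            f"McFadden R^2 = {lf.mcfadden_r2:.3f}, AIC = {lf.aic:.2f}, "
            f"accuracy = {lf.accuracy:.1%}"
            + (" [separation flagged]" if lf.separation else "")
        )
        beta = np.array([lf.coefficients["intercept"]]
                        + [lf.coefficients[p] for p in lf.predictors])
        design_mat = models.sm.add_constant(
            feats[lf.predictors].astype(float), has_constant="add"
        ).to_numpy()
        predicted = 1.0 / (1.0 + np.exp(-design_mat @ beta)) > 0.5
        ct = pd.crosstab(
            feats.high_performance, pd.Series(predicted, name="predicted")
        )
        lines.append("")
        lines.append("Classification table (rows observed, columns predicted):")
        lines.append("```")
        lines.append(ct.to_string())
        lines.append("```")
    (out / "model_report.md").write_text("\n".join(lines) + "\n")
    return out


def _band_counts(run_dir: Path) -> dict:
    participants = read_table(run_dir / "raw" / "participants.csv")
    eda = read_table(run_dir / "summaries" / "eda_summary.csv")
    counts = {
        "pss10": participants.pss10.map(design.classify_pss10)
        .value_counts().to_dict(),
        "vas_stress": participants.vas_stress
        .map(lambda v: design.classify_vas(v, "stress")).value_counts().to_dict(),
        "vas_anxiety": participants.vas_anxiety
        .map(lambda v: design.classify_vas(v, "anxiety")).value_counts().to_dict(),
    }
    counts["arousal"] = {
        ph: grp.band.value_counts().to_dict()
        for ph, grp in eda.groupby("phase")
    }
    return counts


def make_report(run_dir: str | Path) -> Path:
    """Assemble the human-readable run report (descriptives, tests, models)."""
    run_dir = Path(run_dir)
    lines = ["# Pipeline report", ""]
    gaps = []

    def section(title, path, formatter):
        lines.append(f"## {title}")
        if path.exists():
            formatter(path)
        else:
            gaps.append(str(path.name))
            lines.append(f"*missing: {path.name}*")
        lines.append("")

    def table_fmt(path):
        df = pd.read_csv(path)
        lines.append("```")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("```")

    section("Descriptives by metric and phase",
            run_dir / "analysis" / "descriptives.csv", table_fmt)
    section("Statistical tests", run_dir / "analysis" / "tests.csv", table_fmt)
    section("Dyadic correlations", run_dir / "analysis" / "correlations.csv",
            table_fmt)

    lines.append("## Psychometric and arousal bands")
    try:
        lines.append("```")
        lines.append(json.dumps(_band_counts(run_dir), indent=1, default=int))
        lines.append("```")
    except PipelineError as exc:
        gaps.append("band counts")
        lines.append(f"*unavailable: {exc}*")
    lines.append("")

    model_md = run_dir / "models" / "model_report.md"
    if model_md.exists():
        lines.append(model_md.read_text())
    else:
        gaps.append("model_report.md")
        lines.append("## Performance models\n*missing*")
    tests_csv = run_dir / "analysis" / "tests.csv"
    if tests_csv.exists():
        t = pd.read_csv(tests_csv)
        deg = t[t.flag.fillna("").str.contains("degenerate")]
        if len(deg):
            lines.append("## Flags")
            for _, r in deg.iterrows():
                lines.append(f"- degenerate result: {r.metric} / {r.test}")
    if gaps:
        lines.append("")
        lines.append("## Gaps")
        lines.extend(f"- missing artifact: {g}" for g in gaps)
    out = run_dir / "report.md"
    out.write_text("\n".join(lines) + "\n")
    return out


def run_pipeline(config: RunConfig, run_dir: str | Path,
                 raw_dir: Optional[str | Path] = None) -> Path:
    """Execute all stages in order under ``run_dir``.

    With a generator configuration the cohort is simulated first; otherwise
    ``raw_dir`` must point at recorded sessions (participants.csv and
    dyads.csv alongside per-participant phase directories).  A stage
    failure halts the run with a structured error naming the stage.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = []
    try:
        if config.generator is not None:
            raw = simulate_stage(config, run_dir)
            stages.append("simulate")
        else:
            if raw_dir is None:
                raise PipelineError("simulate", "neither generator config nor raw_dir given")
            raw = Path(raw_dir)
        process_stage(config, raw, run_dir)
        stages.append("process")
        analyze_stage(config, run_dir)
        stages.append("analyze")
        model_stage(config, run_dir)
        stages.append("model")
        make_report(run_dir)
        stages.append("report")
    except PipelineError:
        raise
    except (ValidationError, OSError) as exc:
        failed = {"simulate": "simulate", "process": "process",
                  "analyze": "analyze", "model": "model"}
        nxt = ["simulate", "process", "analyze", "model", "report"]
        stage = nxt[len(stages)] if len(stages) < len(nxt) else "report"
        raise PipelineError(stage, str(exc)) from exc
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
        "config": config.to_dict(),
    }
    (run_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return run_dir
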