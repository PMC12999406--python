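"""Phase-level aggregation and the study's statistical battery.

Works on a tidy *cohort table*: one row per participant x phase x metric
with columns ``participant_id, role, dyad_id, phase, metric, value`` and
phases limited to ``pre`` / ``Sim`` / ``post``.  Provides descriptives with
t-based mean CIs and percentile-bootstrap median CIs, Kolmogorov-Smirnov
normality screening with estimated parameters (Lilliefors correction),
paired tests routed parametric/non-parametric, Friedman's rank ANOVA with
Durbin-Conover post hoc, a mixed repeated-measures ANOVA (role between,
phase within) with a Bartlett homogeneity check, and the dyadic
cross-member correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .synth import PHASES

__all__ = [
    "validate_cohort_table",
    "aggregate_by_phase",
    "descriptives",
    "normality_screen",
    "NormalityDecision",
    "paired_tests",
    "PairedTestResult",
    "friedman_test",
    "FriedmanResult",
    "mixed_anova",
    "MixedAnovaResult",
    "dyadic_correlation",
    "DyadicCorrelation",
]

_KEY = ["participant_id", "phase", "metric"]


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "role", "dyad_id", "phase", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table lacks columns: {sorted(missing)}")
    bad = set(table.phase.unique()) - set(PHASES)
    if bad:
        raise ValidationError(f"unknown phase labels: {sorted(bad)}")
    dup = table.duplicated(subset=_KEY)
    if dup.any():
        raise ValidationError(
            f"duplicate participant x phase x metric rows: "
            f"{table.loc[dup, _KEY].to_dict(orient='records')[:5]}"
        )
    return table


def aggregate_by_phase(
    summaries: Sequence[pd.DataFrame] | pd.DataFrame,
    participants: Optional[pd.DataFrame] = None,
    expected_phases: Sequence[str] = PHASES,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Collapse raw per-phase summaries to one value per subject-phase-metric.

    Each input frame is long (``participant_id, phase, metric, value``);
    repeated measurements of a key within one frame (e.g. several windows)
    are averaged.  The same key arriving from two different frames is a
    duplicate-key error.  Missing participant-phase-metric combinations are
    flagged in the returned list, never imputed.  Role and dyad membership
    are joined from ``participants`` when given.
    """
    frames = [summaries] if isinstance(summaries, pd.DataFrame) else list(summaries)
    parts = []
    for f in frames:
        need = {"participant_id", "phase", "metric", "value"}
        if not need <= set(f.columns):
            raise ValidationError(f"summary frame lacks columns {sorted(need - set(f.columns))}")
        parts.append(f.groupby(_KEY, as_index=False)["value"].mean())
    merged = pd.concat(parts, ignore_index=True)
    dup = merged.duplicated(subset=_KEY)
    if dup.any():
        raise ValidationError(
            f"metric supplied by more than one source: "
            f"{merged.loc[dup, _KEY].drop_duplicates().to_dict(orient='records')[:5]}"
        )
    if participants is not None:
        cols = ["participant_id", "role", "dyad_id"]
        merged = merged.merge(participants[cols], on="participant_id", how="left")
    else:
        merged["role"] = pd.NA
        merged["dyad_id"] = pd.NA

    flagged = []
    for metric, grp in merged.groupby("metric"):
        for pid in grp.participant_id.unique():
            have = set(grp.loc[grp.participant_id == pid, "phase"])
            for ph in expected_phases:
                if ph not in have:
                    flagged.append((pid, ph, metric))
    out = merged[["participant_id", "role", "dyad_id", "phase", "metric", "value"]]
    return validate_cohort_table(out.reset_index(drop=True)), flagged


def descriptives(
    table: pd.DataFrame, bootstrap_reps: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Per metric x phase: mean with t CI, SD, median with bootstrap CI.

    The mean interval is the classical t interval; the median interval is a
    seeded percentile bootstrap (2.5/97.5 percentiles of ``bootstrap_reps``
    resample medians).  Cells with fewer than two observations are emitted
    with a ``flag`` instead of intervals.
    """
    validate_cohort_table(table)
    rng = np.random.default_rng(seed)
    rows = []
    for (metric, phase), grp in table.groupby(["metric", "phase"], sort=True):
        v = grp.value.to_numpy(dtype=float)
        n = len(v)
        row = {"metric": metric, "phase": phase, "n": n}
        if n < 2:
            row.update(
                mean=float(v.mean()) if n else np.nan, sd=np.nan, median=np.nan,
                ci95_mean_lo=np.nan, ci95_mean_hi=np.nan,
                ci95_median_lo=np.nan, ci95_median_hi=np.nan,
                flag="insufficient-data",
            )
            rows.append(row)
            continue
        m, sd = float(np.mean(v)), float(np.std(v, ddof=1))
        sem = sd / np.sqrt(n)
        lo, hi = stats.t.interval(0.95, n - 1, loc=m, scale=sem) if sem > 0 else (m, m)
        boots = np.median(
            v[rng.integers(0, n, size=(bootstrap_reps, n))], axis=1
        )
        blo, bhi = np.percentile(boots, [2.5, 97.5])
        row.update(
            mean=m, sd=sd, median=float(np.median(v)),
            ci95_mean_lo=float(lo), ci95_mean_hi=float(hi),
            ci95_median_lo=float(blo), ci95_median_hi=float(bhi),
            flag="",
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class NormalityDecision:
    statistic: float
    pvalue: float
    route: Literal["parametric", "nonparametric"]
    warning: str = ""


def normality_screen(values, alpha: float = 0.05) -> NormalityDecision:
    """Kolmogorov-Smirnov normality screen with estimated mean/SD.

    Because mean and SD are estimated from the data, the plain KS reference
    distribution is invalid; the Lilliefors-corrected p-value (statsmodels,
    table/simulation based) is used.  Variables that are not rejected at
    ``alpha`` are routed to parametric tests, all others (including
    degenerate constant input) to non-parametric tests.
    """
    from statsmodels.stats.diagnostic import lilliefors

    v = np.asarray(values, dtype=float)
    if len(v) < 5:
        raise ValidationError("normality screen needs n >= 5")
    if np.std(v) == 0:
        return NormalityDecision(
            np.nan, np.nan, "nonparametric", warning="constant input; screen degenerate"
        )
    stat, p = lilliefors(v, dist="norm")
    route = "parametric" if p > alpha else "nonparametric"
    return NormalityDecision(float(stat), float(p), route)


@dataclass
class PairedTestResult:
    test: str
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def paired_tests(
    values_a,
    values_b,
    route: Literal["auto", "parametric", "nonparametric"] = "auto",
    sides: Literal["one", "two"] = "two",
    alpha: float = 0.05,
) -> PairedTestResult:
    """Paired comparison: Student t or Wilcoxon signed-rank, per routing.

    ``route="auto"`` screens the paired differences for normality.  The
    one-sided alternative is "a > b".  All-zero differences make the
    Wilcoxon statistic undefined; the result is then flagged degenerate
    with p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    if len(a) < 5:
        raise ValidationError("paired tests need n >= 5")
    d = a - b
    if route == "auto":
        route = normality_screen(d, alpha=alpha).route
    alt = "greater" if sides == "one" else "two-sided"
    if np.all(d == 0):
        return PairedTestResult("degenerate", 0.0, 1.0, len(a), degenerate=True)
    if route == "parametric":
        res = stats.ttest_rel(a, b, alternative=alt)
        return PairedTestResult("t-paired", float(res.statistic), float(res.pvalue), len(a))
    res = stats.wilcoxon(d, alternative=alt)
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), len(a))


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    pvalue: float
    n: int
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False


def _pivot_complete(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = table[table.metric == metric]
    wide = sub.pivot(index="participant_id", columns="phase", values="value")
    missing_cols = [ph for ph in PHASES if ph not in wide.columns]
    incomplete = wide.index[wide.reindex(columns=PHASES).isna().any(axis=1)].tolist()
    if missing_cols or incomplete:
        raise ValidationError(
            f"incomplete three-phase data for metric {metric!r}: "
            f"participants {incomplete or 'all'}"
        )
    return wide[list(PHASES)]


def _durbin_conover(wide: pd.DataFrame) -> pd.DataFrame:
    """Durbin-Conover pairwise comparisons after Friedman (rank t-tests)."""
    ranks = wide.rank(axis=1)
    n, k = wide.shape
    rj = ranks.sum(axis=0)
    a1 = float((ranks.to_numpy() ** 2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    df = (n - 1) * (k - 1)
    t1_den = a1 - c1
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = wide.columns[i], wide.columns[j]
            if t1_den <= 0:
                rows.append({"a": pi, "b": pj, "statistic": 0.0, "pvalue": 1.0})
                continue
            t1 = (k - 1) * float(((rj - n * (k + 1) / 2.0) ** 2).sum()) / t1_den
            denom = np.sqrt(
                2.0 * n * t1_den * (1.0 - t1 / (n * (k - 1))) / df
            )
            if denom <= 0:
                stat, p = np.inf, 0.0
            else:
                stat = abs(rj[pi] - rj[pj]) / denom
                p = 2.0 * stats.t.sf(stat, df)
            rows.append({"a": pi, "b": pj, "statistic": float(stat), "pvalue": float(min(p, 1.0))})
    return pd.DataFrame(rows)


def _pairwise_wilcoxon_holm(wide: pd.DataFrame) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    cols = list(wide.columns)
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            d = wide[cols[i]] - wide[cols[j]]
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(d)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append({"a": cols[i], "b": cols[j], "statistic": stat, "pvalue": p})
    out = pd.DataFrame(rows)
    out["pvalue"] = multipletests(out.pvalue, method="holm")[1]
    return out


def friedman_test(
    table: pd.DataFrame,
    metric: str,
    posthoc: Literal["durbin-conover", "wilcoxon-holm"] = "durbin-conover",
) -> FriedmanResult:
    """Friedman rank ANOVA over the three phases, with pairwise post hoc.

    Requires complete three-phase data per participant (incomplete blocks
    raise, listing the participants).  The omnibus chi-square has
    ``phases - 1`` degrees of freedom and is invariant to strictly monotone
    transforms of the metric.  Post hoc defaults to the Durbin-Conover rank
    procedure; pairwise Wilcoxon with Holm correction is available.
    """
    wide = _pivot_complete(validate_cohort_table(table), metric)
    n = len(wide)
    if n < 2:
        raise ValidationError("Friedman test needs at least two complete blocks")
    if (wide.nunique(axis=1) == 1).all():
        return FriedmanResult(0.0, len(PHASES) - 1, 1.0, n, degenerate=True)
    chi2, p = stats.friedmanchisquare(*[wide[ph] for ph in PHASES])
    ph = (
        _durbin_conover(wide)
        if posthoc == "durbin-conover"
        else _pairwise_wilcoxon_holm(wide)
    )
    return FriedmanResult(float(chi2), len(PHASES) - 1, float(p), n, posthoc=ph)


@dataclass
class MixedAnovaResult:
    effects: pd.DataFrame   # Source, F, df1, df2, pvalue
    bartlett_stat: float
    bartlett_p: float
    degenerate: bool = False
    warning: str = ""


def mixed_anova(table: pd.DataFrame, metric: str) -> MixedAnovaResult:
    """Mixed repeated-measures ANOVA: phase within, role between.

    Classical sums-of-squares F tests (via pingouin) for the phase effect,
    the role effect and their interaction, with Bartlett's homogeneity test
    across phases reported alongside.  Unbalanced role groups are computed
    with a warning; an all-constant metric is reported degenerate.
    """
    import pingouin as pg

    vt = validate_cohort_table(table)
    sub = vt[vt.metric == metric].copy()
    _pivot_complete(vt, metric)  # raises on incomplete blocks
    if sub.value.nunique() == 1:
        return MixedAnovaResult(
            pd.DataFrame(), np.nan, np.nan, degenerate=True,
            warning="zero total variance; effects undefined",
        )
    counts = sub.groupby("role").participant_id.nunique()
    warning = ""
    if counts.nunique() > 1:
        warning = f"unbalanced roles: {counts.to_dict()}"
    aov = pg.mixed_anova(
        data=sub, dv="value", within="phase", subject="participant_id",
        between="role", correction=False,
    )
    effects = aov.rename(
        columns={"Source": "source", "DF1": "df1", "DF2": "df2",
                 "p-unc": "pvalue", "p_unc": "pvalue"}
    )[["source", "F", "df1", "df2", "pvalue"]]
    groups = [g.value.to_numpy() for _, g in sub.groupby("phase")]
    b_stat, b_p = stats.bartlett(*groups)
    return MixedAnovaResult(effects, float(b_stat), float(b_p), warning=warning)


@dataclass
class DyadicCorrelation:
    r: float
    n: int
    pvalue: float
    flag: str = ""


def dyadic_correlation(
    table: pd.DataFrame,
    x: tuple[str, str, str],
    y: tuple[str, str, str],
) -> DyadicCorrelation:
    """Pearson correlation across dyads between two member-specific values.

    ``x`` and ``y`` are ``(role, phase, metric)`` selectors; each dyad
    contributes the x value of its member in the first role paired with the
    y value of its member in the second role.  Needs at least three
    complete dyads; zero variance in either margin is flagged undefined.
    """
    vt = validate_cohort_table(table)

    def side(sel):
        role, phase, metric = sel
        s = vt[(vt.role == role) & (vt.phase == phase) & (vt.metric == metric)]
        return s.set_index("dyad_id")["value"]

    xs, ys = side(x), side(y)
    joined = pd.concat([xs, ys], axis=1, join="inner", keys=["x", "y"]).dropna()
    n = len(joined)
    if n < 3:
        raise ValidationError(f"dyadic correlation needs >= 3 complete dyads, got {n}")
    if joined.x.nunique() == 1 or joined.y.nunique() == 1:
        return DyadicCorrelation(np.nan, n, np.nan, flag="zero-variance margin")
    r, p = stats.pearsonr(joined.x, joined.y)
    return DyadicCorrelation(float(r), n, float(p))
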