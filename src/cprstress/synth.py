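"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a two-person simulated-resuscitation
study: three monitoring phases (pre / Sim / post), per-phase heart-rate and
RMSSD targets, right-skewed tonic electrodermal activity (log-normal,
calibrated exactly from a reported mean/median pair), Poisson-arriving skin
conductance responses with ramp-rise/exponential-decay shapes, a dyadic
coupling between team-leader pre-phase tonic EDA and team-member post-phase
SCR rate, and a noisy concave quadratic linking dyad-mean SD1 to a 0-10
performance score.

Every stochastic draw descends from a single integer seed through
``numpy.random.SeedSequence``, so identical configurations reproduce the
cohort byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .eda import EDATrace
from .errors import ValidationError
from .hrv import IBISeries

__all__ = [
    "PHASES",
    "GeneratorConfig",
    "GroundTruth",
    "CohortData",
    "InjectedSCR",
    "calibrate_lognormal",
    "latent_coupling_rho",
    "generate_ibi_trace",
    "generate_eda_trace",
    "generate_cohort",
    "write_cohort",
    "inject_eda_spikes",
    "inject_ibi_dropouts",
]

#: Monitoring-phase labels: baseline, during the simulated scenario, recovery.
PHASES = ("pre", "Sim", "post")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def calibrate_lognormal(mean: float, median: float) -> tuple[float, float]:
    """Log-normal parameters hitting a (mean, median) pair exactly.

    With location ``ln(median)`` and scale ``sqrt(2 ln(mean/median))`` the
    distribution's median is ``median`` and its mean
    ``median * exp(scale^2 / 2)`` equals ``mean``.  Requires
    ``0 < median <= mean`` (a log-normal is right-skewed).
    """
    if median <= 0 or mean <= 0:
        raise ValidationError("mean and median must be positive")
    if median > mean:
        raise ValidationError(
            "median > mean would need a left-skewed law; log-normal cannot fit"
        )
    return float(np.log(median)), float(np.sqrt(2.0 * np.log(mean / median)))


#: Physiological bounds on tonic skin conductance level (uS).  Human SCL
#: essentially never exceeds ~30 uS; the generator clips its log-normal
#: draws to this range the same way HR and RMSSD draws are clipped.
TONIC_BOUNDS = (0.05, 30.0)


def _clipped_lognormal_moments(loc, scale, lo, hi):
    """E[g], SD[g] and E[g'] for g(Z) = clip(exp(loc + scale Z), lo, hi)."""
    from scipy.stats import norm

    z_lo = (np.log(lo) - loc) / scale
    z_hi = (np.log(hi) - loc) / scale
    mean_ln = np.exp(loc + scale**2 / 2)
    mid = norm.cdf(z_hi - scale) - norm.cdf(z_lo - scale)
    eg = lo * norm.cdf(z_lo) + mean_ln * mid + hi * norm.sf(z_hi)
    eg2 = (
        lo**2 * norm.cdf(z_lo)
        + np.exp(2 * loc + 2 * scale**2)
        * (norm.cdf(z_hi - 2 * scale) - norm.cdf(z_lo - 2 * scale))
        + hi**2 * norm.sf(z_hi)
    )
    egp = scale * mean_ln * mid  # E[g'(Z)], g' = scale*exp(.) inside the bounds
    return eg, float(np.sqrt(max(eg2 - eg**2, 0.0))), egp


def latent_coupling_rho(
    rho: float, log_loc: float, log_scale: float,
    bounds: tuple[float, float] = TONIC_BOUNDS,
) -> float:
    """Latent bivariate-normal correlation producing Pearson ``rho``.

    The dyadic coupling pairs the bounded log-normal tonic-EDA margin
    ``g(Z1) = clip(exp(loc + s Z1), lo, hi)`` with a normal margin (SCR
    rate, linear in Z2).  By Stein's lemma ``Cov(g(Z1), Z2) =
    rho_latent E[g'(Z1)]``, so the latent correlation
    ``rho * SD[g] / E[g']`` makes the *measured* Pearson correlation of the
    pair exactly ``rho``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValidationError("dyad_rho must lie in [-1, 1]")
    if log_scale <= 0:
        return rho
    _, sd_g, e_gp = _clipped_lognormal_moments(log_loc, log_scale, *bounds)
    lat = rho * sd_g / e_gp
    if abs(lat) > 1.0:
        raise ValidationError(
            f"requested Pearson correlation {rho} is unattainable through the "
            f"tonic-EDA margin (latent {lat:.3f})"
        )
    return float(lat)


def generate_ibi_trace(
    mean_hr: float,
    rmssd_target: float,
    duration: float,
    seed,
    start_time: float = 0.0,
) -> IBISeries:
    """White-jitter IBI series with prescribed mean HR and expected RMSSD.

    Intervals are ``60000 / mean_hr`` ms plus iid zero-mean Gaussian jitter
    with SD ``rmssd_target / sqrt(2)``; successive differences of iid noise
    have variance twice the per-beat variance, so the expected RMSSD of the
    series equals the target.  Intervals are floored at 1 ms to stay
    positive.  Beats fill the requested duration.
    """
    if not 20.0 < mean_hr < 250.0:
        raise ValidationError(f"mean_hr {mean_hr} outside the physiologic (20, 250) bpm")
    if rmssd_target < 0:
        raise ValidationError("rmssd_target must be non-negative")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    rng = _rng(seed)
    mean_iv = 60000.0 / mean_hr
    sd = rmssd_target / np.sqrt(2.0)
    intervals = np.empty(0)
    total = 0.0
    while total < duration:
        chunk = mean_iv + sd * rng.standard_normal(256)
        chunk = np.maximum(chunk, 1.0)
        intervals = np.concatenate([intervals, chunk])
        total = intervals.sum() / 1000.0
    offsets = np.cumsum(intervals) / 1000.0
    keep = offsets <= duration
    return IBISeries(start_time, offsets[keep], intervals[keep])


@dataclass
class InjectedSCR:
    """Ground-truth record of one injected skin conductance response."""

    time: float       # onset, s from trace start
    amplitude: float  # uS
    rise: float       # ramp duration, s


def _scr_shape(t: np.ndarray, t0: float, amp: float, rise: float, half_life: float):
    """Linear ramp to ``amp`` over ``rise`` s, then exponential decay."""
    dt = t - t0
    out = np.zeros_like(t)
    ramp = (dt >= 0) & (dt < rise)
    out[ramp] = amp * dt[ramp] / rise
    tail = dt >= rise
    out[tail] = amp * np.exp2(-(dt[tail] - rise) / half_life)
    return out


def generate_eda_trace(
    tonic_mean: float,
    tonic_median: float,
    scr_rate: float,
    duration: float,
    fs: float,
    seed,
    *,
    tonic_level: Optional[float] = None,
    noise_sd: float = 0.0,
    amplitude_range: tuple[float, float] = (0.5, 1.0),
    rise_range: tuple[float, float] = (1.0, 3.0),
    decay_half_life: float = 4.0,
    min_spacing: float = 0.0,
    start_time: float = 0.0,
) -> tuple[EDATrace, list[InjectedSCR]]:
    """Synthesize a skin-conductance trace plus its ground-truth events.

    The tonic level is one draw from the log-normal calibrated to
    ``(tonic_mean, tonic_median)`` unless ``tonic_level`` overrides it (used
    for dyad-coupled draws).  SCRs arrive as a homogeneous Poisson process
    at ``scr_rate`` per minute; when ``min_spacing > 0``, arrivals closer
    than that to the previously kept event are thinned, which guarantees
    detector-resolvable events at the cost of exact Poisson counts.
    Samples are floored at 0.001 uS so the trace stays positive.
    """
    if fs <= 0:
        raise ValidationError("sampling rate must be positive")
    if scr_rate < 0:
        raise ValidationError("scr_rate must be non-negative")
    if duration <= 0:
        raise ValidationError("duration must be positive")
    loc, scale = calibrate_lognormal(tonic_mean, tonic_median)
    rng = _rng(seed)
    tonic = (
        float(np.clip(np.exp(loc + scale * rng.standard_normal()), *TONIC_BOUNDS))
        if tonic_level is None
        else float(tonic_level)
    )
    if tonic <= 0:
        raise ValidationError("tonic level must be positive")

    n_events = rng.poisson(scr_rate * duration / 60.0)
    times = np.sort(rng.uniform(0.0, duration, n_events))
    if min_spacing > 0 and len(times):
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= min_spacing:
                kept.append(t)
        times = np.array(kept)
    amps = rng.uniform(*amplitude_range, len(times))
    rises = rng.uniform(*rise_range, len(times))

    t = np.arange(int(round(duration * fs))) / fs
    v = np.full_like(t, tonic)
    horizon = decay_half_life * 14.0  # shape < 1e-4 of amplitude beyond this
    for t0, a, r in zip(times, amps, rises):
        i0 = int(np.floor(t0 * fs))
        i1 = min(len(t), int(np.ceil((t0 + r + horizon) * fs)) + 1)
        v[i0:i1] += _scr_shape(t[i0:i1], t0, a, r, decay_half_life)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(len(v))
    v = np.maximum(v, 1e-3)
    trace = EDATrace(start_time=start_time, fs=fs, values=v)
    events = [InjectedSCR(float(t0), float(a), float(r)) for t0, a, r in zip(times, amps, rises)]
    return trace, events


def _phase_dict(value, name):
    if not isinstance(value, dict) or set(value) != set(PHASES):
        raise ValidationError(f"{name} must map exactly the phases {PHASES}")
    return value


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Per-phase targets default to the study's reported descriptives: HR and
    RMSSD mean/SD, EDA mean/median pairs, and the baseline SCR rate
    (6.193 +- 3.23 events/min).  Scenario-phase and recovery-phase SCR
    rates have no reported value and default to 10 and 8 events/min (elevated
    sympathetic activity during and shortly after the scenario).
    """

    n_participants: int = 30
    seed: int = 0
    phase_durations: dict = field(
        default_factory=lambda: {"pre": 300.0, "Sim": 480.0, "post": 300.0}
    )
    hr_targets: dict = field(
        default_factory=lambda: {
            "pre": (79.771, 13.924),
            "Sim": (95.522, 8.0693),
            "post": (81.090, 18.648),
        }
    )
    rmssd_targets: dict = field(
        default_factory=lambda: {
            "pre": (45.507, 18.894),
            "Sim": (57.594, 31.750),
            "post": (45.611, 21.665),
        }
    )
    eda_mean_targets: dict = field(
        default_factory=lambda: {"pre": 3.2113, "Sim": 3.7927, "post": 6.0953}
    )
    eda_median_targets: dict = field(
        default_factory=lambda: {"pre": 1.48, "Sim": 1.985, "post": 2.57}
    )
    scr_rate_targets: dict = field(
        default_factory=lambda: {
            "pre": (6.193, 3.23),
            "Sim": (10.0, 3.23),
            "post": (8.0, 3.23),
        }
    )
    dyad_rho: float = 0.62
    perf_coeffs: tuple = (-15748.2, 631.81, 2.88)
    perf_noise_sd: float = 0.75
    eda_fs: float = 4.0
    eda_noise_sd: float = 0.01
    scr_amplitude_range: tuple = (0.5, 1.0)
    scr_rise_range: tuple = (1.0, 3.0)
    scr_decay_half_life: float = 4.0
    scr_min_spacing: float = 0.0
    pss_targets: tuple = (16.67, 6.64)
    vas_stress_targets: tuple = (3.89, 1.93)
    vas_anxiety_targets: tuple = (3.93, 1.98)
    cpt_max_raw: float = 20.0
    start_time: float = 1700000000.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 2 or self.n_participants % 2:
            raise ValidationError("n_participants must be a positive even integer")
        for name in ("phase_durations", "hr_targets", "rmssd_targets",
                     "eda_mean_targets", "eda_median_targets", "scr_rate_targets"):
            _phase_dict(getattr(self, name), name)
        if any(d <= 0 for d in self.phase_durations.values()):
            raise ValidationError("phase durations must be positive")
        for name in ("hr_targets", "rmssd_targets", "scr_rate_targets"):
            if any(sd < 0 for _, sd in getattr(self, name).values()):
                raise ValidationError(f"{name} SDs must be non-negative")
        if not -1.0 <= self.dyad_rho <= 1.0:
            raise ValidationError("dyad_rho must lie in [-1, 1]")
        for ph in PHASES:
            if self.eda_median_targets[ph] > self.eda_mean_targets[ph]:
                raise ValidationError(
                    f"phase {ph}: EDA median exceeds mean (right-skew assumption)"
                )
        if self.eda_fs <= 0:
            raise ValidationError("eda_fs must be positive")
        if self.perf_noise_sd < 0:
            raise ValidationError("perf_noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown generator fields: {sorted(unknown)}")
        d = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline tries to recover."""

    phase_truth: pd.DataFrame   # participant_id, role, dyad_id, phase, hr, rmssd, sd1, tonic_eda, scr_rate
    dyad_truth: pd.DataFrame    # dyad_id, tl_id, tm_id, scenario, dyad_sd1, perf_true, cpt_score
    events: dict                # (participant_id, phase) -> list[InjectedSCR]
    perf_coeffs: tuple
    dyad_rho: float
    latent_rho: float
    seed: int

    def to_cohort_table(self) -> pd.DataFrame:
        """Tidy participant x phase x metric table of the true values."""
        long = self.phase_truth.melt(
            id_vars=["participant_id", "role", "dyad_id", "phase"],
            value_vars=["hr", "rmssd", "sd1", "tonic_eda", "scr_rate"],
            var_name="metric",
            value_name="value",
        )
        return long.sort_values(
            ["metric", "participant_id", "phase"], ignore_index=True
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "dyad_rho": self.dyad_rho,
            "latent_rho": self.latent_rho,
            "perf_coeffs": list(self.perf_coeffs),
            "phase_truth": self.phase_truth.to_dict(orient="records"),
            "dyad_truth": self.dyad_truth.to_dict(orient="records"),
            "events": {
                f"{pid}/{phase}": [dataclasses.asdict(e) for e in evs]
                for (pid, phase), evs in self.events.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class CohortData:
    sessions: dict              # (participant_id, phase) -> {"eda": EDATrace, "ibi": IBISeries}
    participants: pd.DataFrame  # participant_id, pss10, vas_stress, vas_anxiety, role, dyad_id
    dyads: pd.DataFrame         # dyad_id, tl_id, tm_id, scenario, cpt_raw, cpt_max_raw
    truth: GroundTruth


def generate_cohort(
    config: GeneratorConfig, render_traces: bool = True
) -> CohortData:
    """Draw a full synthetic cohort.

    Participants receive psychometrics, are paired under the constrained
    randomization (no very-high-stress with very-low-stress pairings), get
    per-phase physiological ground truth (with the TL-pre-EDA / TM-post-SCR
    coupling applied per dyad), and a dyad performance score from the
    concave quadratic in dyad-mean SD1.  Raw traces are rendered per
    participant-phase unless ``render_traces`` is False (ground truth and
    tables only — useful for large calibration cohorts).
    """
    from .design import ParticipantProfile, constrained_randomize

    config.validate()
    n = config.n_participants
    ss = np.random.SeedSequence(config.seed)
    psych_rng, phys_rng, perf_rng, trace_ss = [
        np.random.default_rng(c) if i < 3 else c
        for i, c in enumerate(ss.spawn(4))
    ]
    pids = [f"P{i + 1:03d}" for i in range(n)]

    pss = np.clip(np.rint(psych_rng.normal(*config.pss_targets, n)), 0, 40).astype(int)
    vas_s = np.round(np.clip(psych_rng.normal(*config.vas_stress_targets, n), 0, 10), 2)
    vas_a = np.round(np.clip(psych_rng.normal(*config.vas_anxiety_targets, n), 0, 10), 2)
    profiles = [
        ParticipantProfile(pid, int(p), float(s), float(a))
        for pid, p, s, a in zip(pids, pss, vas_s, vas_a)
    ]
    rand_seed = int(psych_rng.integers(2**31))
    assignments = constrained_randomize(profiles, seed=rand_seed)

    role = {}
    dyad_of = {}
    for a in assignments:
        role[a.tl_id], role[a.tm_id] = "TL", "TM"
        dyad_of[a.tl_id] = dyad_of[a.tm_id] = a.dyad_id

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "pss10": pss,
            "vas_stress": vas_s,
            "vas_anxiety": vas_a,
            "role": [role[p] for p in pids],
            "dyad_id": [dyad_of[p] for p in pids],
        }
    )

    # --- per-phase physiological ground truth ------------------------------
    eda_params = {
        ph: calibrate_lognormal(
            config.eda_mean_targets[ph], config.eda_median_targets[ph]
        )
        for ph in PHASES
    }
    rows = []
    draws = {}
    for ph in PHASES:
        hr_m, hr_sd = config.hr_targets[ph]
        rm_m, rm_sd = config.rmssd_targets[ph]
        sc_m, sc_sd = config.scr_rate_targets[ph]
        draws[ph] = {
            "hr": np.clip(phys_rng.normal(hr_m, hr_sd, n), 30.0, 220.0),
            "rmssd": np.maximum(phys_rng.normal(rm_m, rm_sd, n), 3.0),
            "scr": np.maximum(phys_rng.normal(sc_m, sc_sd, n), 0.0),
            "z_tonic": phys_rng.standard_normal(n),
        }

    # dyadic coupling: TL pre tonic EDA <-> TM post SCR/min
    loc_pre, scale_pre = eda_params["pre"]
    lat = latent_coupling_rho(config.dyad_rho, loc_pre, scale_pre)
    sc_post_m, sc_post_sd = config.scr_rate_targets["post"]
    cov = np.array([[1.0, lat], [lat, 1.0]])
    z_pairs = phys_rng.multivariate_normal([0.0, 0.0], cov, size=len(assignments))
    idx = {p: i for i, p in enumerate(pids)}
    for a, (z1, z2) in zip(assignments, z_pairs):
        draws["pre"]["z_tonic"][idx[a.tl_id]] = z1
        draws["post"]["scr"][idx[a.tm_id]] = max(sc_post_m + sc_post_sd * z2, 0.0)

    for ph in PHASES:
        loc, scale = eda_params[ph]
        tonic = np.clip(np.exp(loc + scale * draws[ph]["z_tonic"]), *TONIC_BOUNDS)
        for i, pid in enumerate(pids):
            rows.append(
                {
                    "participant_id": pid,
                    "role": role[pid],
                    "dyad_id": dyad_of[pid],
                    "phase": ph,
                    "hr": float(draws[ph]["hr"][i]),
                    "rmssd": float(draws[ph]["rmssd"][i]),
                    "sd1": float(draws[ph]["rmssd"][i] / np.sqrt(2.0) / 1000.0),
                    "tonic_eda": float(tonic[i]),
                    "scr_rate": float(draws[ph]["scr"][i]),
                }
            )
    phase_truth = pd.DataFrame(rows)

    # --- dyad performance ---------------------------------------------------
    a_c, b_c, c_c = config.perf_coeffs
    sim = phase_truth[phase_truth.phase == "Sim"].set_index("participant_id")
    drows = []
    for asg in assignments:
        x = 0.5 * (sim.loc[asg.tl_id, "sd1"] + sim.loc[asg.tm_id, "sd1"])
        perf_true = a_c * x**2 + b_c * x + c_c
        score = float(
            np.clip(perf_true + perf_rng.normal(0.0, config.perf_noise_sd), 0.0, 10.0)
        )
        drows.append(
            {
                "dyad_id": asg.dyad_id,
                "tl_id": asg.tl_id,
                "tm_id": asg.tm_id,
                "scenario": asg.scenario,
                "dyad_sd1": float(x),
                "perf_true": float(perf_true),
                "cpt_score": score,
            }
        )
    dyad_truth = pd.DataFrame(drows)
    dyads = dyad_truth[["dyad_id", "tl_id", "tm_id", "scenario"]].copy()
    dyads["cpt_raw"] = dyad_truth.cpt_score / 10.0 * config.cpt_max_raw
    dyads["cpt_max_raw"] = config.cpt_max_raw

    # --- raw traces ---------------------------------------------------------
    sessions: dict = {}
    events: dict = {}
    if render_traces:
        children = trace_ss.spawn(2 * n * len(PHASES))
        pt = phase_truth.set_index(["participant_id", "phase"])
        k = 0
        t0 = config.start_time
        for pid in pids:
            for ph in PHASES:
                tr = pt.loc[(pid, ph)]
                dur = config.phase_durations[ph]
                ibi = generate_ibi_trace(
                    float(tr.hr), float(tr.rmssd), dur,
                    np.random.default_rng(children[k]), start_time=t0,
                )
                eda, evs = generate_eda_trace(
                    config.eda_mean_targets[ph],
                    config.eda_median_targets[ph],
                    float(tr.scr_rate),
                    dur,
                    config.eda_fs,
                    np.random.default_rng(children[k + 1]),
                    tonic_level=float(tr.tonic_eda),
                    noise_sd=config.eda_noise_sd,
                    amplitude_range=config.scr_amplitude_range,
                    rise_range=config.scr_rise_range,
                    decay_half_life=config.scr_decay_half_life,
                    min_spacing=config.scr_min_spacing,
                    start_time=t0,
                )
                sessions[(pid, ph)] = {"eda": eda, "ibi": ibi}
                events[(pid, ph)] = evs
                k += 2
                t0 += dur + 60.0

    truth = GroundTruth(
        phase_truth=phase_truth,
        dyad_truth=dyad_truth,
        events=events,
        perf_coeffs=tuple(config.perf_coeffs),
        dyad_rho=config.dyad_rho,
        latent_rho=lat,
        seed=config.seed,
    )
    return CohortData(sessions, participants, dyads, truth)


def write_cohort(data: CohortData, outdir: str | Path) -> Path:
    """Write wristband-dialect CSVs plus cohort tables under ``outdir``."""
    from .io import write_eda_csv, write_ibi_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (pid, ph), sess in data.sessions.items():
        d = outdir / pid / ph
        write_eda_csv(sess["eda"], d / "EDA.csv")
        write_ibi_csv(sess["ibi"], d / "IBI.csv")
    data.participants.to_csv(outdir / "participants.csv", index=False)
    data.dyads.to_csv(outdir / "dyads.csv", index=False)
    data.truth.to_json(outdir / "ground_truth.json")
    return outdir


def inject_eda_spikes(
    trace: EDATrace, times: list[float], magnitude: float = 10.0
) -> EDATrace:
    """Add single-sample motion spikes at the given times (for cleaning tests)."""
    v = trace.values.copy()
    for t in times:
        i = int(round(t * trace.fs))
        if 0 <= i < len(v):
            v[i] += magnitude
    return EDATrace(trace.start_time, trace.fs, v)


def inject_ibi_dropouts(
    series: IBISeries, indices: list[int], mode: str = "zero", factor: float = 2.5
) -> IBISeries:
    """Corrupt beats: ``zero`` sets intervals to 0, ``spike`` multiplies them."""
    iv = series.intervals.copy()
    for i in indices:
        if 0 <= i < len(iv):
            iv[i] = 0.0 if mode == "zero" else iv[i] * factor
    return IBISeries(series.start_time, series.offsets, iv, series.contiguous.copy())
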