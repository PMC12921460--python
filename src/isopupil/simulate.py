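"""Ground-truthed synthetic pupillometry sessions.

The generator embodies the physiological contrast the pipeline is built to
detect: luminance steps drive the pupil through *fast* first-order
dynamics (reflex constriction with a time constant of a couple hundred
milliseconds after a short latency, slower redilation in the dark), while
high-load task blocks add a *slow* saturating dilation that builds over
seconds and decays during rests. On top of the deterministic signal sit a
hippus sinusoid (the spontaneous slow oscillation of the resting pupil),
independent per-eye Gaussian sensor noise, timestamp jitter around the
nominal 90 Hz, and blinks inserted as zero-valued gaps at Poisson times —
the artifact the cleaning chain must remove.

Pupil dynamics are modeled as exact exponential tracking of a piecewise-
constant target: between samples, x += (target − x)(1 − exp(−dt/tau)),
with tau chosen by direction (constriction vs. redilation). The model is
deliberately minimal — first-order kinetics are the simplest dynamics
consistent with reflex completion within hundreds of milliseconds and
task-evoked dilation over 1–3 s — and every derived truth (plateau
amplitude, peak velocities = amplitude/tau at onset) is analytic.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .protocol import ProtocolTimeline, build_timeline
from .session import CANONICAL_COLUMNS, SessionTrace


@dataclass(frozen=True)
class SimulationParams:
    """Physiological and sensor parameters for one synthetic session.

    Magnitudes are mm, times seconds, rates Hz. Defaults are calibrated to
    a typical adult session: a ~4.75 mm dark-adapted pupil constricting
    ~1.5 mm under bright light with a 0.2 s time constant after a 0.25 s
    latency, and a ~0.38 mm task-evoked dilation building over ~2 s.
    """

    baseline_dark_mm: float = 4.75
    plr_amplitude_mm: float = 1.52
    plr_latency_s: float = 0.25
    constriction_tau_s: float = 0.2
    redilation_tau_s: float = 0.4
    iso_level_frac: float = 0.5  # iso target = baseline − frac·amplitude
    tepr_amplitude_mm: float = 0.38
    tepr_ramp_s: float = 2.0  # ~95% rise time; tracking tau = ramp/3
    blink_rate_hz: float = 0.2
    blink_duration_s: tuple[float, float] = (0.1, 0.2)
    noise_sd_mm: float = 0.02
    hippus_amplitude_mm: float = 0.05
    hippus_freq_hz: float = 0.15
    rate_hz: float = 90.0
    timestamp_jitter_s: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "baseline_dark_mm", "plr_amplitude_mm", "plr_latency_s",
            "constriction_tau_s", "redilation_tau_s", "tepr_amplitude_mm",
            "tepr_ramp_s", "blink_rate_hz", "noise_sd_mm",
            "hippus_amplitude_mm", "hippus_freq_hz", "timestamp_jitter_s",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.rate_hz <= 2 * self.hippus_freq_hz:
            raise ConfigError("rate_hz must exceed twice the hippus frequency")
        if self.blink_duration_s[0] > self.blink_duration_s[1]:
            raise ConfigError("blink_duration_s range must be (lo, hi)")


@dataclass
class GroundTruth:
    """Analytic truths recorded alongside each simulated session."""

    plr_amplitude_mm: float
    peak_constriction_velocity_mm_s: float  # amplitude / constriction tau
    tepr_difference_mm: float  # noiseless high-mean − low-mean of the TEPR term
    peak_dilation_velocity_mm_s: float  # tepr amplitude / (ramp/3)
    blink_intervals: list[tuple[float, float]]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _track(target: np.ndarray, dt: np.ndarray, tau_down: float, tau_up: float) -> np.ndarray:
    """Exponential tracking of a piecewise-constant target.

    tau_down applies when moving toward a smaller value (constriction),
    tau_up when moving toward a larger one (dilation).
    """
    x = np.empty_like(target)
    x[0] = target[0]
    for i in range(1, len(target)):
        tau = tau_down if target[i] < x[i - 1] else tau_up
        a = 1.0 - np.exp(-dt[i - 1] / tau)
        x[i] = x[i - 1] + (target[i] - x[i - 1]) * a
    return x


def _luminance_target(params: SimulationParams, timeline: ProtocolTimeline, t: np.ndarray) -> np.ndarray:
    """Diameter the luminance pathway drives toward, after the reflex latency."""
    labels = timeline.label_samples(np.clip(t - params.plr_latency_s, 0.0, None))
    target = np.full(len(t), params.baseline_dark_mm - params.iso_level_frac * params.plr_amplitude_mm)
    target[labels["luminance"] == "dark"] = params.baseline_dark_mm
    target[labels["luminance"] == "bright"] = params.baseline_dark_mm - params.plr_amplitude_mm
    return target


def simulate_session(
    params: SimulationParams,
    timeline: ProtocolTimeline | None = None,
    session_id: str = "sim",
) -> tuple[SessionTrace, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Deterministic given ``params.seed``: the same parameters always produce
    bit-identical traces.
    """
    tl = timeline or build_timeline()
    rng = np.random.default_rng(params.seed)
    dt_nom = 1.0 / params.rate_hz
    n = int(round(tl.total_s * params.rate_hz))
    t = np.arange(n) * dt_nom
    if params.timestamp_jitter_s > 0:
        jitter = np.clip(
            rng.normal(0.0, params.timestamp_jitter_s, n), -0.4 * dt_nom, 0.4 * dt_nom
        )
        t = t + jitter
        t[0] = 0.0
        t = np.maximum.accumulate(t + np.arange(n) * 1e-12)  # keep strictly increasing
    dt = np.diff(t)

    # luminance-driven component (fast constriction, slower redilation)
    lum = _track(_luminance_target(params, tl, t), dt, params.constriction_tau_s, params.redilation_tau_s)

    # task-evoked component: saturating ramp toward tepr_amplitude in high
    # blocks, decay toward 0 elsewhere, shared time constant ramp/3
    labels = tl.label_samples(t)
    high = (labels["load"] == "high").astype(float)
    tau_c = max(params.tepr_ramp_s / 3.0, 1e-9)
    tepr = _track(params.tepr_amplitude_mm * high, dt, tau_c, tau_c)

    phase = rng.uniform(0, 2 * np.pi)
    hippus = params.hippus_amplitude_mm * np.sin(2 * np.pi * params.hippus_freq_hz * t + phase)
    common = lum + tepr + hippus

    left = common + rng.normal(0.0, params.noise_sd_mm, n)
    right = common + rng.normal(0.0, params.noise_sd_mm, n)
    left_open = np.ones(n)
    right_open = np.ones(n)
    gaze = 0.5 + 0.02 * rng.standard_normal((n, 2))

    # blinks: Poisson count, uniform onsets, zero-valued gaps in both eyes
    n_blinks = rng.poisson(params.blink_rate_hz * tl.total_s)
    blink_intervals: list[tuple[float, float]] = []
    for _ in range(n_blinks):
        dur = rng.uniform(*params.blink_duration_s)
        start = rng.uniform(0.0, max(tl.total_s - dur, 0.0))
        blink_intervals.append((float(start), float(start + dur)))
        m = (t >= start) & (t < start + dur)
        left[m] = 0.0
        right[m] = 0.0
        left_open[m] = 0.0
        right_open[m] = 0.0

    df = pd.DataFrame(
        {
            "t_s": t,
            "left_mm": np.clip(left, 0.0, 11.99),
            "right_mm": np.clip(right, 0.0, 11.99),
            "left_open": left_open,
            "right_open": right_open,
            "gaze_x": gaze[:, 0],
            "gaze_y": gaze[:, 1],
        },
        columns=list(CANONICAL_COLUMNS),
    )
    trace = SessionTrace(df, session_id=session_id, nominal_rate_hz=params.rate_hz)

    low = labels["load"] == "low"
    high_m = labels["load"] == "high"
    tepr_diff = float(np.mean(tepr[high_m]) - np.mean(tepr[low])) if low.any() and high_m.any() else 0.0
    truth = GroundTruth(
        plr_amplitude_mm=params.plr_amplitude_mm,
        peak_constriction_velocity_mm_s=(
            params.plr_amplitude_mm / params.constriction_tau_s
            if params.constriction_tau_s > 0
            else float("inf")
        ),
        tepr_difference_mm=tepr_diff,
        peak_dilation_velocity_mm_s=params.tepr_amplitude_mm / tau_c,
        blink_intervals=blink_intervals,
    )
    return trace, truth


@dataclass(frozen=True)
class CohortRanges:
    """Per-session sampling ranges for cohort simulation.

    Defaults span the published distribution of healthy adults: dark
    baselines of 3.75–6.80 mm and constriction fractions of 25–41 % of the
    dark baseline, with task-evoked dilations of 0.15–0.80 mm. Dynamics
    (time constants, ramp) are held at the session defaults.
    """

    baseline_dark_mm: tuple[float, float] = (3.75, 6.80)
    constriction_frac: tuple[float, float] = (0.254, 0.411)
    tepr_amplitude_mm: tuple[float, float] = (0.15, 0.80)


def simulate_cohort(
    n: int,
    seed: int = 0,
    ranges: CohortRanges | None = None,
    base_params: SimulationParams | None = None,
    timeline: ProtocolTimeline | None = None,
) -> list[tuple[SessionTrace, GroundTruth]]:
    """Simulate ``n`` independent sessions with per-session parameters.

    Seeding is splittable and prefix-stable: per-session seeds come from
    ``np.random.SeedSequence(seed).spawn(n)``, so session *i* is identical
    regardless of ``n``.
    """
    if n < 1:
        raise ConfigError("cohort size must be >= 1")
    rg = ranges or CohortRanges()
    base = base_params or SimulationParams()
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        baseline = rng.uniform(*rg.baseline_dark_mm)
        amp = baseline * rng.uniform(*rg.constriction_frac)
        tepr = rng.uniform(*rg.tepr_amplitude_mm)
        session_seed = int(rng.integers(0, 2**31 - 1))
        params = SimulationParams(
            **{
                **asdict(base),
                "baseline_dark_mm": baseline,
                "plr_amplitude_mm": amp,
                "tepr_amplitude_mm": tepr,
                "seed": session_seed,
            }
        )
        out.append(simulate_session(params, timeline, session_id=f"sim_{i:03d}"))
    return out
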