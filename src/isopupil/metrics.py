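"""Per-session outcome metrics: light-reflex, cognitive-load, velocity ratio.

The light-reflex (PLR) metrics come from the minimally filtered (4 Hz)
pathway over Phase 1; the cognitive metrics from the aggressively filtered
(0.5 Hz) pathway over Phase 3. Each pathway's velocity is computed on its
own filtered trace: cross-applying filters would either flatten the reflex
peak (0.5 Hz on PLR) or let noise masquerade as dilation velocity (4 Hz on
the cognitive signal).

The dissociation statistic is the **velocity ratio**

    velocity_ratio = peak constriction velocity / peak dilation velocity,

which is well above 1 when constriction is reflex-fast (hundreds of ms)
and dilation is effort-slow (seconds) — the temporal signature that the
iso-luminant design aims to demonstrate.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .errors import (
    MissingConditionError,
    MissingPhaseError,
    PreconditionError,
    UndefinedRatioError,
)
from .preprocess import FilteredTrace, PreprocessConfig, preprocess
from .protocol import ProtocolTimeline
from .session import SessionTrace, combine_eyes


def derivative(trace: FilteredTrace) -> np.ndarray:
    """First derivative (mm/s) on the trace's uniform grid.

    Central differences in the interior, one-sided at the edges; exact for
    affine signals.
    """
    if len(trace.value) < 3:
        raise PreconditionError("derivative needs at least 3 samples")
    return np.gradient(trace.value, 1.0 / trace.rate_hz)


@dataclass(frozen=True)
class PLRMetrics:
    """Pupillary light reflex outcomes from Phase 1."""

    dark_mean_mm: float
    bright_mean_mm: float
    amplitude_mm: float
    constriction_pct: float
    peak_constriction_velocity_mm_s: float

    @classmethod
    def from_means(
        cls,
        dark_mean_mm: float,
        bright_mean_mm: float,
        peak_constriction_velocity_mm_s: float = float("nan"),
    ) -> "PLRMetrics":
        """Build from state means; amplitude = dark − bright, constriction
        percentage = 100 · amplitude / dark."""
        amp = dark_mean_mm - bright_mean_mm
        pct = 100.0 * amp / dark_mean_mm if dark_mean_mm > 0 else float("nan")
        return cls(dark_mean_mm, bright_mean_mm, amp, pct, peak_constriction_velocity_mm_s)


@dataclass(frozen=True)
class CognitiveMetrics:
    """Task-evoked response outcomes from Phase 3."""

    low_mean_mm: float
    high_mean_mm: float
    difference_mm: float
    percent_change: float
    peak_dilation_velocity_mm_s: float

    @classmethod
    def from_means(
        cls,
        low_mean_mm: float,
        high_mean_mm: float,
        peak_dilation_velocity_mm_s: float = float("nan"),
    ) -> "CognitiveMetrics":
        """Build from condition means; difference = high − low, percent
        change relative to the low-load mean."""
        diff = high_mean_mm - low_mean_mm
        pct = 100.0 * diff / low_mean_mm if low_mean_mm > 0 else float("nan")
        return cls(low_mean_mm, high_mean_mm, diff, pct, peak_dilation_velocity_mm_s)


@dataclass
class SessionMetrics:
    """All per-session outcomes plus QC fields."""

    session_id: str
    plr: PLRMetrics
    cognitive: CognitiveMetrics
    velocity_ratio: float
    data_loss_fraction: float
    excluded: bool
    artifact_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionMetrics":
        return cls(
            session_id=d["session_id"],
            plr=PLRMetrics(**d["plr"]),
            cognitive=CognitiveMetrics(**d["cognitive"]),
            velocity_ratio=d["velocity_ratio"],
            data_loss_fraction=d["data_loss_fraction"],
            excluded=d["excluded"],
            artifact_counts=d.get("artifact_counts", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SessionMetrics":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class MetricsConfig:
    """Windows used by the metric extractors.

    ``plr_onset_window_s`` bounds the search for peak constriction velocity
    after each dark->bright transition (the reflex completes within a few
    hundred ms); ``cognitive_onset_window_s`` bounds the dilation-velocity
    search after each rest->high transition (effort-driven dilation builds
    over seconds). ``settle_skip_s`` optionally drops the first part of each
    state before pooling means; the default pools whole states.
    """

    plr_onset_window_s: float = 1.0
    cognitive_onset_window_s: float = 5.0
    settle_skip_s: float = 0.0


def _state_mean(
    trace: FilteredTrace, labels: np.ndarray, sel: np.ndarray, skip_s: float, timeline: ProtocolTimeline
) -> float:
    if skip_s > 0:
        # drop samples within skip_s of the start of their interval
        starts = np.array([iv.start_s for iv in timeline.intervals])
        idx = np.searchsorted(starts, trace.t, side="right") - 1
        since_start = trace.t - starts[np.clip(idx, 0, None)]
        sel = sel & (since_start >= skip_s)
    if not sel.any():
        return float("nan")
    return float(np.mean(trace.value[sel]))


def plr_metrics(
    trace: FilteredTrace,
    timeline: ProtocolTimeline,
    config: MetricsConfig | None = None,
) -> PLRMetrics:
    """Light-reflex metrics from the 4 Hz pathway.

    Dark/bright means pool every Phase 1 sample in the respective state.
    Peak constriction velocity is the largest magnitude of negative
    derivative within ``plr_onset_window_s`` after any dark->bright
    transition, reported as a positive number.
    """
    cfg = config or MetricsConfig()
    labels = timeline.label_samples(trace.t)
    in_plr = labels["phase"] == "plr"
    if not in_plr.any():
        raise MissingPhaseError("trace does not cover the PLR phase")
    dark = in_plr & (labels["luminance"] == "dark")
    bright = in_plr & (labels["luminance"] == "bright")
    if not dark.any() or not bright.any():
        raise MissingPhaseError("PLR phase needs both dark and bright samples")
    dark_mean = _state_mean(trace, labels, dark, cfg.settle_skip_s, timeline)
    bright_mean = _state_mean(trace, labels, bright, cfg.settle_skip_s, timeline)

    vel = derivative(trace)
    peak = 0.0
    for onset in timeline.transitions("plr", "bright"):
        w = (trace.t >= onset) & (trace.t <= onset + cfg.plr_onset_window_s)
        if w.any():
            peak = max(peak, float(-np.min(vel[w])))
    return PLRMetrics.from_means(dark_mean, bright_mean, peak)


def cognitive_metrics(
    trace: FilteredTrace,
    timeline: ProtocolTimeline,
    config: MetricsConfig | None = None,
) -> CognitiveMetrics:
    """Cognitive-load metrics from the 0.5 Hz pathway.

    Low/high means pool task-block samples (rests excluded). Peak dilation
    velocity is the largest positive derivative within
    ``cognitive_onset_window_s`` after each transition into a high block.
    """
    cfg = config or MetricsConfig()
    labels = timeline.label_samples(trace.t)
    cog = labels["phase"] == "cognitive"
    low = cog & (labels["load"] == "low")
    high = cog & (labels["load"] == "high")
    if not low.any() or not high.any():
        raise MissingConditionError("need samples in both low- and high-load blocks")
    low_mean = _state_mean(trace, labels, low, cfg.settle_skip_s, timeline)
    high_mean = _state_mean(trace, labels, high, cfg.settle_skip_s, timeline)

    vel = derivative(trace)
    peak = 0.0
    for onset in timeline.transitions("cognitive", "high"):
        w = (trace.t >= onset) & (trace.t <= onset + cfg.cognitive_onset_window_s)
        if w.any():
            peak = max(peak, float(np.max(vel[w])))
    return CognitiveMetrics.from_means(low_mean, high_mean, peak)


def velocity_ratio(plr: PLRMetrics, cognitive: CognitiveMetrics) -> float:
    """Peak constriction velocity over peak dilation velocity.

    Values substantially above 1 indicate that constriction is much faster
    than task-evoked dilation, i.e. the two responses are temporally
    dissociated.
    """
    vc = plr.peak_constriction_velocity_mm_s
    vd = cognitive.peak_dilation_velocity_mm_s
    if not (vd > 0) or not (vc > 0):
        raise UndefinedRatioError(
            f"velocity ratio undefined for constriction={vc}, dilation={vd} mm/s"
        )
    return vc / vd


def analyze_session(
    trace: SessionTrace,
    timeline: ProtocolTimeline,
    pre_config: PreprocessConfig | None = None,
    metrics_config: MetricsConfig | None = None,
    eye_mode: str = "mean",
) -> SessionMetrics:
    """Full pipeline for one session: combine eyes, clean, filter, score.

    Metrics are computed even for sessions failing the data-loss criterion;
    ``excluded`` records the QC verdict for cohort-level filtering.
    """
    diam = combine_eyes(trace, eye_mode)
    res = preprocess(trace.t, diam, pre_config)
    plr = plr_metrics(res.plr, timeline, metrics_config)
    cog = cognitive_metrics(res.cognitive, timeline, metrics_config)
    return SessionMetrics(
        session_id=trace.session_id,
        plr=plr,
        cognitive=cog,
        velocity_ratio=velocity_ratio(plr, cog),
        data_loss_fraction=res.data_loss_fraction,
        excluded=res.excluded,
        artifact_counts=res.mask.counts(),
    )
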