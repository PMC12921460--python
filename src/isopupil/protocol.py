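"""Three-phase iso-luminant protocol timeline.

The session alternates a reflex-probing phase with an iso-luminant
cognitive phase:

* **Phase 1 — PLR validation** (default 60 s): the whole visual field
  alternates between a dark gray (RGB 20) and a bright gray (RGB 180),
  three cycles of 10 s per state, probing the pupillary light reflex.
* **Phase 2 — washout** (default 60 s): constant mid-gray (RGB 90) lets
  residual constriction dissipate; the final 10 s are labeled ``baseline``.
* **Phase 3 — cognitive load** (default 240 s): luminance stays clamped at
  the mid-gray while auditory tasks alternate low and high working-memory
  load in an ABBA block order (Low-High-High-Low), 45 s blocks with 15 s
  rests. By default a leading 15 s rest precedes the first block so the
  phase totals 240 s with three inter-block rests.

Gray levels are single-channel 0-255 proxies for relative luminance; the
RGB stimuli are achromatic and no photometric calibration is assumed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError

PHASES = ("plr", "washout", "baseline", "cognitive")
LUMINANCE_STATES = ("dark", "bright", "iso")
LOADS = ("none", "low", "high", "rest")


@dataclass(frozen=True)
class Interval:
    """Half-open labeled interval [start_s, end_s) of the session."""

    start_s: float
    end_s: float
    phase: str
    luminance_state: str
    load: str
    gray_level: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and luminance parameters of the protocol.

    Defaults reproduce the canonical 360 s session (60 + 60 + 240 s).
    """

    plr_cycles: int = 3
    plr_state_s: float = 10.0
    plr_start_state: str = "dark"
    washout_s: float = 60.0
    baseline_s: float = 10.0
    block_s: float = 45.0
    rest_s: float = 15.0
    block_order: tuple[str, ...] = ("low", "high", "high", "low")
    leading_rest: bool = True
    gray_dark: int = 20
    gray_bright: int = 180
    gray_iso: int = 90

    def __post_init__(self) -> None:
        if self.plr_cycles < 1:
            raise ConfigError("plr_cycles must be >= 1")
        for name in ("plr_state_s", "washout_s", "baseline_s", "block_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.baseline_s > self.washout_s:
            raise ConfigError("baseline_s cannot exceed washout_s")
        if self.plr_start_state not in ("dark", "bright"):
            raise ConfigError("plr_start_state must be 'dark' or 'bright'")
        bad = set(self.block_order) - {"low", "high"}
        if bad:
            raise ConfigError(f"block_order entries must be low/high, got {bad}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "block_order" in d:
            d["block_order"] = tuple(d["block_order"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["block_order"] = list(self.block_order)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


@dataclass
class ProtocolTimeline:
    """Contiguous, non-overlapping labeled intervals covering the session."""

    intervals: list[Interval]
    config: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __post_init__(self) -> None:
        iv = self.intervals
        if not iv:
            raise ConfigError("timeline has no intervals")
        if abs(iv[0].start_s) > 1e-12:
            raise ConfigError("timeline must start at t = 0")
        for a, b in zip(iv, iv[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ConfigError("timeline intervals must be contiguous")

    @property
    def total_s(self) -> float:
        return self.intervals[-1].end_s

    def phase_duration(self, phase: str) -> float:
        """Summed duration of all intervals in a phase.

        ``"washout"`` includes the trailing baseline window since baseline
        is the final part of the washout period.
        """
        members = {phase}
        if phase == "washout":
            members.add("baseline")
        return sum(iv.duration_s for iv in self.intervals if iv.phase in members)

    def transitions(self, phase: str, into: str) -> list[float]:
        """Start times of intervals of ``phase`` whose luminance state or
        load equals ``into`` and differs from the previous interval."""
        out = []
        prev: Interval | None = None
        for iv in self.intervals:
            if iv.phase == phase and into in (iv.luminance_state, iv.load):
                if prev is None or (into not in (prev.luminance_state, prev.load)):
                    out.append(iv.start_s)
            prev = iv
        return out

    def _lookup(self, times: np.ndarray) -> np.ndarray:
        starts = np.array([iv.start_s for iv in self.intervals])
        idx = np.searchsorted(starts, times, side="right") - 1
        idx[(times < 0) | (times >= self.total_s)] = -1
        return idx

    def label_samples(self, times: Sequence[float]) -> np.ndarray:
        """Label each time with (phase, luminance_state, load, gray_level).

        Membership is by half-open interval: a boundary time belongs to the
        interval it starts. Times outside the session get phase
        ``"outside"``.
        """
        times = np.asarray(times, float)
        idx = self._lookup(times)
        out = np.empty(
            len(times),
            dtype=[("phase", "U12"), ("luminance", "U8"), ("load", "U8"), ("gray", "i4")],
        )
        out["phase"] = "outside"
        out["luminance"] = ""
        out["load"] = ""
        out["gray"] = -1
        inside = idx >= 0
        for k in np.unique(idx[inside]):
            iv = self.intervals[k]
            m = idx == k
            out["phase"][m] = iv.phase
            out["luminance"][m] = iv.luminance_state
            out["load"][m] = iv.load
            out["gray"][m] = iv.gray_level
        return out

    def luminance_trace(self, times: Sequence[float]) -> np.ndarray:
        """Programmed gray level (0-255) at each time; -1 outside."""
        return self.label_samples(times)["gray"]


def build_timeline(config: ProtocolConfig | None = None) -> ProtocolTimeline:
    """Construct the protocol timeline from a configuration.

    With defaults: Phase 1 = 3 x (10 s dark + 10 s bright) = 60 s;
    Phase 2 = 60 s washout at the iso gray with the final 10 s labeled
    ``baseline``; Phase 3 = leading 15 s rest, then 45 s blocks in the
    order low, high, high, low separated by 15 s rests (240 s total).
    """
    cfg = config or ProtocolConfig()
    iv: list[Interval] = []
    t = 0.0

    states = ["dark", "bright"] if cfg.plr_start_state == "dark" else ["bright", "dark"]
    for _ in range(cfg.plr_cycles):
        for state in states:
            gray = cfg.gray_dark if state == "dark" else cfg.gray_bright
            iv.append(Interval(t, t + cfg.plr_state_s, "plr", state, "none", gray))
            t += cfg.plr_state_s

    pre = cfg.washout_s - cfg.baseline_s
    if pre > 0:
        iv.append(Interval(t, t + pre, "washout", "iso", "none", cfg.gray_iso))
        t += pre
    iv.append(Interval(t, t + cfg.baseline_s, "baseline", "iso", "none", cfg.gray_iso))
    t += cfg.baseline_s

    def rest() -> None:
        nonlocal t
        iv.append(Interval(t, t + cfg.rest_s, "cognitive", "iso", "rest", cfg.gray_iso))
        t += cfg.rest_s

    if cfg.leading_rest:
        rest()
    for i, load in enumerate(cfg.block_order):
        if i > 0:
            rest()
        iv.append(Interval(t, t + cfg.block_s, "cognitive", "iso", load, cfg.gray_iso))
        t += cfg.block_s

    return ProtocolTimeline(iv, cfg)
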