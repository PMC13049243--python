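"""cMRF excitation/preparation schedule.

The acquisition spans 15 heartbeats in a breathhold.  Each heartbeat opens
with a magnetization preparation drawn from a repeating 5-heartbeat block
(inversion / none / T2-prep 30 ms / T2-prep 80 ms / none), followed by 12
FISP excitations at TR = 20.4 ms (a 245 ms diastolic window) with a
sinusoidal flip-angle ramp between 5.7 and 20 degrees; the remainder of each
R-R interval is free recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


class TimingError(ValueError):
    """R-R interval too short for the acquisition window."""


@dataclass(frozen=True)
class PrepEvent:
    kind: str  # "inversion" | "t2prep" | "none"
    te_ms: float = 0.0

    def __post_init__(self):
        if self.kind not in ("inversion", "t2prep", "none"):
            raise ValueError(f"unknown prep kind {self.kind!r}")


@dataclass
class RFPulseSpec:
    """Windowed-sinc excitation pulse used for slice-profile correction."""

    duration_us: float = 800.0
    time_bandwidth: float = 2.0
    n_subslices: int = 1

    def __post_init__(self):
        if self.n_subslices < 1:
            raise ValueError("n_subslices must be >= 1")


@dataclass
class ScheduleConfig:
    n_heartbeats: int = 15
    exc_per_heartbeat: int = 12
    tr_ms: float = 20.4
    flip_min_deg: float = 5.7
    flip_max_deg: float = 20.0
    te1_ms: float = 1.74
    dte_ms: float = 0.79
    t2prep_te_ms: tuple[float, float] = (30.0, 80.0)
    inversion_efficiency: float = 0.95

    @property
    def acq_window_ms(self) -> float:
        return self.exc_per_heartbeat * self.tr_ms


@dataclass
class AcquisitionSchedule:
    """Fully resolved per-excitation schedule."""

    n_heartbeats: int
    exc_per_heartbeat: int
    tr_ms: float
    flip_deg: np.ndarray          # (n_excitations,)
    prep_events: list[PrepEvent]  # one per heartbeat
    rr_ms: np.ndarray             # (n_heartbeats,)
    te1_ms: float
    dte_ms: float
    inversion_efficiency: float = 0.95

    @property
    def n_excitations(self) -> int:
        return self.n_heartbeats * self.exc_per_heartbeat

    @property
    def recovery_ms(self) -> np.ndarray:
        """Free-recovery time after the acquisition window, per heartbeat."""
        return self.rr_ms - self.exc_per_heartbeat * self.tr_ms


def default_flip_pattern(cfg: ScheduleConfig) -> np.ndarray:
    """Raised-sine flip ramp per heartbeat spanning the configured extrema.

    alpha_j = fmin + (fmax - fmin) * sin(pi * j / n) for j = 0..n-1, so each
    heartbeat starts at the minimum and peaks at the maximum mid-window.
    """
    j = np.arange(cfg.exc_per_heartbeat)
    ramp = cfg.flip_min_deg + (cfg.flip_max_deg - cfg.flip_min_deg) * np.sin(
        np.pi * j / cfg.exc_per_heartbeat
    )
    return np.tile(ramp, cfg.n_heartbeats)


def default_prep_pattern(cfg: ScheduleConfig) -> list[PrepEvent]:
    """5-heartbeat block (inversion, none, T2-prep short, T2-prep long, none)
    repeated to cover all heartbeats."""
    te_a, te_b = cfg.t2prep_te_ms
    block = [PrepEvent("inversion"), PrepEvent("none"),
             PrepEvent("t2prep", te_a), PrepEvent("t2prep", te_b),
             PrepEvent("none")]
    return [block[h % len(block)] for h in range(cfg.n_heartbeats)]


def build_schedule(rr_ms_list, config: ScheduleConfig | None = None,
                   flip_deg: np.ndarray | None = None,
                   prep_events: list[PrepEvent] | None = None) -> AcquisitionSchedule:
    """Build the per-excitation schedule from heartbeat R-R intervals."""
    cfg = config or ScheduleConfig()
    rr = np.asarray(rr_ms_list, dtype=float)
    if rr.size == 0:
        raise TimingError("at least one heartbeat is required")
    if rr.size != cfg.n_heartbeats:
        cfg = ScheduleConfig(**{**cfg.__dict__, "n_heartbeats": int(rr.size)})
    if np.any(rr < cfg.acq_window_ms):
        raise TimingError(
            f"R-R interval shorter than the {cfg.acq_window_ms:.1f} ms acquisition window"
        )
    flips = default_flip_pattern(cfg) if flip_deg is None else np.asarray(flip_deg, float)
    preps = default_prep_pattern(cfg) if prep_events is None else list(prep_events)
    if flips.size != cfg.n_heartbeats * cfg.exc_per_heartbeat:
        raise ValueError("flip angle list does not match the excitation count")
    if len(preps) != cfg.n_heartbeats:
        raise ValueError("one prep event per heartbeat is required")
    return AcquisitionSchedule(
        n_heartbeats=cfg.n_heartbeats, exc_per_heartbeat=cfg.exc_per_heartbeat,
        tr_ms=cfg.tr_ms, flip_deg=flips, prep_events=preps, rr_ms=rr,
        te1_ms=cfg.te1_ms, dte_ms=cfg.dte_ms,
        inversion_efficiency=cfg.inversion_efficiency,
    )


def save_schedule(path: str, sched: AcquisitionSchedule) -> None:
    doc = {
        "tr_ms": sched.tr_ms, "te1_ms": sched.te1_ms, "dte_ms": sched.dte_ms,
        "exc_per_heartbeat": sched.exc_per_heartbeat,
        "inversion_efficiency": sched.inversion_efficiency,
        "rr_ms": [float(x) for x in sched.rr_ms],
        "prep_events": [{"kind": p.kind, "te_ms": p.te_ms} for p in sched.prep_events],
        "flip_deg": [float(x) for x in sched.flip_deg],
    }
    with open(path, "w") as f:
        yaml.safe_dump(doc, f)


def load_schedule(path: str) -> AcquisitionSchedule:
    with open(path) as f:
        doc = yaml.safe_load(f)
    rr = np.asarray(doc["rr_ms"], float)
    return AcquisitionSchedule(
        n_heartbeats=rr.size, exc_per_heartbeat=int(doc["exc_per_heartbeat"]),
        tr_ms=float(doc["tr_ms"]),
        flip_deg=np.asarray(doc["flip_deg"], float),
        prep_events=[PrepEvent(p["kind"], float(p.get("te_ms", 0.0)))
                     for p in doc["prep_events"]],
        rr_ms=rr, te1_ms=float(doc["te1_ms"]), dte_ms=float(doc["dte_ms"]),
        inversion_efficiency=float(doc.get("inversion_efficiency", 0.95)),
    )
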