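"""Proximity-feedback mappings: traffic-light zone, audio pitch, haptic
intensity, and streaming evaluation over a dual-sensor tracker log.

The operator is guided by three redundant channels driven by the same
margins:

* traffic light — RED "do not continue with entry", AMBER "continue with
  entry, but with caution", GREEN "safe to continue with entry";
* audio — a beep rising in pitch by a fixed step (default 25 Hz from a
  470 Hz base) as the needle approaches the target;
* haptic — a wrist-worn vibration (up to 80% waveform intensity) that
  weakens on approach and stops completely in the green state.

Margins (defaults): RED for radial distance R > 4.0 mm or angular
deviation α > 10°, GREEN for R ≤ 2.0 mm with α in limit, AMBER between.
The printed device margins quote amber as 2.6–4.0 mm; the classifier here
is total, with amber covering the whole interval (2.0, 4.0] — the 2.6 mm
figure is retained in the config for documentation.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .geometry import (
    GuidanceParameters,
    Pose6DOF,
    RigidTransform,
    guidance_parameters,
)

__all__ = [
    "Zone",
    "FeedbackConfig",
    "GuidanceState",
    "classify_zone",
    "audio_frequency",
    "haptic_intensity",
    "evaluate",
    "guidance_stream",
    "states_to_dataframe",
    "write_states",
]


class Zone(str, Enum):
    """Traffic-light indicator states."""

    RED = "RED"
    AMBER = "AMBER"
    GREEN = "GREEN"


@dataclass(frozen=True)
class FeedbackConfig:
    """Margins and mapping parameters for the three feedback channels.

    Attributes
    ----------
    red_R_threshold : mm
        Radial distance above which the indicator is red (exclusive bound).
    amber_R_lower : mm
        Lower end of the amber band as printed on the device spec sheet;
        documentation only — the classifier assigns amber to the whole gap
        between the green and red thresholds so that it is total.
    green_R_threshold : mm
        Largest radial distance classified green (inclusive bound).
    alpha_limit : degrees
        Maximum angular deviation tolerated outside the red state
        (inclusive: exactly at the limit is in-limit).
    audio_base_hz, audio_step_hz : Hz
        Beep pitch at the start radius and the increment per distance step.
    audio_start_radius : mm
        Distance at which audio feedback starts from the base pitch and the
        haptic ramp sits at its maximum.
    audio_step_mm : mm
        Approach distance corresponding to one audio pitch step.
    haptic_max_pct : %
        Vibration waveform intensity at/beyond the start radius.
    haptic_floor_pct : %
        Minimum non-zero vibration whenever the zone is not green, so the
        vibration stops exactly when the state is safe-to-proceed even if
        only the angle is out of limit.
    safe_cone_deg : degrees
        Full width of the clock-face safe entry window (10:00–02:00 ≙ 60°);
        informational.
    pairing_tolerance_s : s or None
        Needle/target sample pairing tolerance for streaming; ``None``
        means half the nominal sample interval of the log.
    debounce_samples : int
        Number of consecutive samples a new zone must persist before the
        streamed zone changes; 0 disables debouncing (default — the device
        applied none).
    """

    red_R_threshold: float = 4.0
    amber_R_lower: float = 2.6
    green_R_threshold: float = 2.0
    alpha_limit: float = 10.0
    audio_base_hz: float = 470.0
    audio_step_hz: float = 25.0
    audio_start_radius: float = 20.0
    audio_step_mm: float = 1.0
    haptic_max_pct: float = 80.0
    haptic_floor_pct: float = 5.0
    safe_cone_deg: float = 60.0
    pairing_tolerance_s: Optional[float] = None
    debounce_samples: int = 0

    def __post_init__(self):
        if not (
            0.0 < self.green_R_threshold <= self.amber_R_lower <= self.red_R_threshold
        ):
            raise ConfigError(
                "need 0 < green_R_threshold <= amber_R_lower <= red_R_threshold"
            )
        if self.audio_step_mm <= 0:
            raise ConfigError("audio_step_mm must be positive")
        if self.audio_start_radius <= self.green_R_threshold:
            raise ConfigError("audio_start_radius must exceed green_R_threshold")
        if not (0.0 <= self.haptic_floor_pct <= self.haptic_max_pct <= 100.0):
            raise ConfigError("need 0 <= haptic_floor_pct <= haptic_max_pct <= 100")

    @property
    def audio_max_steps(self) -> int:
        """Number of pitch steps from the start radius down to the green
        boundary (the pitch cap)."""
        return int(
            math.floor(
                (self.audio_start_radius - self.green_R_threshold) / self.audio_step_mm
            )
        )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FeedbackConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown feedback config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "FeedbackConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a key-value mapping")
        return cls.from_mapping(data)


DEFAULT_CONFIG = FeedbackConfig()


def _check_R(R: float) -> None:
    if R < 0 or not math.isfinite(R):
        raise ValueError(f"radial distance must be finite and >= 0, got {R}")


def classify_zone(R: float, alpha: float, cfg: FeedbackConfig = DEFAULT_CONFIG) -> Zone:
    """Traffic-light zone for a radial distance R (mm) and angular
    deviation α (degrees, unsigned).

    Total over R ≥ 0, α ≥ 0: RED if R > red threshold or α > limit;
    GREEN if R ≤ green threshold and α ≤ limit; AMBER otherwise.
    """
    _check_R(R)
    if alpha < 0 or not math.isfinite(alpha):
        raise ValueError(f"alpha must be finite and >= 0, got {alpha}")
    if R > cfg.red_R_threshold or alpha > cfg.alpha_limit:
        return Zone.RED
    if R <= cfg.green_R_threshold:
        return Zone.GREEN
    return Zone.AMBER


def audio_frequency(
    R: float, alpha: float = 0.0, cfg: FeedbackConfig = DEFAULT_CONFIG
) -> float:
    """Beep pitch in Hz for a radial distance R.

    The pitch starts at the base frequency at/beyond the start radius and
    rises by one step per ``audio_step_mm`` of approach, capped at the
    green boundary: with defaults 470 Hz at 20 mm, +25 Hz per mm, maximum
    470 + 25 × 18 = 920 Hz.  Non-increasing in R.
    """
    _check_R(R)
    clamped = min(max(R, 0.0), cfg.audio_start_radius)
    k = int(math.floor((cfg.audio_start_radius - clamped) / cfg.audio_step_mm))
    return cfg.audio_base_hz + cfg.audio_step_hz * min(k, cfg.audio_max_steps)


def haptic_intensity(
    R: float, alpha: float = 0.0, cfg: FeedbackConfig = DEFAULT_CONFIG
) -> float:
    """Vibration waveform intensity in percent for (R, α).

    Linear ramp from ``haptic_max_pct`` at/beyond the start radius down to
    zero at the green boundary; exactly 0% in the green zone ("the
    vibration stops completely") and never below ``haptic_floor_pct``
    otherwise, so a needle at depth with an out-of-limit angle still
    vibrates.  Non-decreasing in R at fixed α.
    """
    zone = classify_zone(R, alpha, cfg)
    if zone is Zone.GREEN:
        return 0.0
    span = cfg.audio_start_radius - cfg.green_R_threshold
    ramp = cfg.haptic_max_pct * min(
        max((R - cfg.green_R_threshold) / span, 0.0), 1.0
    )
    return max(ramp, cfg.haptic_floor_pct)


@dataclass(frozen=True)
class GuidanceState:
    """Everything the feedback channels present at one instant."""

    timestamp: float
    params: GuidanceParameters
    zone: Zone
    audio_hz: Optional[float]
    haptic_pct: float

    def to_record(self) -> dict:
        p = self.params
        return {
            "timestamp": self.timestamp,
            "R_mm": p.radial_distance_R,
            "alpha_deg": p.alpha_deg,
            "DTT_mm": p.depth_to_target_DTT,
            "euclidean_mm": p.euclidean_distance,
            "zone": self.zone.value,
            "audio_hz": self.audio_hz,
            "haptic_pct": self.haptic_pct,
        }


def evaluate(
    params: GuidanceParameters,
    cfg: FeedbackConfig = DEFAULT_CONFIG,
    timestamp: float = 0.0,
) -> GuidanceState:
    """Map guidance parameters to a full feedback state."""
    R, alpha = params.radial_distance_R, params.alpha_deg
    return GuidanceState(
        timestamp=timestamp,
        params=params,
        zone=classify_zone(R, alpha, cfg),
        audio_hz=audio_frequency(R, alpha, cfg),
        haptic_pct=haptic_intensity(R, alpha, cfg),
    )


def guidance_stream(
    log,
    cfg: FeedbackConfig = DEFAULT_CONFIG,
    anatomical: RigidTransform | None = None,
) -> list[GuidanceState]:
    """Evaluate the feedback state over a dual-sensor tracker log.

    Needle and target samples are paired by nearest timestamp within the
    configured tolerance (default: half the log's nominal sample
    interval); unpairable needle samples are skipped with a warning.
    Returns one :class:`GuidanceState` per paired sample, timestamps
    strictly increasing.
    """
    from .tracker_io import SENSOR_NEEDLE, SENSOR_TARGET  # local import: no cycle

    if not log.records:
        return []
    needle_recs = [r for r in log.records if r.sensor_id == SENSOR_NEEDLE]
    target_recs = [r for r in log.records if r.sensor_id == SENSOR_TARGET]
    if not needle_recs or not target_recs:
        raise ValueError(
            "guidance_stream requires both NEEDLE and TARGET sensor records"
        )

    tol = cfg.pairing_tolerance_s
    if tol is None:
        tol = 0.5 / log.nominal_rate_hz

    target_ts = np.array([r.timestamp for r in target_recs])
    states: list[GuidanceState] = []
    last_t = -math.inf
    pending_zone: Optional[Zone] = None
    pending_count = 0
    current_zone: Optional[Zone] = None
    n_skipped = 0

    for rec in needle_recs:
        j = int(np.searchsorted(target_ts, rec.timestamp))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(target_recs):
                gap = abs(target_ts[k] - rec.timestamp)
                if best is None or gap < best[0]:
                    best = (gap, k)
        if best is None or best[0] > tol:
            n_skipped += 1
            continue
        if rec.timestamp <= last_t:
            n_skipped += 1
            continue
        tgt = target_recs[best[1]]
        pose = Pose6DOF(
            np.array([rec.x, rec.y, rec.z]),
            rec.roll,
            rec.pitch,
            rec.yaw,
            frame=log.frame,
            timestamp=rec.timestamp,
        )
        params = guidance_parameters(pose, np.array([tgt.x, tgt.y, tgt.z]), anatomical)
        state = evaluate(params, cfg, timestamp=rec.timestamp)

        if cfg.debounce_samples > 0 and current_zone is not None:
            if state.zone != current_zone:
                if state.zone == pending_zone:
                    pending_count += 1
                else:
                    pending_zone, pending_count = state.zone, 1
                if pending_count >= cfg.debounce_samples:
                    current_zone = state.zone
                else:
                    state = dataclasses.replace(state, zone=current_zone)
            else:
                pending_zone, pending_count = None, 0
        else:
            current_zone = state.zone

        states.append(state)
        last_t = rec.timestamp

    if n_skipped:
        warnings.warn(
            f"guidance_stream: skipped {n_skipped} needle samples without a "
            f"target sample within {tol:.6g} s",
            stacklevel=2,
        )
    return states


def states_to_dataframe(states: Sequence[GuidanceState]) -> pd.DataFrame:
    return pd.DataFrame([s.to_record() for s in states])


def write_states(states: Iterable[GuidanceState], path, dialect: str = "jsonl") -> None:
    """Serialize a guidance stream to JSONL (one state per line) or CSV."""
    path = Path(path)
    if dialect == "jsonl":
        with open(path, "w") as fh:
            for s in states:
                fh.write(json.dumps(s.to_record()) + "\n")
    elif dialect == "csv":
        states_to_dataframe(list(states)).to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'jsonl' or 'csv')")
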