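"""Stochastic simulator of the bench insertion experiment.

The physical study inserted a PDT needle through 25 mm of simulated soft
tissue into a 10 mm-diameter model trachea whose position and tilt were
re-randomized between attempts.  Twenty participants (ten laboratory,
ten hospital staff) each made eight attempts — two with each of four
feedback modalities (palpation only, visual, haptic-visual,
audio-visual) — with a 5-minute abandonment cutoff.  Outcomes were time
to target (first skin puncture to the needle entering the trachea) and
the tip-to-target distance at completion.

This module replaces the human-and-phantom hardware with a behavioural
operator model in the anatomical frame (+Z = insertion direction into
the neck, +Y = cranial, +X = patient-left; skin at z = 0):

* Unguided (palpation) attempts draw a lateral aiming error and insert
  straight along the aimed line with no correction.
* Guided attempts run a discrete-time loop at the operator's reaction
  interval: re-evaluate the feedback state, nudge the trajectory toward
  the target by a proportional correction gain (plus motor noise), and
  advance the needle only while the traffic light is not red.

Operator parameters are a calibrated stand-in for human behaviour, not
ground truth: defaults give an unguided lateral aim SD of ~10 mm per
axis at the 25 mm tissue depth (matching the scale of unguided misses)
and guided attempt durations slower than palpation, with haptic-visual
slowest.  Every attempt emits a tracker log that replays through
:func:`tracheoguide.feedback.guidance_stream` to the same zone sequence
the simulated operator saw.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import feedback as fb
from .geometry import Pose6DOF, axis_to_euler, guidance_parameters
from .tracker_io import SENSOR_NEEDLE, SENSOR_TARGET, TrackerLog, TrackerRecord

__all__ = [
    "MODALITIES",
    "GUIDED_MODALITIES",
    "STAFF_GROUPS",
    "PhantomConfig",
    "PhantomModel",
    "OperatorModel",
    "AttemptOutcome",
    "TrialDesign",
    "TrialDataset",
    "make_phantom",
    "simulate_attempt",
    "simulate_trial",
]

MODALITY_PALPATION = "PALPATION"
MODALITY_VISUAL = "VISUAL"
MODALITY_HAPTIC_VISUAL = "HAPTIC_VISUAL"
MODALITY_AUDIO_VISUAL = "AUDIO_VISUAL"

MODALITIES = (
    MODALITY_PALPATION,
    MODALITY_VISUAL,
    MODALITY_HAPTIC_VISUAL,
    MODALITY_AUDIO_VISUAL,
)
GUIDED_MODALITIES = MODALITIES[1:]
STAFF_GROUPS = ("LABORATORY", "HOSPITAL")

#: Pre-determined abandonment cutoff, seconds.
TIME_LIMIT_S = 300.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry of the bench neck model and its randomization bounds."""

    tissue_depth: float = 25.0  # mm of simulated soft tissue over the trachea
    trachea_diameter: float = 10.0  # mm internal diameter
    max_lateral_offset: float = 15.0  # mm, uniform per-axis target offset bound
    max_tilt_deg: float = 15.0  # deg, uniform tracheal-axis tilt bound

    def __post_init__(self):
        if self.tissue_depth <= 0 or self.trachea_diameter <= 0:
            raise ValueError("tissue_depth and trachea_diameter must be positive")


@dataclass(frozen=True)
class PhantomModel:
    """One concrete randomized phantom: target sensor pose inside the
    trachea.  The target sensor sits on the tracheal long axis at the
    centre of the lumen, i.e. at depth ``tissue_depth + radius``."""

    tissue_depth: float
    trachea_diameter: float
    target_position: np.ndarray  # mm, anatomical frame
    target_axis: np.ndarray  # unit vector, tracheal long axis
    seed: int

    @property
    def trachea_radius(self) -> float:
        return self.trachea_diameter / 2.0

    @property
    def target_depth(self) -> float:
        return float(self.target_position[2])

    def lateral_distance_to_axis(self, point: np.ndarray) -> float:
        """Perpendicular distance of a point from the tracheal long axis."""
        d = np.asarray(point, dtype=float) - self.target_position
        along = float(d @ self.target_axis)
        return float(np.linalg.norm(d - along * self.target_axis))


def make_phantom(
    cfg: PhantomConfig = PhantomConfig(), rng_seed: int | np.random.SeedSequence = 0
) -> PhantomModel:
    """Draw a randomized phantom: target offset uniform within
    ±max_lateral_offset per lateral axis, tracheal axis (nominally +Y,
    cranio-caudal) tilted by independent uniform angles within
    ±max_tilt_deg about +X and +Z.  Deterministic given the seed."""
    rng = np.random.default_rng(rng_seed)
    off = rng.uniform(-cfg.max_lateral_offset, cfg.max_lateral_offset, size=2)
    depth = cfg.tissue_depth + cfg.trachea_diameter / 2.0
    target = np.array([off[0], off[1], depth])

    tilt_x, tilt_z = np.radians(
        rng.uniform(-cfg.max_tilt_deg, cfg.max_tilt_deg, size=2)
    )
    axis = np.array([0.0, 1.0, 0.0])
    rot_x = np.array(
        [
            [1, 0, 0],
            [0, math.cos(tilt_x), -math.sin(tilt_x)],
            [0, math.sin(tilt_x), math.cos(tilt_x)],
        ]
    )
    rot_z = np.array(
        [
            [math.cos(tilt_z), -math.sin(tilt_z), 0],
            [math.sin(tilt_z), math.cos(tilt_z), 0],
            [0, 0, 1],
        ]
    )
    axis = rot_z @ rot_x @ axis
    axis /= np.linalg.norm(axis)

    seed_repr = rng_seed if isinstance(rng_seed, int) else -1
    return PhantomModel(
        tissue_depth=cfg.tissue_depth,
        trachea_diameter=cfg.trachea_diameter,
        target_position=target,
        target_axis=axis,
        seed=seed_repr,
    )


@dataclass(frozen=True)
class OperatorModel:
    """Behavioural stand-in for a human participant.

    ``aim_error_sd`` is the per-axis SD (mm) of the unguided lateral
    aiming error at target depth; ``angle_error_sd`` tilts the insertion
    direction.  Guided behaviour: every ``reaction_time`` seconds the
    operator applies a proportional correction of ``correction_gain`` ×
    the current lateral error (plus ``correction_noise_sd`` motor noise)
    and advances only while the zone is not red, at
    ``insertion_speed × guided_speed_factor``.  ``modality_time_factor``
    scales the reaction interval and slows the advance rate per modality
    (haptic-visual slowest by default, matching the observed ordering of
    attempt durations).  A missed unguided pass is re-inserted with probability
    ``reinsertion_probability`` (with a time penalty), up to
    ``max_insertions`` passes.
    """

    aim_error_sd: float = 10.0  # mm per lateral axis, unguided
    angle_error_sd: float = 4.0  # deg
    correction_gain: float = 0.25  # fraction of lateral error per update
    correction_noise_sd: float = 0.4  # mm per update
    reaction_time: float = 1.5  # s per guided update
    insertion_speed: float = 0.7  # mm/s, unguided advance rate
    guided_speed_factor: float = 0.5  # cautious advance under guidance
    reinsertion_probability: float = 0.25
    reinsertion_penalty_s: float = 10.0
    max_insertions: int = 3
    modality_time_factor: dict = field(
        default_factory=lambda: {
            MODALITY_VISUAL: 1.0,
            MODALITY_AUDIO_VISUAL: 0.95,
            MODALITY_HAPTIC_VISUAL: 1.35,
        }
    )

    def __post_init__(self):
        if not (0.0 <= self.correction_gain <= 1.0):
            raise ValueError("correction_gain must lie in [0, 1]")
        for name in (
            "aim_error_sd",
            "angle_error_sd",
            "correction_noise_sd",
            "reaction_time",
            "insertion_speed",
            "reinsertion_probability",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, aim_factor: float = 1.0, time_factor: float = 1.0) -> "OperatorModel":
        """A copy with aiming error and tempo scaled (participant/group
        heterogeneity)."""
        return dataclasses.replace(
            self,
            aim_error_sd=self.aim_error_sd * aim_factor,
            angle_error_sd=self.angle_error_sd * aim_factor,
            reaction_time=self.reaction_time * time_factor,
            insertion_speed=self.insertion_speed / time_factor,
        )


@dataclass(frozen=True)
class AttemptOutcome:
    """Metrics of one insertion attempt."""

    participant_id: str
    staff_group: str
    modality: str
    time_to_target: float  # s
    final_radial_distance: float  # mm, Euclidean tip-to-target at completion
    final_lateral_distance: float  # mm, perpendicular miss from the needle line
    n_insertions: int
    abandoned: bool
    entered_trachea: bool
    order_index: int  # 1..8 within a participant's session

    def __post_init__(self):
        if self.final_radial_distance < 0 or self.n_insertions < 1:
            raise ValueError("invalid outcome metrics")
        if not self.abandoned and self.time_to_target > TIME_LIMIT_S + 1e-9:
            raise ValueError("time_to_target exceeds cutoff on a completed attempt")


@dataclass(frozen=True)
class TrialDesign:
    """The crossover study design: participants per staff group, attempts
    per modality, modality set and per-participant order randomization."""

    n_participants_per_group: int = 10
    attempts_per_modality: int = 2
    modalities: tuple = MODALITIES
    randomize_order: bool = True
    groups: tuple = STAFF_GROUPS

    def __post_init__(self):
        if self.n_participants_per_group < 1 or self.attempts_per_modality < 1:
            raise ValueError("design counts must be positive")
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}")

    @property
    def attempts_per_participant(self) -> int:
        return len(self.modalities) * self.attempts_per_modality


@dataclass
class TrialDataset:
    """Attempt outcomes labelled by participant, group, modality, order."""

    outcomes: list[AttemptOutcome]
    design: TrialDesign
    master_seed: int
    logs: Optional[list[TrackerLog]] = None  # parallel to outcomes when kept

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(o) for o in self.outcomes])
        df["guided"] = df["modality"] != MODALITY_PALPATION
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def _child_seed(master_seed: int, *indices: int) -> np.random.SeedSequence:
    """Documented counter scheme: child streams are keyed by
    (master_seed, index, ...) through :class:`numpy.random.SeedSequence`."""
    return np.random.SeedSequence([int(master_seed), *map(int, indices)])


def _needle_record(t: float, tip: np.ndarray, axis: np.ndarray) -> TrackerRecord:
    roll, pitch, yaw = axis_to_euler(axis)
    return TrackerRecord(
        timestamp=round(t, 6),
        sensor_id=SENSOR_NEEDLE,
        x=round(float(tip[0]), 6),
        y=round(float(tip[1]), 6),
        z=round(float(tip[2]), 6),
        roll=round(roll, 6),
        pitch=round(pitch, 6),
        yaw=round(yaw, 6),
    )


def _target_record(t: float, phantom: PhantomModel) -> TrackerRecord:
    roll, pitch, yaw = axis_to_euler(phantom.target_axis)
    p = phantom.target_position
    return TrackerRecord(
        timestamp=round(t, 6),
        sensor_id=SENSOR_TARGET,
        x=round(float(p[0]), 6),
        y=round(float(p[1]), 6),
        z=round(float(p[2]), 6),
        roll=round(roll, 6),
        pitch=round(pitch, 6),
        yaw=round(yaw, 6),
    )


def _state_from_records(
    needle_rec: TrackerRecord, target_rec: TrackerRecord, feedback_cfg: fb.FeedbackConfig
) -> fb.GuidanceState:
    # Evaluate feedback through the exact record round-trip the replay path
    # uses, so streamed zones reproduce the simulated ones bit-for-bit.
    pose = Pose6DOF(
        np.array([needle_rec.x, needle_rec.y, needle_rec.z]),
        needle_rec.roll,
        needle_rec.pitch,
        needle_rec.yaw,
        timestamp=needle_rec.timestamp,
    )
    params = guidance_parameters(
        pose, np.array([target_rec.x, target_rec.y, target_rec.z])
    )
    return fb.evaluate(params, feedback_cfg, timestamp=needle_rec.timestamp)


def simulate_attempt(
    phantom: PhantomModel,
    operator: OperatorModel,
    modality: str,
    feedback_cfg: fb.FeedbackConfig = fb.DEFAULT_CONFIG,
    rng_seed: int | np.random.SeedSequence = 0,
    participant_id: str = "P00",
    staff_group: str = "LABORATORY",
    order_index: int = 1,
) -> tuple[AttemptOutcome, TrackerLog]:
    """Simulate one insertion attempt; returns the outcome and a replayable
    tracker log (one needle/target record pair per operator update).

    The attempt completes when the tip reaches the target's depth plane
    (the bronchoscope view confirms entry or miss there) and is abandoned
    at the 5-minute cutoff.  ``entered_trachea`` records whether the tip
    finished inside the tracheal lumen cylinder.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r} (expected one of {MODALITIES})")
    rng = np.random.default_rng(rng_seed)
    guided = modality != MODALITY_PALPATION
    depth = phantom.target_depth
    target_xy = phantom.target_position[:2]

    time_factor = operator.modality_time_factor.get(modality, 1.0) if guided else 1.0
    dt = operator.reaction_time * time_factor
    speed = operator.insertion_speed * (
        operator.guided_speed_factor / time_factor if guided else 1.0
    )

    records: list[TrackerRecord] = []
    t = 0.0
    n_insertions = 1
    abandoned = False
    entered = False

    def new_pass():
        aim_err = rng.normal(0.0, operator.aim_error_sd, size=2)
        tilt = np.tan(np.radians(rng.normal(0.0, operator.angle_error_sd, size=2)))
        tip = np.array([target_xy[0] + aim_err[0], target_xy[1] + aim_err[1], 0.0])
        heading = tip[:2] + depth * tilt  # aimed lateral position at target depth
        return tip, heading

    tip, heading = new_pass()

    while True:
        to_go = depth - tip[2]
        axis = np.array([heading[0] - tip[0], heading[1] - tip[1], max(to_go, 1e-6)])
        axis /= np.linalg.norm(axis)

        needle_rec = _needle_record(t, tip, axis)
        target_rec = _target_record(t, phantom)
        records.extend([needle_rec, target_rec])
        state = _state_from_records(needle_rec, target_rec, feedback_cfg)

        if not entered and phantom.lateral_distance_to_axis(tip) <= phantom.trachea_radius:
            # Tip has crossed the tracheal wall: success is confirmed on the
            # bronchoscope view; the operator advances to the target without
            # further feedback-driven corrections.
            entered = True

        if tip[2] >= depth - 1e-9:
            # Completion: tip has reached the target's depth plane.
            if (
                not entered
                and n_insertions < operator.max_insertions
                and rng.random() < operator.reinsertion_probability
                and t + operator.reinsertion_penalty_s < TIME_LIMIT_S
            ):
                # The operator notices the miss (no air aspirated / still in
                # the red), withdraws completely and re-inserts afresh.
                n_insertions += 1
                t += operator.reinsertion_penalty_s
                tip, heading = new_pass()
                continue
            break

        if t + dt > TIME_LIMIT_S:
            abandoned = True
            t = TIME_LIMIT_S
            break

        if guided and not entered:
            # Two corrective controls, both proportional with motor noise:
            # (1) re-aim the shaft toward the target, never steeper than the
            # angle limit allows (deep, the trajectory goes near-vertical
            # and residual lateral error is accepted); (2) walk the puncture
            # site toward the target where the tissue still permits lateral
            # repositioning (the `shallow` factor fades this out with depth).
            want = target_xy - tip[:2]
            want_norm = float(np.linalg.norm(want))
            aim_max = to_go * math.tan(math.radians(0.8 * feedback_cfg.alpha_limit))
            if want_norm > aim_max:
                want = want * (aim_max / want_norm)
            slant = heading - tip[:2]
            slant = (
                slant
                + operator.correction_gain * (want - slant)
                + rng.normal(0.0, operator.correction_noise_sd, size=2)
            )
            slant_norm = float(np.linalg.norm(slant))
            slant_max = to_go * math.tan(math.radians(1.2 * feedback_cfg.alpha_limit))
            if slant_norm > slant_max:
                slant = slant * (slant_max / slant_norm)

            shallow = 1.0 - tip[2] / depth
            walk = shallow * (
                operator.correction_gain * (target_xy - tip[:2])
                + rng.normal(0.0, operator.correction_noise_sd, size=2)
            )
            tip = tip + np.append(walk, 0.0)
            heading = tip[:2] + slant

        if (not guided) or entered or state.zone is not fb.Zone.RED:
            step = min(speed * dt, depth - tip[2])
            tip = tip + axis * (step / axis[2])
        elif tip[2] > 0.0:
            # Blocked deep on a red light: the operator partially withdraws
            # along the shaft to re-correct where the tissue still permits
            # lateral repositioning.
            step = min(speed * dt, tip[2])
            tip = tip - axis * (step / axis[2])
        t += dt

    final_euclid = float(np.linalg.norm(tip - phantom.target_position))
    final_params = guidance_parameters(
        Pose6DOF(tip, *axis_to_euler(axis)), phantom.target_position
    )

    outcome = AttemptOutcome(
        participant_id=participant_id,
        staff_group=staff_group,
        modality=modality,
        time_to_target=round(t, 6),
        final_radial_distance=round(final_euclid, 6),
        final_lateral_distance=round(final_params.radial_distance_R, 6),
        n_insertions=n_insertions,
        abandoned=abandoned,
        entered_trachea=bool(entered and not abandoned),
        order_index=order_index,
    )
    log = TrackerLog(
        records=records,
        nominal_rate_hz=1.0 / dt,
        provenance=(
            f"simulated attempt participant={participant_id} modality={modality}"
        ),
    )
    return outcome, log


#: Mild group-level tempo/accuracy advantage for experienced hospital staff
#: (the bench study found small, non-significant differences).
_GROUP_FACTORS = {
    "LABORATORY": {"aim": 1.0, "time": 1.0},
    "HOSPITAL": {"aim": 0.95, "time": 0.82},
}


def simulate_trial(
    design: TrialDesign = TrialDesign(),
    operator: OperatorModel = OperatorModel(),
    phantom_cfg: PhantomConfig = PhantomConfig(),
    feedback_cfg: fb.FeedbackConfig = fb.DEFAULT_CONFIG,
    master_seed: int = 0,
    keep_logs: bool = False,
) -> TrialDataset:
    """Run the full crossover trial: every participant performs
    ``attempts_per_modality`` attempts with each modality, order
    randomized per participant, phantom re-randomized before every
    attempt.  Fully deterministic given ``master_seed``."""
    outcomes: list[AttemptOutcome] = []
    logs: list[TrackerLog] = [] if keep_logs else None

    p_index = 0
    for group in design.groups:
        for i in range(design.n_participants_per_group):
            pid = f"{group[0]}{i + 1:02d}"
            p_rng = np.random.default_rng(_child_seed(master_seed, p_index, 0))
            gf = _GROUP_FACTORS.get(group, {"aim": 1.0, "time": 1.0})
            # Participant heterogeneity: lognormal multipliers on accuracy/tempo.
            op = operator.scaled(
                aim_factor=gf["aim"] * float(np.exp(p_rng.normal(0.0, 0.15))),
                time_factor=gf["time"] * float(np.exp(p_rng.normal(0.0, 0.15))),
            )
            schedule = [
                m for m in design.modalities for _ in range(design.attempts_per_modality)
            ]
            if design.randomize_order:
                schedule = [schedule[k] for k in p_rng.permutation(len(schedule))]
            for a_index, modality in enumerate(schedule):
                phantom = make_phantom(
                    phantom_cfg, _child_seed(master_seed, p_index, a_index + 1, 0)
                )
                outcome, log = simulate_attempt(
                    phantom,
                    op,
                    modality,
                    feedback_cfg,
                    rng_seed=_child_seed(master_seed, p_index, a_index + 1, 1),
                    participant_id=pid,
                    staff_group=group,
                    order_index=a_index + 1,
                )
                outcomes.append(outcome)
                if keep_logs:
                    logs.append(log)
            p_index += 1

    return TrialDataset(
        outcomes=outcomes, design=design, master_seed=int(master_seed), logs=logs
    )
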