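"""Policy rollouts in an isolated evaluation environment and the
approach/synchronization stage analysis.

A learned cooperative policy typically shows two stages: an approach
stage in which the back swimmer strokes toward the (mostly waiting) front
swimmer, shrinking the gap d, followed by a synchronization stage in
which both swimmers run phase-locked strokes and d oscillates with the
4-step gait period.  The transition is detected from the step pattern of
(configuration, quantized change of d): the synchronization stage begins
where that pattern first repeats with period 4 for a required number of
gait cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import SwimmerPairEnv, encode_observation
from .ppo import ActorCritic, Checkpoint, select_action
from .trajectory import Trajectory, TrajectoryBuilder

GAIT_PERIOD = 4
#: dead-band below which a per-step change of d counts as zero
DELTA_D_DEADBAND = 1e-6


def rollout_policy(
    policy,
    env: SwimmerPairEnv,
    mode: str = "stochastic",
    steps: int = 2000,
    seed: int = 0,
    initial_state=None,
) -> Trajectory:
    """Run a policy without learning and record the full trajectory.

    ``policy`` may be an :class:`ActorCritic`, a :class:`Checkpoint`, or
    any callable mapping an encoded observation to an action index.
    Environment termination ends the rollout and is recorded, not raised.
    ``initial_state`` overrides the randomized reset (e.g. both swimmers
    fully extended at a chosen gap).
    """
    if isinstance(policy, Checkpoint):
        policy = policy.policy()
    rng = np.random.default_rng(seed)
    if initial_state is not None:
        obs = env.set_state(initial_state)
    else:
        obs, _ = env.reset(seed=seed)
    builder = TrajectoryBuilder()
    for n in range(steps):
        x = encode_observation(obs, env.reward_spec)
        if isinstance(policy, ActorCritic):
            a, _ = select_action(policy, x, mode, rng)
        else:
            a = int(policy(x))
        obs, reward, terminated, truncated, info = env.step(a)
        builder.append(
            step=n,
            action=a,
            reward=reward,
            x=env.state.x,
            d_b_step=info["D_B"],
            d_f_step=info["D_F"],
        )
        if terminated or truncated:
            break
    return builder.build()


@dataclass
class StageReport:
    """Where a trajectory switches from approach to synchronization."""

    transition_step: int | None
    pattern_period: int
    approach_speed_back: float | None
    approach_speed_front: float | None
    sync_speed_back: float | None
    sync_speed_front: float | None

    @property
    def has_transition(self) -> bool:
        return self.transition_step is not None


def _slope(y: np.ndarray) -> float | None:
    if len(y) < 2:
        return None
    t = np.arange(len(y), dtype=float)
    return float(np.polyfit(t, y, 1)[0])


def _step_patterns(traj: Trajectory) -> np.ndarray:
    """Per-step discrete pattern: the 4 arm bits after the step plus the
    sign of the step's change in d (with a dead-band)."""
    bits = traj.config_bits().astype(np.int8)
    dd = np.diff(traj.d, prepend=traj.d[0])
    # the change of d during the first step is unobservable (no prior d is
    # recorded); backfill it from the same phase one gait period later so a
    # trajectory that is periodic from the start is detected as such
    if len(traj) > GAIT_PERIOD:
        dd[0] = dd[GAIT_PERIOD]
    sign = np.where(np.abs(dd) <= DELTA_D_DEADBAND, 0, np.sign(dd)).astype(np.int8)
    return np.column_stack([bits, sign])


def detect_stage_transition(
    traj: Trajectory,
    cycles_required: int = 5,
    mismatch_tolerance: int = 0,
) -> StageReport:
    """Earliest step from which the step pattern of (configuration,
    quantized delta-d) is 4-periodic for ``cycles_required`` consecutive
    gait cycles.  ``mismatch_tolerance`` allows that many deviating steps
    per window (for stochastic rollouts)."""
    window = GAIT_PERIOD * cycles_required
    if len(traj) < window:
        raise ValueError(
            f"trajectory of {len(traj)} steps is shorter than "
            f"{cycles_required} gait cycles"
        )
    pat = _step_patterns(traj)
    T = len(traj)
    transition = None
    for t in range(0, T - window + 1):
        seg = pat[t : t + window]
        mismatches = int((seg[GAIT_PERIOD:] != seg[:-GAIT_PERIOD]).any(axis=1).sum())
        if mismatches <= mismatch_tolerance:
            transition = t
            break
    if transition is None:
        return StageReport(None, GAIT_PERIOD, _slope(traj.D_B), _slope(traj.D_F), None, None)
    return StageReport(
        transition_step=transition,
        pattern_period=GAIT_PERIOD,
        approach_speed_back=_slope(traj.D_B[:transition]),
        approach_speed_front=_slope(traj.D_F[:transition]),
        sync_speed_back=_slope(traj.D_B[transition:]),
        sync_speed_front=_slope(traj.D_F[transition:]),
    )


def trajectory_metrics(traj: Trajectory, stage_report: StageReport | None = None) -> dict:
    """Deterministic summary of a rollout.

    Includes overall and per-stage speeds (least-squares slopes of the
    cumulative displacements), the range of d, per-step reward statistics,
    and the order of magnitude of the mean per-step pair displacement
    |D_F + D_B|.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    step_pair_disp = np.diff(traj.D_B + traj.D_F, prepend=0.0)
    # cumulative arrays start after the first step, so prepend=0 gives the
    # true per-step increments
    mean_abs = float(np.abs(step_pair_disp).mean())
    out = {
        "n_steps": int(len(traj)),
        "speed_back": _slope(traj.D_B),
        "speed_front": _slope(traj.D_F),
        "speed_avg": _slope(traj.avg_displacement),
        "min_d": float(traj.d.min()),
        "max_d": float(traj.d.max()),
        "reward_mean": float(traj.reward.mean()),
        "reward_min": float(traj.reward.min()),
        "reward_max": float(traj.reward.max()),
        "mean_abs_pair_step_displacement": mean_abs,
        "pair_step_displacement_magnitude": float(np.log10(mean_abs))
        if mean_abs > 0
        else None,
    }
    if stage_report is not None:
        out.update(
            {
                "transition_step": stage_report.transition_step,
                "approach_speed_back": stage_report.approach_speed_back,
                "approach_speed_front": stage_report.approach_speed_front,
                "sync_speed_back": stage_report.sync_speed_back,
                "sync_speed_front": stage_report.sync_speed_front,
            }
        )
    return out
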