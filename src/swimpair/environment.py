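"""Markov decision process for the cooperating swimmer pair.

The agent controls both swimmers jointly.  It observes the four arm bits
(16 discrete configurations) plus the continuous gap ``d`` between the
swimmers, and picks one of 8 joint actions: each swimmer toggles its rear
arm, toggles its front arm, or holds, with the double-hold excluded.

The reward is the summed centroid displacement of the two swimmers while
``d`` stays in the productive band [d_soft, d_upper); a soft penalty
applies in the buffer zone (d_lower, d_soft), and the episode terminates
with a hard penalty when the swimmers get too close (d <= d_lower) or
drift too far apart (d >= d_upper).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .hydro import (
    ARM_CONTRACTED,
    ARM_EXTENDED,
    GeometryError,
    HydroParams,
    SimState,
    _integrate_kernel,
)


class ArmChoice(IntEnum):
    """Per-swimmer action: toggle one of the two arms, or hold."""

    TOGGLE_REAR = 0
    TOGGLE_FRONT = 1
    HOLD = 2


@dataclass(frozen=True)
class JointAction:
    back: ArmChoice
    front: ArmChoice

    def __post_init__(self) -> None:
        if self.back == ArmChoice.HOLD and self.front == ArmChoice.HOLD:
            raise ValueError("double hold is not a legal joint action")

    @property
    def arm_indices(self) -> tuple[int, ...]:
        """Global arm indices (0-3) toggled by this action."""
        idx = []
        if self.back != ArmChoice.HOLD:
            idx.append(int(self.back))
        if self.front != ArmChoice.HOLD:
            idx.append(2 + int(self.front))
        return tuple(idx)


def enumerate_joint_actions() -> list[JointAction]:
    """All 8 legal joint actions in a stable order (back choice major,
    front choice minor, double-hold excluded)."""
    actions = []
    for back in ArmChoice:
        for front in ArmChoice:
            if back == ArmChoice.HOLD and front == ArmChoice.HOLD:
                continue
            actions.append(JointAction(back, front))
    return actions


JOINT_ACTIONS = enumerate_joint_actions()
N_ACTIONS = len(JOINT_ACTIONS)
N_CONFIGURATIONS = 16


@dataclass(frozen=True)
class Observation:
    """What the agent sees: 4 arm bits plus the continuous gap d."""

    arm_bits: tuple[bool, bool, bool, bool]
    d: float


@dataclass
class RewardSpec:
    """Distance bounds and penalties of the piecewise reward."""

    d_lower: float = 5.0
    d_soft: float = 6.0
    d_upper: float = 70.0
    r_soft: float = -0.3
    r_terminate: float = -1.0

    def __post_init__(self) -> None:
        if not (self.d_lower < self.d_soft < self.d_upper):
            raise ValueError("need d_lower < d_soft < d_upper")
        if not (self.r_terminate < self.r_soft < 0):
            raise ValueError("need r_terminate < r_soft < 0")


@dataclass
class EpisodeSpec:
    """Episode length cap and randomized-initialization distributions."""

    max_steps: int = 16_384
    d_initial_range: tuple[float, float] = (10.0, 40.0)

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        lo, hi = self.d_initial_range
        if not (lo < hi):
            raise ValueError("d_initial_range must be a nonempty interval")


def encode_observation(obs: Observation, reward_spec: RewardSpec) -> np.ndarray:
    """Fixed-length feature vector for the networks: the 4 arm bits as
    0/1 followed by d rescaled by d_upper."""
    return np.array(
        [*(1.0 if b else 0.0 for b in obs.arm_bits), obs.d / reward_spec.d_upper]
    )


OBS_DIM = 5


class SwimmerPairEnv:
    """Episodic environment with a gymnasium-style reset/step interface.

    ``step`` accepts either a :class:`JointAction` or its index into
    :data:`JOINT_ACTIONS` and returns
    ``(observation, reward, terminated, truncated, info)``.
    """

    def __init__(
        self,
        hydro_params: HydroParams | None = None,
        reward_spec: RewardSpec | None = None,
        episode_spec: EpisodeSpec | None = None,
        seed: int | None = None,
    ) -> None:
        self.hydro_params = hydro_params or HydroParams()
        self.reward_spec = reward_spec or RewardSpec()
        self.episode_spec = episode_spec or EpisodeSpec()
        lo, hi = self.episode_spec.d_initial_range
        if not (self.reward_spec.d_soft < lo and hi < self.reward_spec.d_upper):
            raise ValueError("d_initial_range must lie inside (d_soft, d_upper)")
        self._rng = np.random.default_rng(seed)
        self._x: np.ndarray | None = None
        self._bits: np.ndarray | None = None
        self._step_count = 0

    # -- state access -----------------------------------------------------

    @property
    def state(self) -> SimState:
        if self._x is None:
            raise RuntimeError("environment not reset")
        return SimState(x=self._x.copy(), arm_bits=self._bits.copy())

    def set_state(self, state: SimState) -> Observation:
        """Place the environment in an explicit state (e.g. for policy
        evaluation from a prescribed initial condition)."""
        state.validate(at_rest=True)
        self._x = state.x.copy()
        self._bits = state.arm_bits.copy()
        self._step_count = 0
        return self._observation()

    def _observation(self) -> Observation:
        return Observation(
            arm_bits=tuple(bool(b) for b in self._bits),
            d=float(self._x[3] - self._x[2]),
        )

    # -- episodic interface ----------------------------------------------

    def reset(self, seed: int | None = None) -> tuple[Observation, dict]:
        """Sample a uniform arm configuration and an initial gap d from
        the configured interval; the back swimmer's centroid starts at the
        origin."""
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        config = int(self._rng.integers(N_CONFIGURATIONS))
        bits = [(config >> i) & 1 == 1 for i in range(4)]
        lo, hi = self.episode_spec.d_initial_range
        d0 = float(self._rng.uniform(lo, hi))
        state = SimState.from_bits(bits, d=d0, back_centroid=0.0)
        obs = self.set_state(state)
        return obs, {"d_initial": d0, "configuration": config}

    def step(
        self, action: JointAction | int
    ) -> tuple[Observation, float, bool, bool, dict]:
        if self._x is None:
            raise RuntimeError("environment not reset")
        if not isinstance(action, JointAction):
            action = JOINT_ACTIONS[int(action)]
        dL = np.zeros(4)
        lengths = np.array(
            [
                self._x[1] - self._x[0],
                self._x[2] - self._x[1],
                self._x[4] - self._x[3],
                self._x[5] - self._x[4],
            ]
        )
        for i in action.arm_indices:
            target = ARM_CONTRACTED if self._bits[i] else ARM_EXTENDED
            dL[i] = target - lengths[i]
        x_new, status = _integrate_kernel(
            self._x,
            dL,
            self.hydro_params.viscosity,
            self.hydro_params.sphere_radius,
            self.hydro_params.substeps,
        )
        self._step_count += 1
        spec = self.reward_spec
        if status != 0:
            # spheres touched mid-step: physically a collision, treated as
            # crossing the hard lower bound
            info = {"collision": True, "D_B": 0.0, "D_F": 0.0, "d": float("nan")}
            return self._observation(), spec.r_terminate, True, False, info
        disp = x_new - self._x
        self._x = x_new
        for i in action.arm_indices:
            self._bits[i] = not self._bits[i]
        d = float(x_new[3] - x_new[2])
        D_B = float(disp[:3].mean())
        D_F = float(disp[3:].mean())
        terminated = False
        if d <= spec.d_lower or d >= spec.d_upper:
            reward = spec.r_terminate
            terminated = True
        elif d < spec.d_soft:
            reward = spec.r_soft
        else:
            reward = D_B + D_F
        truncated = (not terminated) and self._step_count >= self.episode_spec.max_steps
        info = {"D_B": D_B, "D_F": D_F, "d": d, "collision": False}
        return self._observation(), reward, terminated, truncated, info
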