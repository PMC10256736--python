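"""Prescribed-gait benchmarks: the canonical four-step stroke, the
single-swimmer baseline, and the phase-mismatch sweep for the swimmer
pair.

The canonical stroke cycles an isolated swimmer through its four arm
configurations (rear contract, front contract, rear extend, front
extend), producing strictly positive net propulsion toward +x.  For the
pair benchmarks the back swimmer runs the canonical cycle and the front
swimmer runs the same cycle delayed by 0-3 actuation steps; for a fair
comparison across delays, each case's initial gap is calibrated so the
steady-cycle minimum of the swimmer distance d equals a common target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hydro
from .environment import ArmChoice, JOINT_ACTIONS, JointAction
from .hydro import (
    GeometryError,
    HydroParams,
    NG_CYCLE_BITS,
    NG_TOGGLE_CYCLE,
    SimState,
)
from .trajectory import Trajectory, TrajectoryBuilder

GAIT_PERIOD = 4


@dataclass(frozen=True)
class StrokeSequence:
    """The canonical cycle rotated by a phase offset (in actuation
    steps)."""

    phase_delay: int

    @property
    def toggles(self) -> tuple[int, ...]:
        """Arm index (0 = rear, 1 = front) toggled at steps 0..3 of the
        rotated cycle."""
        dl = self.phase_delay % GAIT_PERIOD
        return tuple(NG_TOGGLE_CYCLE[(k + dl) % GAIT_PERIOD] for k in range(GAIT_PERIOD))

    @property
    def start_bits(self) -> tuple[bool, bool]:
        """Arm configuration the swimmer must hold at step 0."""
        return NG_CYCLE_BITS[self.phase_delay % GAIT_PERIOD]

    def toggle_at(self, step: int) -> int:
        """Toggle for the given actuation step: the canonical cycle with
        the swimmer's stroke phase offset by ``phase_delay`` steps within
        the 4-periodic cycle (offset orientation chosen so that a 1-step
        mismatch of the front swimmer is the cooperative gait)."""
        return NG_TOGGLE_CYCLE[(step + self.phase_delay) % GAIT_PERIOD]


def ng_stroke_sequence(phase_delay: int = 0) -> StrokeSequence:
    if phase_delay < 0:
        raise ValueError("phase_delay must be >= 0")
    return StrokeSequence(phase_delay=phase_delay % GAIT_PERIOD)


def _steady_speed(avg_disp: np.ndarray, tail_steps: int) -> float:
    """Least-squares slope (displacement per step) over the final
    ``tail_steps`` entries of a cumulative displacement curve."""
    y = avg_disp[-tail_steps:]
    t = np.arange(len(y), dtype=float)
    return float(np.polyfit(t, y, 1)[0])


@dataclass
class BaselineResult:
    curve: np.ndarray  # cumulative centroid displacement per step
    speed: float       # displacement per actuation step
    cycle_displacement: float


def single_swimmer_baseline(
    cycles: int = 50, params: HydroParams | None = None
) -> BaselineResult:
    """Cumulative displacement and per-step speed of one isolated swimmer
    running the canonical stroke.  With no partner the speed is exactly
    periodic, so the per-step speed is the per-cycle displacement / 4."""
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    params = params or HydroParams()
    seq = ng_stroke_sequence(0)
    x = hydro.single_swimmer_positions(seq.start_bits)
    bits = list(seq.start_bits)
    start = x.mean()
    curve = np.empty(GAIT_PERIOD * cycles)
    for n in range(curve.size):
        x, bits = hydro.integrate_single_swimmer_step(x, bits, seq.toggle_at(n), params)
        curve[n] = x.mean() - start
    cycle_disp = curve[-1] - (curve[-1 - GAIT_PERIOD] if cycles > 1 else 0.0)
    return BaselineResult(
        curve=curve, speed=cycle_disp / GAIT_PERIOD, cycle_displacement=cycle_disp
    )


def _pair_action(back_arm: int, front_arm: int) -> int:
    """Index into JOINT_ACTIONS for simultaneous toggles of one arm per
    swimmer."""
    act = JointAction(ArmChoice(back_arm), ArmChoice(front_arm))
    return JOINT_ACTIONS.index(act)


def prescribed_pair_rollout(
    delay: int,
    initial_d: float,
    cycles: int,
    params: HydroParams | None = None,
) -> Trajectory:
    """Simulate the pair with both swimmers on the canonical stroke, the
    front swimmer delayed by ``delay`` actuation steps, starting from the
    phase-consistent resting configuration at gap ``initial_d``."""
    if delay not in (0, 1, 2, 3):
        raise ValueError("delay must be one of 0, 1, 2, 3")
    params = params or HydroParams()
    back = ng_stroke_sequence(0)
    front = ng_stroke_sequence(delay)
    bits = np.array([*back.start_bits, *front.start_bits], dtype=bool)
    state = SimState.from_bits(bits, d=initial_d)
    x = state.x.copy()
    builder = TrajectoryBuilder()
    for n in range(GAIT_PERIOD * cycles):
        ba = back.toggle_at(n)
        fa = front.toggle_at(n)
        dL = np.zeros(4)
        for arm, sphere0 in ((ba, 0), (2 + fa, 3)):
            target = hydro.ARM_CONTRACTED if bits[arm] else hydro.ARM_EXTENDED
            cur = x[sphere0 + (arm % 2) + 1] - x[sphere0 + (arm % 2)]
            dL[arm] = target - cur
        x_new, status = hydro._integrate_kernel(
            x, dL, params.viscosity, params.sphere_radius, params.substeps
        )
        if status != 0:
            raise GeometryError(
                f"sphere contact in pair rollout (delay {delay}, d0 {initial_d})"
            )
        bits[ba] = not bits[ba]
        bits[2 + fa] = not bits[2 + fa]
        disp = x_new - x
        x = x_new
        d_b = float(disp[:3].mean())
        d_f = float(disp[3:].mean())
        builder.append(
            step=n,
            action=_pair_action(ba, fa),
            reward=d_b + d_f,
            x=x,
            d_b_step=d_b,
            d_f_step=d_f,
        )
    return builder.build()


@dataclass
class CalibrationResult:
    initial_d: float
    achieved_min_d: float
    drift_per_cycle: float
    iterations: int


def calibrate_initial_distance(
    delay: int,
    target_min_d: float = 6.0,
    params: HydroParams | None = None,
    transient_cycles: int = 10,
    bracket: tuple[float, float] = (3.0, 40.0),
    tol: float = 1e-4,
    max_iter: int = 60,
) -> CalibrationResult:
    """Bisection on the initial gap so that, after the transient, the
    minimum of d over one full gait cycle equals ``target_min_d``.

    The objective (steady-cycle min d as a function of the initial gap) is
    monotone increasing over the bracket.  ``drift_per_cycle`` reports the
    residual change of the cycle minimum between the two cycles after the
    transient (secular drift diagnostic).
    """
    params = params or HydroParams()

    def steady_min(d0: float) -> tuple[float, float]:
        traj = prescribed_pair_rollout(delay, d0, transient_cycles + 2, params)
        d = traj.d
        m1 = d[GAIT_PERIOD * transient_cycles : GAIT_PERIOD * (transient_cycles + 1)].min()
        m2 = d[GAIT_PERIOD * (transient_cycles + 1) :].min()
        return float(m1), float(m2 - m1)

    lo, hi = bracket
    f_lo, _ = steady_min(lo)
    f_hi, _ = steady_min(hi)
    if not (f_lo < target_min_d < f_hi):
        raise ValueError(
            f"target min d {target_min_d} not bracketed by "
            f"[{f_lo:.3f}, {f_hi:.3f}] for delay {delay}"
        )
    mid, f_mid, drift = lo, f_lo, 0.0
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid, drift = steady_min(mid)
        if abs(f_mid - target_min_d) < tol:
            return CalibrationResult(mid, f_mid, drift, it)
        if f_mid < target_min_d:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge for delay {delay}: "
        f"last min d {f_mid:.6f} (target {target_min_d})"
    )


@dataclass
class SweepResult:
    """Phase-sweep comparison against the single-swimmer baseline."""

    table: pd.DataFrame
    baseline: BaselineResult
    curves: dict = field(default_factory=dict)

    @property
    def best_delay(self) -> int:
        return int(self.table.loc[self.table["speed"].idxmax(), "delay"])

    @property
    def best_improvement_percent(self) -> float:
        return float(self.table["improvement_percent"].max())


def phase_sweep(
    delays=(0, 1, 2, 3),
    target_min_d: float = 6.0,
    cycles: int = 50,
    params: HydroParams | None = None,
    measure_cycles: int = 20,
) -> SweepResult:
    """Calibrate and simulate each phase delay, measure steady speeds from
    the final ``measure_cycles`` gait cycles, and compare with the
    single-swimmer baseline."""
    params = params or HydroParams()
    baseline = single_swimmer_baseline(cycles, params)
    rows = []
    curves = {}
    for delay in delays:
        cal = calibrate_initial_distance(delay, target_min_d, params)
        traj = prescribed_pair_rollout(delay, cal.initial_d, cycles, params)
        speed = _steady_speed(traj.avg_displacement, GAIT_PERIOD * measure_cycles)
        rows.append(
            {
                "delay": delay,
                "initial_d": cal.initial_d,
                "speed": speed,
                "improvement_percent": 100.0 * (speed - baseline.speed) / baseline.speed,
            }
        )
        curves[delay] = traj
    return SweepResult(table=pd.DataFrame(rows), baseline=baseline, curves=curves)
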