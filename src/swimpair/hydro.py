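"""Quasi-static Stokes dynamics of colinear three-sphere swimmers.

Two identical swimmers, each made of three rigid spheres of radius ``R``
joined by two extensible arms, sit on a common axis.  Sphere velocities
``V`` and the forces ``F`` the fluid exerts on them are related through the
axial (xx) component of the Oseen mobility tensor, ``V = H F``.  Each
swimmer is force-free, and the arm-length rates are prescribed, which
closes the linear system at every instant (inertia plays no role at low
Reynolds number, so the dynamics is quasi-static: the displacement over an
actuation step depends only on the shape path, not on how fast it is
traversed).

All lengths are expressed in units of the sphere radius; arms toggle
between a contracted length of 6 and an extended length of 10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

ARM_CONTRACTED = 6.0
ARM_EXTENDED = 10.0
#: separation below which spheres of radius 1 would overlap
CONTACT_DISTANCE = 2.0
#: separation below which the far-field (Oseen) approximation degrades
OSEEN_WARN_DISTANCE = 5.0


class GeometryError(ValueError):
    """Raised when sphere positions overlap, cross, or leave the model's
    domain of validity."""


@dataclass
class HydroParams:
    """Physical scales and integrator resolution.

    sphere_radius and viscosity are kept symbolic (the package works in
    scaled units where both are 1); substeps is the number of RK4
    sub-intervals per actuation step.
    """

    sphere_radius: float = 1.0
    viscosity: float = 1.0
    substeps: int = 128

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")


@dataclass
class SimState:
    """Full physical state: six sphere centres and four arm bits.

    ``x`` holds the axial coordinates x1..x6 (strictly increasing; spheres
    1-3 form the back swimmer, 4-6 the front swimmer).  ``arm_bits[i]`` is
    True when arm i is extended (length 10) and False when contracted
    (length 6); between actuation steps the arm lengths implied by ``x``
    must match the bits.
    """

    x: np.ndarray
    arm_bits: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.arm_bits = np.asarray(self.arm_bits, dtype=bool)
        if self.x.shape != (6,):
            raise ValueError("x must have shape (6,)")
        if self.arm_bits.shape != (4,):
            raise ValueError("arm_bits must have shape (4,)")

    @property
    def arm_lengths(self) -> np.ndarray:
        x = self.x
        return np.array([x[1] - x[0], x[2] - x[1], x[4] - x[3], x[5] - x[4]])

    @property
    def d(self) -> float:
        """Closest distance between the swimmers, |x4 - x3|."""
        return float(self.x[3] - self.x[2])

    @property
    def back_centroid(self) -> float:
        return float(self.x[:3].mean())

    @property
    def front_centroid(self) -> float:
        return float(self.x[3:].mean())

    def validate(self, at_rest: bool = True) -> None:
        if not np.all(np.diff(self.x) > 0):
            raise GeometryError("sphere positions must be strictly increasing")
        if self.d <= CONTACT_DISTANCE:
            raise GeometryError(f"swimmers in contact: d = {self.d:.3f} <= 2")
        lengths = self.arm_lengths
        if np.any(lengths < ARM_CONTRACTED - 1e-9) or np.any(
            lengths > ARM_EXTENDED + 1e-9
        ):
            raise GeometryError(f"arm lengths {lengths} outside [6, 10]")
        if at_rest:
            targets = np.where(self.arm_bits, ARM_EXTENDED, ARM_CONTRACTED)
            if not np.allclose(lengths, targets, atol=1e-6):
                raise GeometryError(
                    f"arm lengths {lengths} inconsistent with bits {self.arm_bits}"
                )

    @classmethod
    def from_bits(
        cls,
        arm_bits,
        d: float,
        back_centroid: float = 0.0,
    ) -> "SimState":
        """Build a resting state from arm bits and the swimmer gap ``d``,
        placing the back swimmer's centroid at ``back_centroid``."""
        bits = np.asarray(arm_bits, dtype=bool)
        L = np.where(bits, ARM_EXTENDED, ARM_CONTRACTED)
        x1 = back_centroid - (2.0 * L[0] + L[1]) / 3.0
        x = np.array(
            [
                x1,
                x1 + L[0],
                x1 + L[0] + L[1],
                x1 + L[0] + L[1] + d,
                x1 + L[0] + L[1] + d + L[2],
                x1 + L[0] + L[1] + d + L[2] + L[3],
            ]
        )
        return cls(x=x, arm_bits=bits)


@dataclass
class ArmRates:
    """Signed arm-length rates dL_i/dt, one entry per arm.

    At most one arm per swimmer may actuate at a time, and all actuating
    arms share the same rate magnitude (the common actuation speed).
    """

    ldot: np.ndarray

    def __post_init__(self) -> None:
        self.ldot = np.asarray(self.ldot, dtype=np.float64)
        if self.ldot.shape != (4,):
            raise ValueError("ldot must have shape (4,)")
        back = np.nonzero(self.ldot[:2])[0]
        front = np.nonzero(self.ldot[2:])[0]
        if len(back) > 1 or len(front) > 1:
            raise ValueError("at most one actuating arm per swimmer")
        mags = np.abs(self.ldot[self.ldot != 0.0])
        if mags.size and not np.allclose(mags, mags[0]):
            raise ValueError("actuating arms must share one rate magnitude")


@dataclass
class MobilityMatrix:
    """Axial mobility coefficients H (velocity per force), one row/column
    per sphere."""

    H: np.ndarray = field()

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)


# ---------------------------------------------------------------------------
# compiled kernels (hot path: one linear solve per RK4 stage)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mobility_kernel(x, mu, R):
    n = x.shape[0]
    H = np.empty((n, n))
    diag = 1.0 / (6.0 * math.pi * mu * R)
    for i in range(n):
        H[i, i] = diag
        for j in range(i + 1, n):
            h = 1.0 / (4.0 * math.pi * mu * abs(x[i] - x[j]))
            H[i, j] = h
            H[j, i] = h
    return H


@njit(cache=True)
def _gauss_solve(A, b):
    # in-place Gaussian elimination with partial pivoting on a small system
    n = b.shape[0]
    for k in range(n):
        p = k
        big = abs(A[k, k])
        for i in range(k + 1, n):
            if abs(A[i, k]) > big:
                big = abs(A[i, k])
                p = i
        if big == 0.0:
            raise np.linalg.LinAlgError("singular constraint system")
        if p != k:
            for j in range(n):
                tmp = A[k, j]
                A[k, j] = A[p, j]
                A[p, j] = tmp
            tmp = b[k]
            b[k] = b[p]
            b[p] = tmp
        inv = 1.0 / A[k, k]
        for i in range(k + 1, n):
            f = A[i, k] * inv
            if f != 0.0:
                for j in range(k, n):
                    A[i, j] -= f * A[k, j]
                b[i] -= f * b[k]
    xout = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = b[i]
        for j in range(i + 1, n):
            s -= A[i, j] * xout[j]
        xout[i] = s / A[i, i]
    return xout


@njit(cache=True)
def _constrained_velocities(x, ldot, mu, R):
    """Velocities/forces for ``n_swimmers = len(x)//3`` colinear three-sphere
    swimmers with prescribed arm rates and per-swimmer force-free closure."""
    n = x.shape[0]
    ns = n // 3
    H = _mobility_kernel(x, mu, R)
    A = np.zeros((n, n))
    b = np.zeros(n)
    r = 0
    for s in range(ns):
        base = 3 * s
        for k in range(2):
            i = base + k
            for j in range(n):
                A[r, j] = H[i + 1, j] - H[i, j]
            b[r] = ldot[2 * s + k]
            r += 1
    for s in range(ns):
        for j in range(3 * s, 3 * s + 3):
            A[r, j] = 1.0
        r += 1
    F = _gauss_solve(A, b)
    V = H @ F
    return V, F


@njit(cache=True)
def _integrate_kernel(x0, dL, mu, R, substeps):
    """RK4 integration of the shape path s in [0, 1] with constant arm
    rates dL (total length change per arm over the step).

    Returns (x_final, status); status 1 means spheres touched or crossed
    mid-step (x_final then holds the last valid positions).
    """
    x = x0.copy()
    h = 1.0 / substeps
    n = x.shape[0]
    for _ in range(substeps):
        k1, _ = _constrained_velocities(x, dL, mu, R)
        k2, _ = _constrained_velocities(x + 0.5 * h * k1, dL, mu, R)
        k3, _ = _constrained_velocities(x + 0.5 * h * k2, dL, mu, R)
        k4, _ = _constrained_velocities(x + h * k3, dL, mu, R)
        x_new = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for i in range(n - 1):
            gap = x_new[i + 1] - x_new[i]
            lo = 2.0 if (n == 6 and i == 2) else 0.0
            if gap <= lo:
                return x, 1
        x = x_new
    return x, 0


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def oseen_mobility(state: SimState, params: HydroParams) -> MobilityMatrix:
    """Assemble the 6x6 axial Oseen mobility matrix for the current
    geometry: 1/(6 pi mu R) on the diagonal and 1/(4 pi mu |xi - xj|) off
    the diagonal (the (I + rr) factor of the Oseen tensor equals 2 along
    the common axis)."""
    x = state.x
    diffs = np.abs(x[:, None] - x[None, :])
    if np.any(diffs[~np.eye(6, dtype=bool)] == 0.0):
        raise GeometryError("coincident sphere positions")
    if state.d < OSEEN_WARN_DISTANCE:
        warnings.warn(
            f"inter-swimmer distance d = {state.d:.3f} < 5: the far-field "
            "Oseen approximation is becoming inaccurate",
            stacklevel=2,
        )
    H = _mobility_kernel(x, params.viscosity, params.sphere_radius)
    return MobilityMatrix(H=H)


def solve_constrained_dynamics(
    state: SimState, rates: ArmRates, params: HydroParams
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the instantaneous closed system: V = H F, prescribed arm
    rates V[i+1]-V[i] = ldot, and zero net force on each swimmer.

    Returns (velocities, forces), each of shape (6,).
    """
    state.validate(at_rest=False)
    V, F = _constrained_velocities(
        state.x, rates.ldot, params.viscosity, params.sphere_radius
    )
    return V, F


def solve_constrained_dynamics_reference(
    x: np.ndarray, ldot: np.ndarray, mu: float = 1.0, R: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pure-NumPy reference solve of the same constraints via a full
    12-unknown least-squares system (independent of the compiled path)."""
    x = np.asarray(x, float)
    n = x.size
    ns = n // 3
    diffs = np.abs(x[:, None] - x[None, :])
    with np.errstate(divide="ignore"):
        H = 1.0 / (4.0 * np.pi * mu * diffs)
    H[np.eye(n, dtype=bool)] = 1.0 / (6.0 * np.pi * mu * R)
    # unknowns z = [V, F]
    rows = []
    rhs = []
    eye = np.eye(n)
    for i in range(n):  # V - H F = 0
        rows.append(np.concatenate([eye[i], -H[i]]))
        rhs.append(0.0)
    r = 0
    for s in range(ns):
        for k in range(2):
            i = 3 * s + k
            row = np.zeros(2 * n)
            row[i + 1] = 1.0
            row[i] = -1.0
            rows.append(row)
            rhs.append(ldot[2 * s + k])
            r += 1
    for s in range(ns):
        row = np.zeros(2 * n)
        row[n + 3 * s : n + 3 * s + 3] = 1.0
        rows.append(row)
        rhs.append(0.0)
    A = np.array(rows)
    b = np.array(rhs)
    z, *_ = np.linalg.lstsq(A, b, rcond=None)
    return z[:n], z[n:]


def integrate_actuation_step(
    state: SimState, arm_indices, params: HydroParams
) -> tuple[SimState, np.ndarray]:
    """Advance one actuation step in which each arm in ``arm_indices``
    toggles between its contracted (6) and extended (10) length.

    The actuating arm lengths vary linearly in a shape parameter
    s in [0, 1]; positions are integrated along the path with RK4 using
    ``params.substeps`` sub-intervals.  Returns the new resting state and
    the six per-sphere displacements.
    """
    arm_indices = tuple(arm_indices)
    if any(i not in (0, 1, 2, 3) for i in arm_indices):
        raise ValueError(f"invalid arm indices {arm_indices}")
    if len([i for i in arm_indices if i < 2]) > 1 or len(
        [i for i in arm_indices if i >= 2]
    ) > 1:
        raise ValueError("at most one actuating arm per swimmer")
    state.validate(at_rest=True)
    if not arm_indices:
        return SimState(x=state.x.copy(), arm_bits=state.arm_bits.copy()), np.zeros(6)
    dL = np.zeros(4)
    new_bits = state.arm_bits.copy()
    lengths = state.arm_lengths
    for i in arm_indices:
        target = ARM_CONTRACTED if state.arm_bits[i] else ARM_EXTENDED
        dL[i] = target - lengths[i]
        new_bits[i] = not new_bits[i]
    x_new, status = _integrate_kernel(
        state.x, dL, params.viscosity, params.sphere_radius, params.substeps
    )
    if status != 0:
        raise GeometryError(
            "spheres came into contact during the actuation step "
            f"(last valid d = {x_new[3] - x_new[2]:.3f})"
        )
    new_state = SimState(x=x_new, arm_bits=new_bits)
    new_state.validate(at_rest=True)
    return new_state, x_new - state.x


# canonical per-swimmer stroke: starting fully extended, toggle the rear
# arm, then the front arm, then the rear, then the front
# (extended,extended) -> (contracted,extended) -> (contracted,contracted)
# -> (extended,contracted) -> back to start.  This orientation propels the
# swimmer toward +x (verified numerically; the mirrored order reverses it).
NG_TOGGLE_CYCLE = (0, 1, 0, 1)
NG_CYCLE_BITS = (
    (True, True),
    (False, True),
    (False, False),
    (True, False),
)


def ng_cycle_phase(arm_bits) -> int:
    """Phase index 0-3 of a single swimmer's configuration on the canonical
    stroke cycle (every configuration lies on the cycle)."""
    key = (bool(arm_bits[0]), bool(arm_bits[1]))
    return NG_CYCLE_BITS.index(key)


@njit(cache=True)
def _single_cycle_kernel(x0, toggles_dl, mu, R, substeps):
    x = x0.copy()
    for k in range(toggles_dl.shape[0]):
        dL = toggles_dl[k]
        x, status = _integrate_kernel(x, dL, mu, R, substeps)
        if status != 0:
            return x, 1
    return x, 0


def single_swimmer_positions(arm_bits, centroid: float = 0.0) -> np.ndarray:
    """Resting positions of one isolated swimmer with the given arm bits."""
    L = np.where(np.asarray(arm_bits, bool), ARM_EXTENDED, ARM_CONTRACTED)
    x1 = centroid - (2.0 * L[0] + L[1]) / 3.0
    return np.array([x1, x1 + L[0], x1 + L[0] + L[1]])


def integrate_single_swimmer_step(
    x: np.ndarray, arm_bits, arm: int, params: HydroParams | None = None
) -> tuple[np.ndarray, list]:
    """Toggle one arm of an isolated three-sphere swimmer (3x3 system,
    one force-free constraint).  Returns the new positions and arm bits."""
    params = params or HydroParams()
    if arm not in (0, 1):
        raise ValueError("arm must be 0 (rear) or 1 (front)")
    x = np.asarray(x, dtype=np.float64)
    bits = [bool(arm_bits[0]), bool(arm_bits[1])]
    dL = np.zeros(2)
    cur = x[arm + 1] - x[arm]
    target = ARM_CONTRACTED if bits[arm] else ARM_EXTENDED
    dL[arm] = target - cur
    x_new, status = _integrate_kernel(
        x, dL, params.viscosity, params.sphere_radius, params.substeps
    )
    if status != 0:
        raise GeometryError("sphere contact during single-swimmer step")
    bits[arm] = not bits[arm]
    return x_new, bits


def ng_cycle_displacement(
    start_config=(True, True),
    params: HydroParams | None = None,
    reverse: bool = False,
) -> float:
    """Net centroid displacement of a single isolated swimmer over one
    complete four-step stroke cycle starting from ``start_config``.

    ``reverse`` runs the time-reversed stroke, which exactly negates the
    displacement (kinematic reversibility of Stokes flow).
    """
    params = params or HydroParams()
    bits = [bool(start_config[0]), bool(start_config[1])]
    phase = ng_cycle_phase(bits)
    order = [NG_TOGGLE_CYCLE[(phase + k) % 4] for k in range(4)]
    if reverse:
        order = order[::-1]
    x = single_swimmer_positions(bits)
    start_centroid = x.mean()
    toggles_dl = np.zeros((4, 2))
    cur = np.where(bits, ARM_EXTENDED, ARM_CONTRACTED).astype(float)
    for k, arm in enumerate(order):
        target = ARM_CONTRACTED if cur[arm] == ARM_EXTENDED else ARM_EXTENDED
        toggles_dl[k, arm] = target - cur[arm]
        cur[arm] = target
    x_final, status = _single_cycle_kernel(
        x, toggles_dl, params.viscosity, params.sphere_radius, params.substeps
    )
    if status != 0:
        raise GeometryError("sphere contact during single-swimmer stroke")
    return float(x_final.mean() - start_centroid)
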