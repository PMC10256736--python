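"""Per-step rollout records and their plain-text (CSV) serialization.

All lengths are in sphere-radius units; one row per actuation step.
``D_B`` and ``D_F`` are the cumulative centroid displacements of the back
and front swimmer since the start of the rollout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydro import ARM_CONTRACTED, ARM_EXTENDED

COLUMNS = [
    "step",
    "action",
    "reward",
    "x1",
    "x2",
    "x3",
    "x4",
    "x5",
    "x6",
    "d",
    "D_B",
    "D_F",
]

_HEADER_COMMENT = (
    "# swimmer-pair trajectory; lengths in sphere radii, one row per "
    "actuation step; D_B/D_F are cumulative centroid displacements\n"
)


class TrajectoryParseError(ValueError):
    pass


@dataclass
class Trajectory:
    """Columnar record of one rollout."""

    step: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    x: np.ndarray  # (T, 6)
    d: np.ndarray
    D_B: np.ndarray
    D_F: np.ndarray

    def __post_init__(self) -> None:
        T = len(self.step)
        for name in ("action", "reward", "d", "D_B", "D_F"):
            if len(getattr(self, name)) != T:
                raise ValueError(f"column {name} length mismatch")
        if self.x.shape != (T, 6):
            raise ValueError("x must have shape (T, 6)")

    def __len__(self) -> int:
        return len(self.step)

    @property
    def avg_displacement(self) -> np.ndarray:
        """Pair-average cumulative displacement <D> = (D_B + D_F)/2."""
        return (self.D_B + self.D_F) / 2.0

    def config_bits(self) -> np.ndarray:
        """(T, 4) boolean arm bits recovered from the resting arm lengths
        at the end of each step (True = extended)."""
        L = np.stack(
            [
                self.x[:, 1] - self.x[:, 0],
                self.x[:, 2] - self.x[:, 1],
                self.x[:, 4] - self.x[:, 3],
                self.x[:, 5] - self.x[:, 4],
            ],
            axis=1,
        )
        mid = 0.5 * (ARM_CONTRACTED + ARM_EXTENDED)
        return L > mid

    def slice(self, start: int, stop: int | None = None) -> "Trajectory":
        """Sub-range view with the cumulative displacements re-based to
        zero at the start of the slice."""
        sl = np.s_[start:stop]
        base_b = self.D_B[start - 1] if start > 0 else 0.0
        base_f = self.D_F[start - 1] if start > 0 else 0.0
        return Trajectory(
            step=self.step[sl],
            action=self.action[sl],
            reward=self.reward[sl],
            x=self.x[sl],
            d=self.d[sl],
            D_B=self.D_B[sl] - base_b,
            D_F=self.D_F[sl] - base_f,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "step": self.step.astype(np.int64),
                "action": self.action.astype(np.int64),
                "reward": self.reward,
            }
        )
        for k in range(6):
            df[f"x{k+1}"] = self.x[:, k]
        df["d"] = self.d
        df["D_B"] = self.D_B
        df["D_F"] = self.D_F
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Trajectory":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise TrajectoryParseError(f"missing columns: {missing}")
        return cls(
            step=df["step"].to_numpy(np.int64),
            action=df["action"].to_numpy(np.int64),
            reward=df["reward"].to_numpy(np.float64),
            x=df[[f"x{k+1}" for k in range(6)]].to_numpy(np.float64),
            d=df["d"].to_numpy(np.float64),
            D_B=df["D_B"].to_numpy(np.float64),
            D_F=df["D_F"].to_numpy(np.float64),
        )


class TrajectoryBuilder:
    """Incremental row-by-row construction during a rollout."""

    def __init__(self) -> None:
        self._rows: dict[str, list] = {c: [] for c in ("step", "action", "reward", "d")}
        self._x: list[np.ndarray] = []
        self._db: list[float] = []
        self._df: list[float] = []
        self._cum_b = 0.0
        self._cum_f = 0.0

    def append(self, step, action, reward, x, d_b_step, d_f_step) -> None:
        x = np.asarray(x, float)
        self._rows["step"].append(int(step))
        self._rows["action"].append(int(action))
        self._rows["reward"].append(float(reward))
        self._rows["d"].append(float(x[3] - x[2]))
        self._x.append(x.copy())
        self._cum_b += d_b_step
        self._cum_f += d_f_step
        self._db.append(self._cum_b)
        self._df.append(self._cum_f)

    def build(self) -> Trajectory:
        T = len(self._x)
        return Trajectory(
            step=np.array(self._rows["step"], np.int64),
            action=np.array(self._rows["action"], np.int64),
            reward=np.array(self._rows["reward"], float),
            x=np.array(self._x).reshape(T, 6),
            d=np.array(self._rows["d"], float),
            D_B=np.array(self._db, float),
            D_F=np.array(self._df, float),
        )


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV at full double precision (lossless
    round-trip)."""
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        traj.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TrajectoryParseError(f"malformed trajectory file {path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise TrajectoryParseError(f"empty trajectory file {path}") from exc
    present = [c for c in COLUMNS if c in df.columns]
    if len(df) and df[present].isna().any(axis=None):
        row = int(df[present].isna().any(axis=1).idxmax())
        # +3: header comment, column header, 1-based numbering
        raise TrajectoryParseError(
            f"malformed trajectory file {path}: incomplete record at line {row + 3}"
        )
    try:
        return Trajectory.from_frame(df)
    except (KeyError, ValueError, TypeError) as exc:
        if isinstance(exc, TrajectoryParseError):
            raise
        raise TrajectoryParseError(f"malformed trajectory file {path}: {exc}") from exc
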