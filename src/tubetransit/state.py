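"""Ensemble state and arrival-curve containers."""

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MM = 1e-3

ACTIVE = 0
ABSORBED = 1


@dataclass
class RunStats:
    """Bookkeeping from one simulation run."""

    dt: float = 0.0               # base time step, s
    n_steps: int = 0
    n_moves: int = 0              # particle-steps attempted
    n_reflections: int = 0
    n_fallback: int = 0           # rejected (resampled-as-stay) moves
    runtime_s: float = 0.0

    @property
    def rejection_rate(self) -> float:
        return self.n_fallback / self.n_moves if self.n_moves else 0.0


@dataclass
class EnsembleState:
    """Positions (m) and absorption bookkeeping of all particles at one time.

    Invariant: every particle is either active or absorbed, so
    ``n_active + n_absorbed == n_total`` at all times; absorption times are
    never revised.
    """

    time: float
    positions: np.ndarray        # (N, 3), metres
    status: np.ndarray           # (N,), uint8: 0 active, 1 absorbed
    absorption_time: np.ndarray  # (N,), s; NaN while active

    @property
    def n_total(self) -> int:
        return len(self.status)

    @property
    def n_active(self) -> int:
        return int(np.sum(self.status == ACTIVE))

    @property
    def n_absorbed(self) -> int:
        return int(np.sum(self.status == ABSORBED))

    @property
    def positions_mm(self) -> np.ndarray:
        return self.positions / MM

    def copy(self) -> "EnsembleState":
        return EnsembleState(self.time, self.positions.copy(),
                             self.status.copy(), self.absorption_time.copy())


@dataclass
class ArrivalCurve:
    """Cumulative fraction of the initial ensemble absorbed at the
    contralateral plane, on a fixed recording grid."""

    times: np.ndarray      # s, starting at 0
    fractions: np.ndarray  # in [0, 1], non-decreasing
    n_total: int
    stats: RunStats | None = field(default=None, compare=False)

    def fraction_at(self, t: float) -> float:
        """Cumulative fraction at the largest recorded time <= t."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(
                f"t={t} outside recorded range "
                f"[{self.times[0]}, {self.times[-1]}]")
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.fractions[i])

    def to_frame(self) -> pd.DataFrame:
        n_abs = np.rint(self.fractions * self.n_total).astype(int)
        return pd.DataFrame({
            "time_min": self.times / 60.0,
            "fraction": self.fractions,
            "n_absorbed": n_abs,
            "n_total": self.n_total,
        })

    def plot(self, ax=None, **kwargs):
        """Plot fraction vs time in minutes (matplotlib convenience)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.times / 60.0, self.fractions, where="post", **kwargs)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("arrival fraction")
        ax.set_ylim(0, 1)
        return ax
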