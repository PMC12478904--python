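"""Numerical integration of the coupled model and curve diagnostics.

Integrates the four-compartment system with an adaptive explicit
Runge-Kutta scheme (the system is non-stiff at epidemic parameter
scales) and extracts the quantities the analysis turns on: compartment
peaks, the time at which genuine infections first overtake the
worried-well, and the worry-to-infection ratio I_W/I_P used as a proxy
for perceived versus actual healthcare demand.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import CompartmentState, ModelParameters, rhs

__all__ = [
    "IntegrationError",
    "DegenerateTrajectoryError",
    "Trajectory",
    "ScenarioSummary",
    "simulate",
    "summarize",
    "ratio_curve",
]

#: solver tolerances (relative, absolute)
RTOL_DEFAULT = 1e-8
ATOL_DEFAULT = 1e-10
#: output grid spacing in days
OUTPUT_STEP_DEFAULT = 0.1
#: negative excursions larger than this are solver failures, not round-off
NEGATIVE_CLIP_TOL = 1e-9
#: conservation tolerance along a trajectory
TRAJECTORY_SUM_ATOL = 1e-6
#: I_W/I_P is reported only where I_P exceeds this floor
RATIO_FLOOR_DEFAULT = 1e-12

_CSV_COLUMNS = ["time_days", "S", "I_P", "I_W", "R_P"]


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a valid trajectory."""


class DegenerateTrajectoryError(ValueError):
    """The trajectory is too short for the requested diagnostic."""


@dataclass(frozen=True)
class Trajectory:
    """Solution of the model on a uniform output grid.

    Attributes
    ----------
    times
        Strictly increasing grid in days, starting at 0.
    values
        Array of shape (n, 4) holding (S, I_P, I_W, R_P) per grid point,
        clipped of sub-``NEGATIVE_CLIP_TOL`` round-off.
    params, initial_state
        The inputs that produced the trajectory.
    """

    times: np.ndarray
    values: np.ndarray
    params: ModelParameters
    initial_state: CompartmentState

    @property
    def S(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def I_P(self) -> np.ndarray:
        return self.values[:, 1]

    @property
    def I_W(self) -> np.ndarray:
        return self.values[:, 2]

    @property
    def R_P(self) -> np.ndarray:
        return self.values[:, 3]

    @property
    def burden(self) -> np.ndarray:
        """I_P + I_W: the proxy for total healthcare demand."""
        return self.values[:, 1] + self.values[:, 2]

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> CompartmentState:
        """The state at grid index ``i`` (conservation checked at 1e-6)."""
        return CompartmentState.from_array(self.values[i], atol=TRAJECTORY_SUM_ATOL)

    def states(self) -> list[CompartmentState]:
        return [self.state(i) for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_days": self.times,
                "S": self.S,
                "I_P": self.I_P,
                "I_W": self.I_W,
                "R_P": self.R_P,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the grid as CSV in full double precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(
        cls, path: str | Path, params: ModelParameters | None = None
    ) -> "Trajectory":
        """Read a trajectory written by :meth:`to_csv`.

        ``params`` may be supplied if known; otherwise diagnostics that
        need only the curves still work.
        """
        frame = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trajectory CSV missing columns {missing}")
        times = frame["time_days"].to_numpy(dtype=float)
        values = frame[["S", "I_P", "I_W", "R_P"]].to_numpy(dtype=float)
        return cls(
            times=times,
            values=values,
            params=params,
            initial_state=CompartmentState.from_array(
                values[0], atol=TRAJECTORY_SUM_ATOL
            ),
        )


@dataclass(frozen=True)
class ScenarioSummary:
    """Peak/crossing diagnostics of one simulated scenario.

    Times are in days within the simulated horizon.  ``first_crossing_time``
    is the first upward crossing of I_P over I_W (``None`` if it never
    happens).  Ratio fields are ``None`` when I_P stays below the floor
    everywhere (``ratio_defined`` is then False).
    """

    peak_IP_value: float
    peak_IP_time: float
    peak_IW_value: float
    peak_IW_time: float
    peak_burden_value: float
    peak_burden_time: float
    peak_ratio_value: float | None
    peak_ratio_time: float | None
    first_crossing_time: float | None
    ratio_defined: bool

    def to_dict(self) -> dict:
        return {
            "peak_IP_value": self.peak_IP_value,
            "peak_IP_time": self.peak_IP_time,
            "peak_IW_value": self.peak_IW_value,
            "peak_IW_time": self.peak_IW_time,
            "peak_burden_value": self.peak_burden_value,
            "peak_burden_time": self.peak_burden_time,
            "peak_ratio_value": self.peak_ratio_value,
            "peak_ratio_time": self.peak_ratio_time,
            "first_crossing_time": self.first_crossing_time,
            "ratio_defined": self.ratio_defined,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _output_grid(horizon_days: float, output_step_days: float) -> np.ndarray:
    n = int(math.floor(horizon_days / output_step_days + 1e-9))
    grid = output_step_days * np.arange(n + 1)
    if grid[-1] < horizon_days - 1e-9 * max(1.0, horizon_days):
        grid = np.append(grid, horizon_days)
    else:
        grid[-1] = horizon_days
    return grid


def simulate(
    params: ModelParameters,
    initial_state: CompartmentState,
    horizon_days: float,
    output_step_days: float = OUTPUT_STEP_DEFAULT,
    rtol: float = RTOL_DEFAULT,
    atol: float = ATOL_DEFAULT,
) -> Trajectory:
    """Integrate the model over ``horizon_days`` on a uniform output grid.

    Uses ``scipy``'s adaptive RK45 with tight tolerances; the returned
    states are clipped of negative round-off (anything below -1e-9 is an
    error, not round-off) and conservation is verified at every output
    point to 1e-6.
    """
    if not horizon_days > 0:
        raise ValueError(f"horizon_days must be positive, got {horizon_days}")
    if not 0 < output_step_days <= horizon_days:
        raise ValueError(
            f"output_step_days must lie in (0, horizon_days], got {output_step_days}"
        )
    grid = _output_grid(horizon_days, output_step_days)
    sol = solve_ivp(
        lambda _t, y: rhs(y, params),
        (0.0, float(horizon_days)),
        initial_state.as_array(),
        method="RK45",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    values = sol.y.T.copy()
    low = values.min()
    if low < -NEGATIVE_CLIP_TOL:
        raise IntegrationError(
            f"solver produced component {low}, below the -{NEGATIVE_CLIP_TOL} round-off band"
        )
    np.clip(values, 0.0, None, out=values)
    totals = values.sum(axis=1)
    worst = np.abs(totals - 1.0).max()
    if worst > TRAJECTORY_SUM_ATOL:
        raise IntegrationError(
            f"conservation violated along trajectory: |sum-1| up to {worst}"
        )
    return Trajectory(
        times=sol.t.copy(), values=values, params=params, initial_state=initial_state
    )


def _refine_peak(
    times: np.ndarray, values: np.ndarray, i: int
) -> tuple[float, float]:
    """Quadratic refinement of a grid argmax through its bracketing points.

    Falls back to the grid point when the peak sits on the boundary or
    the three points are collinear.
    """
    if i == 0 or i == len(times) - 1:
        return float(times[i]), float(values[i])
    t0, t1, t2 = times[i - 1], times[i], times[i + 1]
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    if a >= 0:  # flat or non-concave bracket: keep the grid point
        return float(t1), float(y1)
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    t_star = -b / (2 * a)
    t_star = min(max(t_star, t0), t2)
    c = y1 - a * t1**2 - b * t1
    return float(t_star), float(a * t_star**2 + b * t_star + c)


def _first_upward_crossing(times: np.ndarray, diff: np.ndarray) -> float | None:
    """First time ``diff`` (= I_P - I_W) crosses from negative to positive.

    A zero-run followed by positive values counts as a crossing at the
    run's left endpoint.  Returns None if no upward crossing occurs.
    """
    for i in range(1, len(diff)):
        if diff[i] > 0 and diff[i - 1] < 0:
            frac = -diff[i - 1] / (diff[i] - diff[i - 1])
            return float(times[i - 1] + frac * (times[i] - times[i - 1]))
        if diff[i] > 0 and diff[i - 1] == 0:
            j = i - 1
            while j > 0 and diff[j - 1] == 0:
                j -= 1
            if j == 0 or diff[j - 1] < 0:
                return float(times[j])
    return None


def ratio_curve(
    traj: Trajectory, ratio_floor: float = RATIO_FLOOR_DEFAULT
) -> np.ndarray:
    """Pointwise I_W/I_P on the output grid, NaN where I_P < ``ratio_floor``.

    The floor only guards exact-zero initial data: starting from any
    positive I_P the infected fraction stays strictly positive, so the
    quotient is well defined along the whole trajectory.
    """
    if not ratio_floor > 0:
        raise ValueError(f"ratio_floor must be positive, got {ratio_floor}")
    ip = traj.I_P
    out = np.full(len(traj), np.nan)
    mask = ip >= ratio_floor
    out[mask] = traj.I_W[mask] / ip[mask]
    return out


def summarize(
    traj: Trajectory, ratio_floor: float = RATIO_FLOOR_DEFAULT
) -> ScenarioSummary:
    """Peak values/times, the I_P-over-I_W crossing, and the peak I_W/I_P ratio.

    Peaks are located on the output grid and refined by a local quadratic
    through the three bracketing points; the crossing is refined by
    linear interpolation inside its grid interval.
    """
    if len(traj) < 3:
        raise DegenerateTrajectoryError(
            f"summary needs at least 3 grid points, got {len(traj)}"
        )
    times = traj.times
    pk_ip_t, pk_ip_v = _refine_peak(times, traj.I_P, int(np.argmax(traj.I_P)))
    pk_iw_t, pk_iw_v = _refine_peak(times, traj.I_W, int(np.argmax(traj.I_W)))
    burden = traj.burden
    pk_b_t, pk_b_v = _refine_peak(times, burden, int(np.argmax(burden)))

    ratio = ratio_curve(traj, ratio_floor)
    defined = np.isfinite(ratio)
    if defined.any():
        masked = np.where(defined, ratio, -np.inf)
        i = int(np.argmax(masked))
        if 0 < i < len(times) - 1 and defined[i - 1] and defined[i + 1]:
            pk_r_t, pk_r_v = _refine_peak(times, ratio, i)
        else:
            pk_r_t, pk_r_v = float(times[i]), float(ratio[i])
        ratio_defined = True
    else:
        pk_r_t = pk_r_v = None
        ratio_defined = False

    crossing = _first_upward_crossing(times, traj.I_P - traj.I_W)

    return ScenarioSummary(
        peak_IP_value=pk_ip_v,
        peak_IP_time=pk_ip_t,
        peak_IW_value=pk_iw_v,
        peak_IW_time=pk_iw_t,
        peak_burden_value=pk_b_v,
        peak_burden_time=pk_b_t,
        peak_ratio_value=pk_r_v,
        peak_ratio_time=pk_r_t,
        first_crossing_time=crossing,
        ratio_defined=ratio_defined,
    )
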