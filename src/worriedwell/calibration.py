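"""Synthetic observation generation and parameter recovery.

Observed epidemic curves are noisy: this module simulates the model,
samples one or more channels (I_P, I_W, or their sum, the healthcare
"burden") at discrete times, perturbs them with multiplicative lognormal
noise, and fits any named subset of the model parameters back to such
observations by bounded nonlinear least squares on log-transformed
channels.  The log-scale loss matches the multiplicative noise model and
keeps the epidemic peak from dominating the residual.

Randomness enters only through :func:`generate_observations`, always via
an explicit seed; fitting is deterministic given its inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model_core import CompartmentState, ModelParameters, rhs
from .scenarios import default_parameters
from .simulation import ATOL_DEFAULT, IntegrationError, RTOL_DEFAULT

__all__ = [
    "ConfigurationError",
    "NoiseModel",
    "ObservationSet",
    "FitResult",
    "CHANNELS",
    "DEFAULT_BOUNDS",
    "generate_observations",
    "flat_directions",
    "fit",
]

CHANNELS = ("I_P", "I_W", "burden")

#: floor applied before taking logs in the loss
LOG_FLOOR = 1e-10

#: box bounds for each fittable parameter
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1e-3, 10.0),
    "beta_P": (0.0, 5.0),
    "beta_W": (0.0, 5.0),
    "beta_WP": (0.0, 5.0),
    "gamma_P": (1e-4, 2.0),
    "gamma_W": (1e-4, 2.0),
    "delta_P": (0.0, 1.0),
}

#: singular values this far below the largest mark a near-flat direction
FLAT_DIRECTION_RTOL = 1e-6


class ConfigurationError(ValueError):
    """Inconsistent free/fixed parameter specification."""


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise descriptor: family and scale (sigma of log)."""

    family: str = "lognormal"
    scale: float = 0.05

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValueError(f"unsupported noise family {self.family!r}")
        if self.scale < 0:
            raise ValueError(f"noise scale must be >= 0, got {self.scale}")


@dataclass(frozen=True)
class ObservationSet:
    """Sampled (possibly noisy) channels of one simulated outbreak."""

    times: np.ndarray
    channels: dict[str, np.ndarray]
    noise_model: NoiseModel
    seed: int
    initial_state: CompartmentState
    truth: ModelParameters | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one observed channel is required")
        for name in self.channels:
            if name not in CHANNELS:
                raise ValueError(f"unknown channel {name!r}; choose from {CHANNELS}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        """CSV of times and channels plus a sidecar ``<path>.meta.json``."""
        path = Path(path)
        frame = pd.DataFrame({"time_days": self.times, **self.channels})
        frame.to_csv(path, index=False, float_format="%.17g")
        meta = {
            "noise_model": {"family": self.noise_model.family, "scale": self.noise_model.scale},
            "seed": self.seed,
            "initial_state": {
                "S": self.initial_state.S,
                "I_P": self.initial_state.I_P,
                "I_W": self.initial_state.I_W,
                "R_P": self.initial_state.R_P,
            },
            "truth": self.truth.as_dict() if self.truth is not None else None,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationSet":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        channels = {
            name: frame[name].to_numpy(dtype=float)
            for name in frame.columns
            if name != "time_days"
        }
        ist = meta["initial_state"]
        return cls(
            times=frame["time_days"].to_numpy(dtype=float),
            channels=channels,
            noise_model=NoiseModel(**meta["noise_model"]),
            seed=meta["seed"],
            initial_state=CompartmentState(ist["S"], ist["I_P"], ist["I_W"], ist["R_P"]),
            truth=ModelParameters(**meta["truth"]) if meta["truth"] else None,
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of one least-squares fit.

    ``near_flat_directions`` lists combinations of the free parameters
    along which the loss surface is (numerically) flat at the optimum —
    the fingerprint of non-identifiability; a fit with such directions
    converged somewhere on a ridge, not to a unique point.
    """

    params: dict[str, float]
    loss: float
    converged: bool
    n_evaluations: int
    message: str
    jacobian_singular_values: tuple[float, ...]
    near_flat_directions: tuple[str, ...] = field(default_factory=tuple)

    @property
    def identifiable(self) -> bool:
        return not self.near_flat_directions


def _sample_channels(
    params: ModelParameters,
    initial_state: CompartmentState,
    times: np.ndarray,
    channel_names: Iterable[str],
) -> dict[str, np.ndarray]:
    """Integrate the model and sample the requested channels at ``times``."""
    t0 = min(0.0, float(times[0]))
    sol = solve_ivp(
        lambda _t, y: rhs(y, params),
        (t0, float(times[-1])),
        initial_state.as_array(),
        method="RK45",
        t_eval=np.asarray(times, dtype=float),
        rtol=RTOL_DEFAULT,
        atol=ATOL_DEFAULT,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None)
    series = {"I_P": y[1], "I_W": y[2], "burden": y[1] + y[2]}
    return {name: series[name].copy() for name in channel_names}


def generate_observations(
    true_params: ModelParameters,
    initial_state: CompartmentState,
    times: Sequence[float],
    noise_model: NoiseModel = NoiseModel(),
    seed: int = 0,
    channels: Sequence[str] = ("I_P", "I_W"),
) -> ObservationSet:
    """Simulate the model and sample noisy channels at the given times.

    Each sampled value is multiplied by an independent lognormal factor
    exp(N(0, scale^2)); scale 0 reproduces the exact trajectory.  The
    same seed always yields the same observations.
    """
    unknown = [name for name in channels if name not in CHANNELS]
    if unknown:
        raise ValueError(f"unknown channels {unknown}; choose from {CHANNELS}")
    times = np.asarray(times, dtype=float)
    exact = _sample_channels(true_params, initial_state, times, channels)
    rng = np.random.default_rng(seed)
    noisy = {
        name: values * rng.lognormal(mean=0.0, sigma=noise_model.scale, size=len(values))
        for name, values in exact.items()
    }
    return ObservationSet(
        times=times,
        channels=noisy,
        noise_model=noise_model,
        seed=seed,
        initial_state=initial_state,
        truth=true_params,
    )


def _log(x: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(x, LOG_FLOOR))


def flat_directions(jac: np.ndarray, names: Sequence[str]) -> tuple[str, ...]:
    """Describe parameter directions along which the residual is flat.

    Singular vectors of the residual Jacobian whose singular value falls
    below ``FLAT_DIRECTION_RTOL`` times the largest are reported as
    signed combinations of the free parameter names; an empty result
    means the fit is locally identifiable.
    """
    sv = np.linalg.svd(jac, compute_uv=False)
    if sv[0] == 0:
        return tuple(names)  # residual insensitive to every parameter
    _, _, vt = np.linalg.svd(jac)
    flat = []
    for k, s in enumerate(sv):
        if s < FLAT_DIRECTION_RTOL * sv[0]:
            weights = ", ".join(
                f"{w:+.2f}*{name}" for w, name in zip(vt[k], names) if abs(w) > 0.05
            )
            flat.append(weights or names[int(np.argmax(np.abs(vt[k])))])
    return tuple(flat)


def fit(
    observations: ObservationSet,
    free: Sequence[str],
    initial_guess: Mapping[str, float],
    fixed: ModelParameters | Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FitResult:
    """Recover the ``free`` parameters from observed channels.

    Minimizes the sum of squared residuals between log-transformed
    simulated and observed channels with a bounded trust-region
    least-squares solver (finite-difference Jacobian), starting from
    ``initial_guess``.  ``fixed`` supplies the non-free parameters as a
    full :class:`ModelParameters` or a mapping of overrides merged onto
    the package defaults.  Non-convergence is reported in the result,
    never raised; a contradictory specification (a parameter both free
    and fixed) raises :class:`ConfigurationError`.
    """
    free = list(free)
    if not free:
        raise ConfigurationError("free parameter subset must be nonempty")
    valid = set(DEFAULT_BOUNDS)
    unknown = [name for name in free if name not in valid]
    if unknown:
        raise ConfigurationError(f"unknown free parameters {unknown}")
    if isinstance(fixed, Mapping):
        overlap = sorted(set(free) & set(fixed))
        if overlap:
            raise ConfigurationError(
                f"parameters {overlap} passed as both free and fixed"
            )
        base = default_parameters().replace(**dict(fixed))
    elif fixed is None:
        base = default_parameters()
    else:
        base = fixed
    missing = [name for name in free if name not in initial_guess]
    if missing:
        raise ConfigurationError(f"initial_guess missing free parameters {missing}")

    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    lo = np.array([box[name][0] for name in free])
    hi = np.array([box[name][1] for name in free])
    x0 = np.array([float(initial_guess[name]) for name in free])
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ConfigurationError("initial guess violates parameter bounds")
    # alpha=0 (and zero recovery rates) are outside the parameter space;
    # keep the solver strictly inside by nudging zero lower bounds.
    lo = np.maximum(lo, 1e-8)

    names = sorted(observations.channels)
    obs_log = np.concatenate([_log(observations.channels[n]) for n in names])

    def residuals(x: np.ndarray) -> np.ndarray:
        params = base.replace(**dict(zip(free, x)))
        sim = _sample_channels(
            params, observations.initial_state, observations.times, names
        )
        return np.concatenate([_log(sim[n]) for n in names]) - obs_log

    result = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10)

    sv = np.linalg.svd(result.jac, compute_uv=False)
    flat = flat_directions(result.jac, free)

    return FitResult(
        params=dict(zip(free, map(float, result.x))),
        loss=float(2.0 * result.cost),  # sum of squared residuals
        converged=bool(result.success),
        n_evaluations=int(result.nfev),
        message=str(result.message),
        jacobian_singular_values=tuple(map(float, sv)),
        near_flat_directions=tuple(flat),
    )
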