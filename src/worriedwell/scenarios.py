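"""Default parameterization, behavioural regimes and the scenario suites.

The default rate constants are early-pandemic estimates: a two-week mean
infectious period and an equally long mean duration of worry
(gamma_P = gamma_W = 1/14 day^-1), a pathogen reproduction number of
10.3 giving beta_P = 0.74 day^-1, an eight-month mean immune period
(delta_P = 1/240 day^-1) and worry transmission beta_W = beta_WP =
0.7 day^-1, i.e. a worry reproduction number of 9.8.  Simulations start
with 1% of the population genuinely infected and 1% worried-well, and
run for 50 weeks (350 days).

Three behavioural regimes are named presets over alpha: cautious
(alpha < 1, preset 0.5), default (alpha = 1) and protesting (alpha > 1,
preset 1.5).  The cautious/protesting preset values are this package's
choice within each regime's inequality; every regime comparison is an
ordering, not a point value, so conclusions do not hinge on them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import CompartmentState, ModelParameters
from .simulation import (
    OUTPUT_STEP_DEFAULT,
    ScenarioSummary,
    Trajectory,
    simulate,
    summarize,
)

__all__ = [
    "RegimeMismatchError",
    "ScenarioSpec",
    "RegimeResult",
    "SensitivityResult",
    "REGIME_PRESETS",
    "HORIZON_DEFAULT_DAYS",
    "default_parameters",
    "default_initial_state",
    "regime",
    "run_regime_suite",
    "initial_condition_sweep",
]

#: preset behavioural modifiers; cautious/protesting are configurable
REGIME_PRESETS: dict[str, float] = {"cautious": 0.5, "default": 1.0, "protesting": 1.5}

#: 50 weeks, in days
HORIZON_DEFAULT_DAYS = 350.0


class RegimeMismatchError(ValueError):
    """An alpha override contradicts the requested regime's inequality."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully specified simulation scenario."""

    name: str
    params: ModelParameters
    initial_state: CompartmentState
    horizon_days: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("scenario name must be nonempty")


@dataclass(frozen=True)
class RegimeResult:
    spec: ScenarioSpec
    trajectory: Trajectory
    summary: ScenarioSummary


@dataclass(frozen=True)
class SensitivityResult:
    """(spec, summary) pairs of an initial-condition sweep, in input order."""

    entries: tuple[tuple[ScenarioSpec, ScenarioSummary], ...]

    def peak_ratios(self) -> list[float | None]:
        return [summary.peak_ratio_value for _, summary in self.entries]


def default_parameters() -> ModelParameters:
    """The default parameter set (all rates per day), with alpha = 1."""
    return ModelParameters(
        alpha=1.0,
        beta_P=0.74,
        beta_W=0.7,
        beta_WP=0.7,
        gamma_P=1.0 / 14.0,
        gamma_W=1.0 / 14.0,
        delta_P=1.0 / 240.0,
    )


def default_initial_state(ip0: float = 0.01, iw0: float = 0.01) -> CompartmentState:
    """Initial state with infected/worried seeds and no prior immunity."""
    return CompartmentState.from_seeds(ip0, iw0, 0.0)


def regime(name: str, alpha_override: float | None = None) -> ModelParameters:
    """Default parameters with alpha set by regime preset or override.

    The override must respect the regime's inequality: cautious needs
    alpha < 1, protesting alpha > 1, default exactly 1.
    """
    if name not in REGIME_PRESETS:
        raise ValueError(
            f"unknown regime {name!r}; choose from {sorted(REGIME_PRESETS)}"
        )
    alpha = REGIME_PRESETS[name] if alpha_override is None else float(alpha_override)
    if name == "cautious" and not alpha < 1:
        raise RegimeMismatchError(f"cautious regime requires alpha < 1, got {alpha}")
    if name == "protesting" and not alpha > 1:
        raise RegimeMismatchError(f"protesting regime requires alpha > 1, got {alpha}")
    if name == "default" and alpha != 1:
        raise RegimeMismatchError(f"default regime requires alpha = 1, got {alpha}")
    return default_parameters().replace(alpha=alpha)


def run_regime_suite(
    horizon_days: float = HORIZON_DEFAULT_DAYS,
    output_step_days: float = OUTPUT_STEP_DEFAULT,
    alpha_overrides: dict[str, float] | None = None,
) -> list[RegimeResult]:
    """Run cautious, default and protesting regimes from the 1%/1% seed.

    Returns one (spec, trajectory, summary) triple per regime, in the
    order cautious, default, protesting.
    """
    overrides = alpha_overrides or {}
    initial = default_initial_state()
    results = []
    for name in ("cautious", "default", "protesting"):
        params = regime(name, overrides.get(name))
        spec = ScenarioSpec(
            name=name, params=params, initial_state=initial, horizon_days=horizon_days
        )
        traj = simulate(params, initial, horizon_days, output_step_days)
        results.append(RegimeResult(spec=spec, trajectory=traj, summary=summarize(traj)))
    return results


def initial_condition_sweep(
    iw0_values: tuple[float, ...] = (0.001, 0.01, 0.1),
    ip0: float = 0.01,
    horizon_days: float = HORIZON_DEFAULT_DAYS,
    output_step_days: float = OUTPUT_STEP_DEFAULT,
) -> SensitivityResult:
    """Sensitivity of the dynamics to the initial worried-well seed.

    Each sweep member runs the default regime (alpha = 1) from
    S(0) = 1 - ip0 - iw0, R_P(0) = 0.  The default sweep sets the
    worried-well seed ten times smaller than, equal to, and ten times
    larger than the 1% infected seed.
    """
    for iw0 in iw0_values:
        if not 0 < iw0 < 1 or not 0 < ip0 < 1 or iw0 + ip0 >= 1:
            raise ValueError(
                f"seeds must lie in (0,1) with iw0 + ip0 < 1, got iw0={iw0}, ip0={ip0}"
            )
    params = regime("default")
    entries = []
    for iw0 in iw0_values:
        initial = default_initial_state(ip0=ip0, iw0=iw0)
        spec = ScenarioSpec(
            name=f"iw0={iw0:g}",
            params=params,
            initial_state=initial,
            horizon_days=horizon_days,
        )
        traj = simulate(params, initial, horizon_days, output_step_days)
        entries.append((spec, summarize(traj)))
    return SensitivityResult(entries=tuple(entries))
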