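"""Coupled pathogen / worried-well compartmental model.

The population is divided into four fractions: susceptible ``S``,
pathogen-infected ``I_P`` (genuinely sick), worried-well ``I_W``
(clinically uninfected but anxious enough to alter behaviour) and
pathogen-recovered ``R_P``.  Both contagions spread by contact: the
pathogen from ``I_P`` alone, worry from contact with either ``I_P`` or
``I_W``.  Recovery from the pathogen confers temporary immunity to both
pathogen and worry; recovery from worry returns individuals directly to
the susceptible pool (no immunity against re-worrying).  Mortality and
demography are neglected, so the four fractions sum to one at all times.

The two forces of infection are

    lambda_P = beta_P * I_P
    lambda_W = beta_WP * I_P + beta_W * I_W

and a dimensionless behavioural modifier ``alpha`` rescales the pathogen
force of infection acting on the worried-well: cautious behaviour
(``alpha < 1``) shields them through reduced contacts, protesting
behaviour (``alpha > 1``) exposes them through amplified contacts, and
``alpha = 1`` means worry does not change pathogen exposure.

The full system, with every rate in units of day^-1, reads

    dS/dt   = -(beta_P + beta_WP) * S * I_P - beta_W * S * I_W
              + delta_P * R_P + gamma_W * I_W
    dI_P/dt = beta_P * S * I_P + alpha * beta_P * I_P * I_W - gamma_P * I_P
    dI_W/dt = -alpha * beta_P * I_P * I_W + beta_W * S * I_W
              + beta_WP * S * I_P - gamma_W * I_W
    dR_P/dt = gamma_P * I_P - delta_P * R_P

The basic reproduction number is the maximum of the two single-contagion
ratios, R0 = max(beta_P / gamma_P, beta_W / gamma_W); it does not depend
on ``beta_WP`` because the genuinely sick are already effective vectors
of worry.  The disease-free equilibrium (1, 0, 0, 0) is locally stable
iff R0 < 1, which this module checks through the eigenvalues of the
Jacobian restricted to (I_P, I_W, R_P).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "InvalidParameterError",
    "InvalidStateError",
    "ModelParameters",
    "CompartmentState",
    "ForcePair",
    "ThresholdReport",
    "forces_of_infection",
    "derivatives",
    "rhs",
    "reproduction_numbers",
    "dfe_jacobian",
    "dfe_stability",
]

#: tolerance on S + I_P + I_W + R_P = 1 at state construction
STATE_SUM_ATOL = 1e-9


class InvalidParameterError(ValueError):
    """A model parameter violates its admissibility constraint."""


class InvalidStateError(ValueError):
    """A compartment state violates bounds or conservation."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and behavioural modifier of the coupled model.

    Parameters
    ----------
    alpha
        Dimensionless behavioural modifier for the worried-well; must be
        strictly positive.  ``alpha < 1`` is the cautious regime,
        ``alpha > 1`` the protesting regime.
    beta_P
        Pathogen transmission coefficient (day^-1).
    beta_W
        Worry transmission coefficient from contact with the worried-well
        (day^-1).
    beta_WP
        Worry transmission coefficient from contact with the genuinely
        sick (day^-1).
    gamma_P
        Pathogen recovery rate (day^-1); inverse mean infectious period.
    gamma_W
        Worry recovery rate (day^-1); inverse mean duration of worry
        ("pandemic fatigue").
    delta_P
        Immunity waning rate (day^-1); inverse mean immune period.
    """

    alpha: float
    beta_P: float
    beta_W: float
    beta_WP: float
    gamma_P: float
    gamma_W: float
    delta_P: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        for name in ("beta_P", "beta_W", "beta_WP", "delta_P"):
            value = getattr(self, name)
            if not value >= 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {value}")
        for name in ("gamma_P", "gamma_W"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(
                    f"{name} must be > 0 (reproduction numbers divide by it), got {value}"
                )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class CompartmentState:
    """Population fractions (S, I_P, I_W, R_P) at one instant.

    Components must lie in [0, 1] and sum to 1; both checks use ``atol``
    (default 1e-9) so that solver output carrying benign round-off can be
    wrapped with a looser tolerance.
    """

    S: float
    I_P: float
    I_W: float
    R_P: float
    atol: float = STATE_SUM_ATOL

    def __post_init__(self) -> None:
        for name in ("S", "I_P", "I_W", "R_P"):
            value = getattr(self, name)
            if not (-self.atol <= value <= 1 + self.atol):
                raise InvalidStateError(f"{name} must lie in [0, 1], got {value}")
        total = self.S + self.I_P + self.I_W + self.R_P
        if abs(total - 1.0) > self.atol:
            raise InvalidStateError(
                f"compartments must sum to 1 within {self.atol}, got {total!r}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I_P, self.I_W, self.R_P], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, atol: float = STATE_SUM_ATOL) -> "CompartmentState":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]), atol=atol)

    @classmethod
    def from_seeds(cls, i_p: float, i_w: float, r_p: float = 0.0) -> "CompartmentState":
        """State with the given infected/worried seeds, S absorbing the rest."""
        return cls(1.0 - i_p - i_w - r_p, i_p, i_w, r_p)


@dataclass(frozen=True)
class ForcePair:
    """Forces of infection (day^-1): pathogen and worry."""

    lambda_P: float
    lambda_W: float


@dataclass(frozen=True)
class ThresholdReport:
    """Reproduction numbers and disease-free-equilibrium stability.

    ``dfe_eigenvalues``/``dfe_stable`` are ``None`` when only the
    reproduction numbers were requested.
    """

    r0_pathogen: float
    r0_worry: float
    r0: float
    dfe_eigenvalues: tuple[float, float, float] | None = None
    dfe_stable: bool | None = None


def forces_of_infection(state: CompartmentState, params: ModelParameters) -> ForcePair:
    """Forces of infection lambda_P = beta_P*I_P, lambda_W = beta_WP*I_P + beta_W*I_W."""
    return ForcePair(
        lambda_P=params.beta_P * state.I_P,
        lambda_W=params.beta_WP * state.I_P + params.beta_W * state.I_W,
    )


def rhs(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Model right-hand side on a raw (S, I_P, I_W, R_P) array.

    Unvalidated fast path shared by :func:`derivatives` and the
    integrator; rates are day^-1.
    """
    s, ip, iw, rp = y
    a = params.alpha
    bp, bw, bwp = params.beta_P, params.beta_W, params.beta_WP
    gp, gw, dp = params.gamma_P, params.gamma_W, params.delta_P
    ds = -(bp + bwp) * s * ip - bw * s * iw + dp * rp + gw * iw
    dip = bp * s * ip + a * bp * ip * iw - gp * ip
    diw = -a * bp * ip * iw + bw * s * iw + bwp * s * ip - gw * iw
    drp = gp * ip - dp * rp
    return np.array([ds, dip, diw, drp], dtype=float)


def derivatives(state: CompartmentState, params: ModelParameters) -> np.ndarray:
    """Time derivatives (day^-1) of (S, I_P, I_W, R_P); they sum to zero."""
    return rhs(state.as_array(), params)


def reproduction_numbers(params: ModelParameters) -> ThresholdReport:
    """Reproduction numbers of both contagions and their maximum.

    R0_pathogen = beta_P / gamma_P, R0_worry = beta_W / gamma_W and
    R0 = max of the two; the result is independent of beta_WP.
    """
    if params.gamma_P <= 0 or params.gamma_W <= 0:
        raise InvalidParameterError("recovery rates must be positive to form R0")
    r0_p = params.beta_P / params.gamma_P
    r0_w = params.beta_W / params.gamma_W
    return ThresholdReport(r0_pathogen=r0_p, r0_worry=r0_w, r0=max(r0_p, r0_w))


def dfe_jacobian(params: ModelParameters) -> np.ndarray:
    """Jacobian at the disease-free equilibrium, restricted to (I_P, I_W, R_P).

    With S eliminated through S = 1 - I_P - I_W - R_P and evaluated at
    (1, 0, 0, 0), the linearization is lower triangular:

        [[beta_P - gamma_P,  0,                0      ],
         [beta_WP,           beta_W - gamma_W, 0      ],
         [gamma_P,           0,               -delta_P]]
    """
    return np.array(
        [
            [params.beta_P - params.gamma_P, 0.0, 0.0],
            [params.beta_WP, params.beta_W - params.gamma_W, 0.0],
            [params.gamma_P, 0.0, -params.delta_P],
        ]
    )


def dfe_stability(params: ModelParameters) -> ThresholdReport:
    """Full threshold report: R0 values, DFE eigenvalues, stability verdict.

    The eigenvalues of the lower-triangular DFE Jacobian are its diagonal
    (beta_P - gamma_P, beta_W - gamma_W, -delta_P); the equilibrium is
    locally stable iff all are strictly negative, equivalently R0 < 1
    (given delta_P > 0).
    """
    base = reproduction_numbers(params)
    eigs = (
        params.beta_P - params.gamma_P,
        params.beta_W - params.gamma_W,
        -params.delta_P,
    )
    return ThresholdReport(
        r0_pathogen=base.r0_pathogen,
        r0_worry=base.r0_worry,
        r0=base.r0,
        dfe_eigenvalues=eigs,
        dfe_stable=all(e < 0 for e in eigs),
    )
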