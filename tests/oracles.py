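"""Independent reference implementations used only as test oracles.

Everything here is transcribed term-by-term from the model equations,
deliberately without importing the package's right-hand side, so that
agreement between the two is a genuine cross-check.
"""

import numpy as np


def rhs_reference(y, alpha, beta_P, beta_W, beta_WP, gamma_P, gamma_W, delta_P):
    """Term-by-term transcription of the four balance equations."""
    S, IP, IW, RP = y
    dS = -(beta_P + beta_WP) * S * IP - beta_W * S * IW + delta_P * RP + gamma_W * IW
    dIP = beta_P * S * IP + alpha * beta_P * IP * IW - gamma_P * IP
    dIW = -alpha * beta_P * IP * IW + beta_W * S * IW + beta_WP * S * IP - gamma_W * IW
    dRP = gamma_P * IP - delta_P * RP
    return np.array([dS, dIP, dIW, dRP])


def euler_reference(y0, t_end, dt, **params):
    """Fixed-step forward Euler; brute force, for short horizons only."""
    n = int(round(t_end / dt))
    y = np.array(y0, dtype=float)
    for _ in range(n):
        y = y + dt * rhs_reference(y, **params)
    return y
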