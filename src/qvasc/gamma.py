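"""Gamma-variate bolus model.

The first pass of an intravascular contrast bolus is modelled as

    C(t) = A * (t - t0)^alpha * exp(-(t - t0) / beta)   for t > t0,  else 0

with onset ``t0`` (s), shape ``alpha`` (dimensionless), scale ``beta`` (s)
and amplitude ``A``.  Its time integral has the closed form
``A * beta**(alpha + 1) * Gamma(alpha + 1)``, which is what relative
blood-volume ratios are built from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma_fn

__all__ = ["GammaVariateFit", "gamma_variate", "gamma_area"]


@dataclass(frozen=True)
class GammaVariateFit:
    """Fitted gamma-variate parameters for one concentration curve."""

    amplitude: float
    t0: float
    alpha: float
    beta: float
    window: tuple[float, float] = (0.0, 0.0)
    rss: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and (self.alpha <= 0 or self.beta <= 0):
            raise ValueError(
                f"alpha and beta must be positive, got alpha={self.alpha}, beta={self.beta}"
            )

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return gamma_variate(t, self.amplitude, self.t0, self.alpha, self.beta)


def gamma_variate(
    t: np.ndarray | float, amplitude: float, t0: float, alpha: float, beta: float
) -> np.ndarray:
    """Evaluate the gamma-variate curve; 0 for t <= t0."""
    t = np.asarray(t, dtype=float)
    tau = t - t0
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = amplitude * tau[pos] ** alpha * np.exp(-tau[pos] / beta)
    return out


def gamma_area(fit: GammaVariateFit) -> float:
    """Closed-form area under the curve, ``A * beta^(alpha+1) * Gamma(alpha+1)``."""
    if not fit.converged:
        return float("nan")
    return float(fit.amplitude * fit.beta ** (fit.alpha + 1.0) * _gamma_fn(fit.alpha + 1.0))
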