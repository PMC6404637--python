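"""Dopamine D1 modulation of synaptic gain.

D1 receptor activation enhances glutamatergic input onto excitatory neurons
earlier (in dose) than onto inhibitory neurons.  The model captures this with
two sigmoids of the D1 activation level D that multiply the E->E and E->I
efficacies:

    A_EE(D) = (1/C_EE) * (1 + D_L / (1 + exp((D_E0 - D)/K_c))) - (1 - A_min)
    A_EI(D) = (1/C_EI) * (1 + D_L / (1 + exp((D_I0 - D)/K_c))) - (1 - A_min)

with D_E0 = D_0 - D_V, D_I0 = D_0 + D_V, D_L = A_max - A_min, and the
normalizers C_EE = C_EI = 1 + D_L/2 obtained by evaluating the sigmoid term at
D = D_0 with D_V = 0.  The half-activation of the E->E gain leads the E->I
gain by 2*D_V, so the gain difference dA = A_EE - A_EI is non-negative and
peaks exactly at the intermediate activation D_0.

Factors are stored as dimensionless multipliers (1.04, not 104%); they apply
multiplicatively to all E->E classes (J_b, J_p, J_b/p) and to J_EI; J_IE and
J_II are never scaled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DAParams", "DAProfile", "scaling_factors", "build_trajectory"]


@dataclass(frozen=True)
class DAParams:
    """Parameters of the D1-activation -> synaptic-gain map.

    ``K_c`` (steepness) and ``D_V`` (half-activation shift) are the published
    "Dopamine1" values; ``A_min``/``A_max`` set the gain range and are
    calibration parameters.  The defaults fix ``A_min = 1`` so that at low D1
    activation both gains are weak (< 1), at high activation both strong
    (> 1), and at D_0 they bracket the baseline efficacies — and set the
    modulation depth so the resting state at D_0 approaches the phase border
    without crossing into spontaneous (imaginary) memory, which is what makes
    WM sensitivity maximal there.  The depth was calibrated once per
    reference network and frozen: 1.5 for the desk-scale default, 1.0 for
    :meth:`full_scale`.
    """

    D_0: float = 1.0
    D_min: float = 0.0
    D_max: float = 2.0
    K_c: float = 0.150
    D_V: float = 0.105
    A_min: float = 1.00
    A_max: float = 2.50

    def __post_init__(self) -> None:
        if not self.D_min <= self.D_0 <= self.D_max:
            raise ValueError("need D_min <= D_0 <= D_max")
        if self.K_c <= 0:
            raise ValueError(f"steepness K_c must be positive, got {self.K_c}")
        if self.D_V < 0:
            raise ValueError(f"shift D_V must be non-negative, got {self.D_V}")
        if not self.A_min < self.A_max:
            raise ValueError("need A_min < A_max")

    # derived quantities
    @property
    def D_E0(self) -> float:
        return self.D_0 - self.D_V

    @property
    def D_I0(self) -> float:
        return self.D_0 + self.D_V

    @property
    def D_L(self) -> float:
        return self.A_max - self.A_min

    @property
    def A_P1(self) -> float:
        return 1.0 - self.A_min

    @property
    def C_norm(self) -> float:
        """Shared normalizer: sigmoid term at D = D_0 with D_V = 0."""
        return 1.0 + self.D_L / 2.0

    @classmethod
    def dopamine1(cls, **overrides) -> "DAParams":
        return cls(K_c=0.150, D_V=0.105, **overrides)

    @classmethod
    def dopamine2(cls, **overrides) -> "DAParams":
        return cls(K_c=0.120, D_V=0.185, **overrides)

    @classmethod
    def full_scale(cls, **overrides) -> "DAParams":
        """Gain range calibrated on the full-size (8000 E / 2000 I) network."""
        overrides.setdefault("A_min", 1.00)
        overrides.setdefault("A_max", 1.85)
        return cls(**overrides)


@dataclass(frozen=True)
class DAProfile:
    """Gain factors tabulated on an increasing grid of D1 activation levels."""

    D: np.ndarray
    A_EE: np.ndarray
    A_EI: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.D) > 0):
            raise ValueError("D grid must be strictly increasing")
        for a in (self.A_EE, self.A_EI):
            if not (np.all(np.isfinite(a)) and np.all(a > 0)):
                raise ValueError("gain factors must be finite and positive")

    @property
    def dA(self) -> np.ndarray:
        return self.A_EE - self.A_EI

    def argmax_dA(self) -> float:
        """D1 activation level where the EE-EI gain difference peaks."""
        return float(self.D[int(np.argmax(self.dA))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"D": self.D, "A_EE": self.A_EE, "A_EI": self.A_EI, "dA": self.dA}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _gain(D, half: float, params: DAParams):
    sig = 1.0 + params.D_L / (1.0 + np.exp((half - D) / params.K_c))
    return sig / params.C_norm - params.A_P1


def scaling_factors(D, params: DAParams | None = None):
    """Closed-form (A_EE, A_EI) gain multipliers at D1 activation level ``D``.

    Accepts a scalar or array ``D`` inside ``[D_min, D_max]``.  Both factors
    are monotone non-decreasing in D; with D_V > 0, A_EE >= A_EI everywhere.
    """
    params = params or DAParams()
    D = np.asarray(D, dtype=float)
    if np.any(D < params.D_min - 1e-12) or np.any(D > params.D_max + 1e-12):
        raise ValueError(
            f"D outside activation domain [{params.D_min}, {params.D_max}]"
        )
    a_ee = _gain(D, params.D_E0, params)
    a_ei = _gain(D, params.D_I0, params)
    if D.ndim == 0:
        return float(a_ee), float(a_ei)
    return a_ee, a_ei


def build_trajectory(params: DAParams | None = None, grid_step: float = 0.01) -> DAProfile:
    """Tabulate the (A_EE, A_EI) state trajectory over [D_min, D_max].

    The returned profile is the path the network state follows in the EE-EI
    gain plane as D1 activation rises: it starts and ends near the diagonal
    (A_EE ~ A_EI) and bulges toward high-EE gain, with the bulge dA maximal
    at D_0.
    """
    params = params or DAParams()
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(round((params.D_max - params.D_min) / grid_step))
    D = params.D_min + grid_step * np.arange(n + 1)
    D[-1] = min(D[-1], params.D_max)
    a_ee, a_ei = scaling_factors(D, params)
    return DAProfile(D=D, A_EE=a_ee, A_EI=a_ei)
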