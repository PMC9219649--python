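"""Diffusion interaction parameter (kD) from DLS concentration series.

Dilute-solution DLS gives the mutual diffusion coefficient as a linear
function of protein concentration,

    D(c) = D0 · (1 + kD · c),

where D0 is the infinite-dilution diffusion coefficient and kD is the
diffusion interaction parameter in mL/g — so c enters the equation in
g/mL even though instrument series are tabulated in mg/mL (a slope of
−4.05×10⁻⁶ cm²·mL·s⁻¹·g⁻¹ changes D by ~1 % per mg/mL).  Negative kD
marks net attractive protein–protein interactions.  The fit is ordinary
least squares of D on c: intercept = D0, slope = kD·D0,
kD = slope/intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DlsSeries", "KdFit", "fit_kd", "kd_from_products"]

# the instrument series behind the fit spans 1–10 mg/mL; Eq. D = D0(1+kD·c)
# is a dilute-limit linearisation, so warn well outside that range
_LINEAR_RANGE_MG_ML = (1.0, 10.0)


@dataclass(frozen=True)
class DlsSeries:
    """Concentration series of diffusion coefficients.

    ``concentrations`` in mg/mL, ``diffusion_coefficients`` in cm²/s.
    """

    concentrations: np.ndarray
    diffusion_coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        d = np.asarray(self.diffusion_coefficients, dtype=float)
        if c.shape != d.shape or c.ndim != 1:
            raise ValueError("concentrations and D must be 1-D arrays of equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(d <= 0):
            raise ValueError("diffusion coefficients must be positive")
        if np.unique(c).size < 2:
            raise ValueError("need at least two distinct concentrations")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "diffusion_coefficients", d)


@dataclass(frozen=True)
class KdFit:
    """Result of the linear D(c) fit."""

    d0: float  # cm²/s
    kd: float  # mL/g
    kd_d0: float  # cm² mL s⁻¹ g⁻¹ (the fitted slope)
    stderr_slope: float
    stderr_intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("fitted D0 must be positive")
        if not np.isclose(self.kd_d0, self.kd * self.d0, rtol=1e-12, atol=0.0):
            raise ValueError("kd_d0 must equal kd × d0")


def fit_kd(series: DlsSeries) -> KdFit:
    """Ordinary least squares of D on c; returns D0, kD and their product.

    Replicate-averaged points are fitted unweighted.  A warning is issued
    when the concentration range extends well outside the 1–10 mg/mL
    regime where the linear model is trusted.
    """
    c = series.concentrations
    d = series.diffusion_coefficients
    lo, hi = _LINEAR_RANGE_MG_ML
    if c.min() < lo / 2 or c.max() > 2 * hi:
        warnings.warn(
            f"concentration range [{c.min():g}, {c.max():g}] mg/mL extends outside "
            f"the {lo}-{hi} mg/mL regime where D(c) is expected to be linear"
        )
    # c is tabulated in mg/mL; kD carries mL/g, so regress on c in g/mL
    res = stats.linregress(c * 1e-3, d)
    d0 = float(res.intercept)
    slope = float(res.slope)
    if d0 <= 0:
        raise ValueError(f"fitted D0 = {d0:g} is non-positive; data are not D(c)-like")
    return KdFit(
        d0=d0,
        kd=slope / d0,
        kd_d0=(slope / d0) * d0,
        stderr_slope=float(res.stderr) if res.stderr is not None else float("nan"),
        stderr_intercept=(
            float(res.intercept_stderr) if res.intercept_stderr is not None else float("nan")
        ),
        r_squared=float(res.rvalue**2),
    )


def kd_from_products(kd_d0_product: float, d0: float) -> float:
    """kD (mL/g) from a printed kD·D0 product and D0.

    Example: (−4.05×10⁻⁶, 4.48×10⁻⁷) → ≈ −9.04 mL/g.
    """
    if d0 <= 0:
        raise ValueError("D0 must be positive")
    return float(kd_d0_product) / float(d0)
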