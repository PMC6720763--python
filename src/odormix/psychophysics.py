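"""Single-odorant psychophysics: Weber–Fechner and Stevens' laws.

Perceived odor intensity (OI) is rated on the German VDI 3940 seven-point
scale (0 = not perceptible … 6 = extremely strong).  For a single odorant
the dependence of OI on concentration ``C`` (ppm) is described by two
classical laws:

* Weber–Fechner:  ``OI = k_WF · log10(C / C_OT)`` — linear in the logarithm
  of concentration, with ``C_OT`` the odor threshold (the concentration at
  which OI = 0).
* Stevens' power law:  ``OI = k_S · C**n`` — a power function whose exponent
  ``n`` also drives the UPL mixture model (see :mod:`odormix.perceptual`).

Both laws are fitted by ordinary least squares on the transformed
coordinates in which they are linear (OI vs log10 C, and log10 OI vs
log10 C respectively), matching how the coefficients are conventionally
determined from panel data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "VDI_SCALE_MAX",
    "PANEL_REPEATABILITY_LIMIT",
    "OdorIntensity",
    "WeberFechnerLaw",
    "StevensLaw",
    "OdorantProfile",
    "PanelistRecord",
    "FitResult",
    "DegenerateFitError",
    "NonMonotoneDataError",
    "fit_weber_fechner",
    "fit_stevens",
    "oi_from_concentration",
    "concentration_for_oi",
    "screen_panelist",
]

#: Top of the VDI 3940 odor-intensity scale.
VDI_SCALE_MAX = 6.0

#: Panel screening criterion: a panelist is retained iff 10**s <= 2.3,
#: s being the sample standard deviation of their repeated ratings.
PANEL_REPEATABILITY_LIMIT = 2.3


class DegenerateFitError(ValueError):
    """Raised when the design has no spread (all concentrations identical)."""


class NonMonotoneDataError(ValueError):
    """Raised when a fitted intensity law has non-positive slope."""


@dataclass(frozen=True)
class OdorIntensity:
    """A continuous odor intensity on the VDI 3940 axis.

    ``sub_threshold`` flags a prediction clamped up to 0 because the
    concentration was below the odor threshold; ``above_scale`` flags a
    prediction exceeding the top of the rating scale (6).  Panel ratings are
    integers in 0..6; model predictions are continuous.
    """

    value: float
    sub_threshold: bool = False
    above_scale: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"odor intensity must be >= 0, got {self.value}")
        object.__setattr__(self, "above_scale", self.value > VDI_SCALE_MAX)

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class WeberFechnerLaw:
    """OI = k_wf * log10(c / c_ot); ``k_wf`` in OI per decade, ``c_ot`` in ppm."""

    k_wf: float
    c_ot: float

    def __post_init__(self) -> None:
        if self.k_wf <= 0:
            raise ValueError(f"k_wf must be > 0, got {self.k_wf}")
        if self.c_ot <= 0:
            raise ValueError(f"c_ot must be > 0, got {self.c_ot}")

    def oi(self, c: float) -> OdorIntensity:
        return oi_from_concentration(self, c)

    def concentration(self, oi: float) -> float:
        return concentration_for_oi(self, oi)


@dataclass(frozen=True)
class StevensLaw:
    """OI = k_s * c**n; dimensionless prefactor ``k_s`` and exponent ``n``."""

    k_s: float
    n: float

    def __post_init__(self) -> None:
        if self.k_s <= 0:
            raise ValueError(f"k_s must be > 0, got {self.k_s}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")

    def oi(self, c: float) -> OdorIntensity:
        return oi_from_concentration(self, c)


@dataclass(frozen=True)
class OdorantProfile:
    """Physical and psychophysical constants for one odorant.

    Parameters
    ----------
    name : str
        Odorant name (e.g. ``"toluene"``).
    molar_mass : float
        g/mol.
    density_liquid : float
        Liquid density, g/cm^3 at 20 °C.
    vapor_pressure : float
        Saturation vapor pressure, Pa at 20 °C.
    odor_threshold_lit : float
        Literature odor threshold in air, ppm.
    wf, stevens :
        Fitted psychophysical laws for this odorant.
    """

    name: str
    molar_mass: float
    density_liquid: float
    vapor_pressure: float
    odor_threshold_lit: float
    wf: WeberFechnerLaw
    stevens: StevensLaw

    def __post_init__(self) -> None:
        for attr in ("molar_mass", "density_liquid", "vapor_pressure",
                     "odor_threshold_lit"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0 for {self.name}")


@dataclass(frozen=True)
class PanelistRecord:
    """Repeated ratings of the same stimulus by one panelist."""

    panelist_id: str
    ratings: tuple[float, ...]

    def __init__(self, panelist_id: str, ratings: Sequence[float]):
        object.__setattr__(self, "panelist_id", panelist_id)
        object.__setattr__(self, "ratings", tuple(float(r) for r in ratings))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a psychophysical-law fit.

    ``std_errors`` maps parameter names (``k_wf``/``c_ot`` or ``n``/``k_s``)
    to large-sample standard errors propagated from the OLS regression on
    the transformed coordinates (delta method for the back-transformed
    parameters).  With exactly two points the residual degrees of freedom
    vanish and the standard errors are NaN.
    """

    law: WeberFechnerLaw | StevensLaw
    std_errors: dict[str, float]
    r_squared: float
    n_points: int


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(data), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be a sequence of (concentration, OI) pairs")
    return arr[:, 0], arr[:, 1]


def fit_weber_fechner(data: Sequence[tuple[float, float]]) -> FitResult:
    """Fit ``OI = k_wf * log10(c / c_ot)`` by OLS of OI on log10(c).

    The slope gives ``k_wf`` directly; the threshold follows from the
    intercept ``a`` as ``c_ot = 10**(-a / k_wf)``.  Its standard error is
    obtained by the delta method using the OLS covariance of slope and
    intercept.

    Raises
    ------
    DegenerateFitError
        If all concentrations are identical.
    NonMonotoneDataError
        If the fitted slope is <= 0 (intensity must grow with concentration).
    """
    c, oi = _as_arrays(data)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(oi < 0):
        raise ValueError("odor intensities must be >= 0")
    if len(np.unique(c)) < 2:
        raise DegenerateFitError("need >= 2 distinct concentrations")

    x = np.log10(c)
    res = stats.linregress(x, oi)
    slope, intercept = res.slope, res.intercept
    if slope <= 0:
        raise NonMonotoneDataError(
            f"fitted slope {slope:.3g} <= 0: OI does not increase with concentration")
    c_ot = 10.0 ** (-intercept / slope)

    n = len(c)
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        se_b, se_a = res.stderr, res.intercept_stderr
        cov_ab = -np.mean(x) * se_b**2  # OLS cov(intercept, slope)
        ln10 = math.log(10.0)
        d_a = -ln10 / slope * c_ot
        d_b = ln10 * intercept / slope**2 * c_ot
        var_cot = d_a**2 * se_a**2 + d_b**2 * se_b**2 + 2 * d_a * d_b * cov_ab
        se_cot = math.sqrt(max(var_cot, 0.0))
        std_errors = {"k_wf": se_b, "c_ot": se_cot}
    else:
        std_errors = {"k_wf": float("nan"), "c_ot": float("nan")}

    return FitResult(
        law=WeberFechnerLaw(k_wf=slope, c_ot=c_ot),
        std_errors=std_errors,
        r_squared=res.rvalue**2,
        n_points=n,
    )


def fit_stevens(data: Sequence[tuple[float, float]]) -> FitResult:
    """Fit ``OI = k_s * c**n`` by OLS of log10(OI) on log10(c).

    Points with OI <= 0 cannot enter the log–log regression; they are
    dropped with a warning.  Fewer than two usable points is an error.
    """
    c, oi = _as_arrays(data)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    usable = oi > 0
    if not np.all(usable):
        warnings.warn(
            f"excluding {np.count_nonzero(~usable)} point(s) with OI <= 0 "
            "from the log-log Stevens fit", stacklevel=2)
    c, oi = c[usable], oi[usable]
    if len(np.unique(c)) < 2:
        raise DegenerateFitError("need >= 2 usable points with distinct concentrations")

    x, y = np.log10(c), np.log10(oi)
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise NonMonotoneDataError(
            f"fitted exponent {res.slope:.3g} <= 0: OI does not increase with concentration")
    k_s = 10.0 ** res.intercept

    n = len(c)
    if n > 2 and np.isfinite(res.stderr) and res.stderr > 0:
        se_ks = math.log(10.0) * k_s * res.intercept_stderr  # delta method
        std_errors = {"n": res.stderr, "k_s": se_ks}
    else:
        std_errors = {"n": float("nan"), "k_s": float("nan")}

    return FitResult(
        law=StevensLaw(k_s=k_s, n=res.slope),
        std_errors=std_errors,
        r_squared=res.rvalue**2,
        n_points=n,
    )


def oi_from_concentration(law: WeberFechnerLaw | StevensLaw, c: float) -> OdorIntensity:
    """Evaluate an intensity law at concentration ``c`` (ppm).

    Weber–Fechner predictions below threshold (c < c_ot) are clamped to 0
    and flagged ``sub_threshold`` — the VDI scale has no negative
    intensities.  Stevens' law is positive for all c > 0.
    """
    if c <= 0:
        raise ValueError(f"concentration must be > 0, got {c}")
    if isinstance(law, WeberFechnerLaw):
        raw = law.k_wf * math.log10(c / law.c_ot)
        if raw < 0:
            return OdorIntensity(0.0, sub_threshold=True)
        return OdorIntensity(raw)
    if isinstance(law, StevensLaw):
        return OdorIntensity(law.k_s * c**law.n)
    raise TypeError(f"unsupported law type: {type(law).__name__}")


def concentration_for_oi(law: WeberFechnerLaw, oi: float) -> float:
    """Invert the Weber–Fechner law: ``c = c_ot * 10**(oi / k_wf)``.

    At ``oi = 0`` this returns the odor threshold.  Exact inverse of
    :func:`oi_from_concentration` for oi >= 0.
    """
    oi = float(oi)
    if oi < 0:
        raise ValueError(f"odor intensity must be >= 0, got {oi}")
    if not isinstance(law, WeberFechnerLaw):
        raise TypeError("concentration_for_oi requires a WeberFechnerLaw")
    return law.c_ot * 10.0 ** (oi / law.k_wf)


def screen_panelist(record: PanelistRecord,
                    limit: float = PANEL_REPEATABILITY_LIMIT) -> bool:
    """Individual-repeatability screen: accept iff ``10**s <= limit``.

    ``s`` is the sample standard deviation (n-1 denominator) of the
    panelist's repeated ratings of the same stimulus.  With the default
    limit 2.3 this is equivalent to s <= log10(2.3) ≈ 0.3617.
    """
    if len(record.ratings) < 2:
        raise ValueError("screening requires >= 2 repeated ratings")
    s = float(np.std(record.ratings, ddof=1))
    return 10.0**s <= limit
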