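"""Forward signal equations for the three diffusion models.

All diffusivities are carried in mm2/s throughout the package (never in the
x10^-3 display convention); only the reporting layer rescales.  Signals are in
arbitrary scanner units.

Models
------
mono-exponential
    S_b = S_0 * exp(-b * ADC)

IVIM (intravoxel incoherent motion, bi-exponential)
    S_b = S_0 * [(1 - f) * exp(-b * Dt) + f * exp(-b * (Dt + Dp))]
    with Dt the true (tissue) diffusion coefficient, Dp the pseudo-diffusion
    coefficient of capillary blood, and f in [0, 1] the perfusion fraction.

RSI (restriction spectrum imaging, three fixed-diffusivity compartments)
    S_b = C1 * exp(-b * ADC1) + C2 * exp(-b * ADC2) + C3 * exp(-b * ADC3)
    with (ADC1, ADC2, ADC3) = (0, 1.4e-3, 10.2e-3) mm2/s: restricted
    intracellular, hindered extracellular, and free water pools.  Signal
    fractions F_i are the contributions normalized at b = 0 so that
    F1 + F2 + F3 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

#: Fixed compartment diffusivities of the breast RSI model, mm2/s
#: (restricted, hindered, free water).
RSI_FIXED_ADCS = (0.0, 1.4e-3, 10.2e-3)

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential parameters: the apparent diffusion coefficient."""

    adc: float  # mm2/s

    def __post_init__(self) -> None:
        if self.adc < 0:
            raise InvalidInputError(f"adc must be >= 0, got {self.adc}")


@dataclass(frozen=True)
class IVIMParams:
    """IVIM bi-exponential parameters (Dt, Dp in mm2/s; f dimensionless)."""

    dt: float
    dp: float
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise InvalidInputError(f"perfusion fraction f must lie in [0, 1], got {self.f}")
        if self.dt < 0 or self.dp < 0:
            raise InvalidInputError("diffusion coefficients must be >= 0")


@dataclass(frozen=True)
class RSIParams:
    """RSI compartment contributions, optional fractions and their products.

    ``c1/c2/c3`` are the unnormalized signal contributions (arbitrary units);
    ``f1/f2/f3`` the b=0-normalized signal fractions summing to 1, populated
    by :func:`contributions_to_fractions`.  ``c1c2`` and ``f1f2`` are the
    restricted-x-hindered products used as diagnostic markers.
    """

    c1: float
    c2: float
    c3: float
    f1: float | None = None
    f2: float | None = None
    f3: float | None = None
    fixed_adcs: tuple[float, float, float] = RSI_FIXED_ADCS

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.c3) < 0:
            raise InvalidInputError("signal contributions must be >= 0")
        fr = (self.f1, self.f2, self.f3)
        if any(v is not None for v in fr):
            if any(v is None for v in fr):
                raise InvalidInputError("either all or none of f1, f2, f3 must be set")
            if min(fr) < -_FRACTION_TOL:
                raise InvalidInputError("signal fractions must be >= 0")
            if abs(sum(fr) - 1.0) > 1e-6:
                raise InvalidInputError("signal fractions must sum to 1")

    @property
    def contributions(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3])

    @property
    def c1c2(self) -> float:
        """Product of the restricted and hindered contributions."""
        return self.c1 * self.c2

    @property
    def f1f2(self) -> float | None:
        """Product of the restricted and hindered signal fractions."""
        if self.f1 is None or self.f2 is None:
            return None
        return self.f1 * self.f2


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise InvalidInputError("b-values must be >= 0")
    return b


def mono_signal(params: MonoParams, s0: float, b) -> np.ndarray | float:
    """Mono-exponential decay ``s0 * exp(-b * adc)``.

    Parameters
    ----------
    params
        Holds the apparent diffusion coefficient in mm2/s.
    s0
        Baseline signal without diffusion weighting; must be positive.
    b
        Diffusion weighting(s), s/mm2 (scalar or array).
    """
    if s0 <= 0:
        raise InvalidInputError(f"s0 must be > 0, got {s0}")
    b = _check_b(b)
    out = s0 * np.exp(-b * params.adc)
    return float(out) if out.ndim == 0 else out


def ivim_signal(params: IVIMParams, s0: float, b) -> np.ndarray | float:
    """IVIM bi-exponential decay.

    Returns ``s0 * [(1-f) exp(-b Dt) + f exp(-b (Dt+Dp))]``; at b=0 this is
    exactly ``s0`` for every admissible parameter set.
    """
    if s0 <= 0:
        raise InvalidInputError(f"s0 must be > 0, got {s0}")
    b = _check_b(b)
    out = s0 * (
        (1.0 - params.f) * np.exp(-b * params.dt)
        + params.f * np.exp(-b * (params.dt + params.dp))
    )
    return float(out) if out.ndim == 0 else out


def rsi_signal(params: RSIParams, b) -> np.ndarray | float:
    """Three-compartment fixed-diffusivity decay.

    The restricted compartment has zero diffusivity, so its exponential is
    evaluated as an explicit constant 1; at b=0 the signal equals
    ``c1 + c2 + c3``.
    """
    b = _check_b(b)
    a1, a2, a3 = params.fixed_adcs
    # exp(-b*0) == 1 written out explicitly
    out = params.c1 * np.ones_like(b) + params.c2 * np.exp(-b * a2) + params.c3 * np.exp(-b * a3)
    return float(out) if out.ndim == 0 else out


def contributions_to_fractions(params: RSIParams, s0: float) -> RSIParams:
    """Convert contributions to b=0-normalized signal fractions.

    Each fraction starts as ``c_i / s0`` and the triple is renormalized so
    that F1 + F2 + F3 = 1 exactly (the fitted b=0 amplitude need not equal
    the supplied ``s0``).  Returns a new record with fractions populated.
    """
    if s0 <= 0:
        raise InvalidInputError(f"s0 must be > 0, got {s0}")
    raw = params.contributions / s0
    total = raw.sum()
    if total <= 0:
        raise InvalidInputError("cannot normalize all-zero contributions")
    f1, f2, f3 = (raw / total).tolist()
    return RSIParams(
        c1=params.c1, c2=params.c2, c3=params.c3,
        f1=f1, f2=f2, f3=f3, fixed_adcs=params.fixed_adcs,
    )
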