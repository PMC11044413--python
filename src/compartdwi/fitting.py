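"""Voxel-wise inverse problems for the three diffusion models.

The module offers two surfaces:

* statsmodels-style model objects (:class:`MonoExponentialModel`,
  :class:`IVIMModel`, :class:`RSIModel`) built from a batch of voxel signals,
  whose ``fit()`` returns a :class:`DWIFitResults` with per-voxel estimates,
  convergence diagnostics and a ``summary()`` table;
* per-voxel functions (:func:`fit_mono_adc`, :func:`fit_ivim`,
  :func:`fit_rsi`) and the whole-volume driver :func:`fit_volume`.

Numerical choices
-----------------
The mono-exponential ADC is the exact two-point inversion on (b=0, b=750);
with two points the least-squares line and the closed form coincide.  The
IVIM fit minimizes squared residuals of the normalized signal S_b/S_0 over
b <= 1000 with a bounded trust-region Gauss-Newton solver, started from a
segmented estimate (log-linear regression over b >= 250).  The RSI fit is
linear in the contributions because the compartment diffusivities are fixed;
it is solved by the same bounded solver on the raw signal and agrees with
non-negative linear least squares to solver precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bvalues import BValueScheme, DEFAULT_SCHEME
from .exceptions import InvalidInputError, UnfittableVoxelError
from .signal_models import (
    IVIMParams,
    MonoParams,
    RSIParams,
    RSI_FIXED_ADCS,
    contributions_to_fractions,
)

# Box constraints of the IVIM fit, mm2/s for the diffusivities.
IVIM_BOUNDS = {
    "dt": (1e-5, 3e-3),
    "dp": (1e-3, 0.5),
    "f": (0.0, 1.0),
}

_MAX_ITER = 500
_TOL = 1e-14  # relative ftol/xtol/gtol of the bounded solver
_BOUND_FLAG_RTOL = 1e-6

#: Column order of the fitted-parameter tables, per model.
PARAM_COLUMNS = {
    "mono": ["adc"],
    "ivim": ["dt", "dp", "f"],
    "rsi": ["c1", "c2", "c3", "c1c2", "f1", "f2", "f3", "f1f2"],
}

#: Map-layer parameter names (reporting convention).
MAP_NAMES = {
    "mono": ["ADC"],
    "ivim": ["Dt", "Dp", "f"],
    "rsi": ["C1", "C2", "C3", "C1C2", "F1", "F2", "F3", "F1F2"],
}


@dataclass
class FitResult:
    """Outcome of a single-voxel fit.

    ``flags`` carries qualitative diagnostics such as ``"clipped"`` (a
    negative closed-form ADC clipped to 0), ``"at_bound"`` (an estimate
    pinned at a box constraint) or ``"dp_nonidentifiable"`` (perfusion
    fraction ~0, leaving the pseudo-diffusion coefficient unconstrained).
    """

    params: MonoParams | IVIMParams | RSIParams
    residual_norm: float
    converged: bool
    n_iter: int = 0
    flags: tuple[str, ...] = ()


def _as_voxel(signal, scheme: BValueScheme) -> np.ndarray:
    sig = np.asarray(signal, dtype=float)
    if sig.shape != (len(scheme),):
        raise InvalidInputError(
            f"signal length {sig.shape} does not match the {len(scheme)}-b-value scheme"
        )
    if np.any(sig < 0):
        raise InvalidInputError("signal intensities must be >= 0")
    return sig


def fit_mono_adc(signal, scheme: BValueScheme = DEFAULT_SCHEME) -> FitResult:
    """Two-point ADC estimate, ``adc = ln(S0/S_750) / 750``.

    Negative estimates (S_750 > S_0, possible under noise) are clipped to 0
    and flagged.  Raises :class:`UnfittableVoxelError` when either of the two
    signals is non-positive.
    """
    sig = _as_voxel(signal, scheme)
    i0, ihi = scheme.mono_indices
    s0, shi = sig[i0], sig[ihi]
    if s0 <= 0 or shi <= 0:
        raise UnfittableVoxelError("two-point ADC needs S0 > 0 and S_750 > 0")
    adc = float(np.log(s0 / shi) / scheme.mono_high_b)
    flags: tuple[str, ...] = ()
    if adc < 0:
        adc, flags = 0.0, ("clipped",)
    return FitResult(MonoParams(adc=adc), residual_norm=0.0, converged=True, flags=flags)


def _ivim_model(b: np.ndarray, dt: float, dp: float, f: float) -> np.ndarray:
    return (1.0 - f) * np.exp(-b * dt) + f * np.exp(-b * (dt + dp))


def _ivim_init(b: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Segmented initialization: log-linear tail fit then extrapolation."""
    tail = b >= 250.0
    yt = np.clip(y[tail], 1e-12, None)
    slope, intercept = np.polyfit(b[tail], np.log(yt), 1)
    dt0 = float(np.clip(-slope, *IVIM_BOUNDS["dt"]))
    a = float(np.exp(intercept))
    f0 = float(np.clip(1.0 - a, 0.01, 0.6))
    dp0 = 0.02
    return np.array([dt0, dp0, f0])


def fit_ivim(signal, scheme: BValueScheme = DEFAULT_SCHEME) -> FitResult:
    """Joint bounded fit of the IVIM bi-exponential on S_b/S_0, b <= 1000.

    Bounds: Dt in [1e-5, 3e-3] mm2/s, Dp in [1e-3, 0.5] mm2/s, f in [0, 1].
    Non-convergence returns the best iterate with ``converged=False``.
    """
    sig = _as_voxel(signal, scheme)
    idx = scheme.ivim_indices
    b = scheme.array[idx]
    s0 = sig[0]
    if s0 <= 0:
        raise UnfittableVoxelError("IVIM fit needs S0 > 0")
    usable = sig[idx] > 0
    if usable.sum() < 4:
        raise UnfittableVoxelError("IVIM fit needs at least 4 usable b-values")
    y = sig[idx] / s0

    def resid(theta: np.ndarray) -> np.ndarray:
        return _ivim_model(b, *theta) - y

    def jac(theta: np.ndarray) -> np.ndarray:
        dt, dp, f = theta
        e_t = np.exp(-b * dt)
        e_p = np.exp(-b * (dt + dp))
        d_dt = -b * ((1.0 - f) * e_t + f * e_p)
        d_dp = -b * f * e_p
        d_f = e_p - e_t
        return np.column_stack([d_dt, d_dp, d_f])

    lo = np.array([IVIM_BOUNDS[k][0] for k in ("dt", "dp", "f")])
    hi = np.array([IVIM_BOUNDS[k][1] for k in ("dt", "dp", "f")])
    x0 = np.clip(_ivim_init(b, y), lo, hi)
    sol = least_squares(
        resid, x0, jac=jac, bounds=(lo, hi),
        method="trf", x_scale=np.array([1e-3, 1e-2, 0.1]),
        ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=_MAX_ITER,
    )
    dt, dp, f = (float(v) for v in sol.x)
    flags: list[str] = []
    if f <= 0.01:
        flags.append("dp_nonidentifiable")
    for val, (lo_v, hi_v) in zip((dt, dp, f), (IVIM_BOUNDS[k] for k in ("dt", "dp", "f"))):
        span = hi_v - lo_v
        if val - lo_v <= _BOUND_FLAG_RTOL * span or hi_v - val <= _BOUND_FLAG_RTOL * span:
            if "at_bound" not in flags:
                flags.append("at_bound")
    return FitResult(
        IVIMParams(dt=dt, dp=dp, f=min(max(f, 0.0), 1.0)),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        n_iter=int(sol.nfev),
        flags=tuple(flags),
    )


def rsi_design_matrix(b: np.ndarray, fixed_adcs=RSI_FIXED_ADCS) -> np.ndarray:
    """Design matrix of the fixed-diffusivity decomposition (n_b x 3)."""
    b = np.asarray(b, dtype=float)
    return np.column_stack([np.exp(-b * a) for a in fixed_adcs])


def fit_rsi(signal, scheme: BValueScheme = DEFAULT_SCHEME) -> FitResult:
    """Bounded fit of the three-compartment model on the raw signal, all b.

    The fixed diffusivities make the problem linear in the contributions, so
    the bounded solver lands on the non-negative least-squares optimum;
    fractions are populated by normalizing at b = 0.
    """
    sig = _as_voxel(signal, scheme)
    if not np.any(sig > 0):
        raise UnfittableVoxelError("all-zero signal")
    b = scheme.rsi_subset
    design = rsi_design_matrix(b)

    def resid(c: np.ndarray) -> np.ndarray:
        return design @ c - sig

    def jac(c: np.ndarray) -> np.ndarray:
        return design

    scale = max(float(sig[0]), float(sig.max()))
    x0 = np.full(3, scale / 3.0)
    sol = least_squares(
        resid, x0, jac=jac, bounds=(0.0, np.inf),
        method="trf", ftol=_TOL, xtol=_TOL, gtol=_TOL, max_nfev=_MAX_ITER,
    )
    c1, c2, c3 = (float(max(v, 0.0)) for v in sol.x)
    params = RSIParams(c1=c1, c2=c2, c3=c3)
    s0 = float(sig[0]) if sig[0] > 0 else c1 + c2 + c3
    if c1 + c2 + c3 > 0:
        params = contributions_to_fractions(params, s0=s0)
    return FitResult(
        params,
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.status > 0),
        n_iter=int(sol.nfev),
        flags=(),
    )


_FITTERS = {"mono": fit_mono_adc, "ivim": fit_ivim, "rsi": fit_rsi}


def _params_row(model: str, result: FitResult) -> list[float]:
    p = result.params
    if model == "mono":
        return [p.adc]
    if model == "ivim":
        return [p.dt, p.dp, p.f]
    return [p.c1, p.c2, p.c3, p.c1c2, p.f1, p.f2, p.f3, p.f1f2]


class DWIFitResults:
    """Batch fit results: per-voxel parameter table plus diagnostics.

    Attributes
    ----------
    params : pandas.DataFrame
        One row per voxel, one column per fitted parameter (model units;
        diffusivities in mm2/s).  Unfittable voxels carry NaN rows.
    residual_norm, converged, n_iter : ndarray
        Per-voxel goodness of fit and solver diagnostics.
    flags : list of tuple of str
        Qualitative per-voxel diagnostics.
    """

    def __init__(self, model_name: str, params: pd.DataFrame,
                 residual_norm: np.ndarray, converged: np.ndarray,
                 n_iter: np.ndarray, flags: list[tuple[str, ...]]):
        self.model_name = model_name
        self.params = params
        self.residual_norm = residual_norm
        self.converged = converged
        self.n_iter = n_iter
        self.flags = flags

    @property
    def nobs(self) -> int:
        return len(self.params)

    def mean_params(self) -> pd.Series:
        """ROI-style mean over fitted voxels (NaN rows excluded)."""
        return self.params.mean(skipna=True)

    def summary(self) -> str:
        lines = [
            f"{self.model_name.upper()} fit results",
            "=" * 40,
            f"voxels fitted:        {self.nobs}",
            f"converged:            {int(np.sum(self.converged))}",
            f"flagged:              {sum(1 for fl in self.flags if fl)}",
            f"median residual norm: {np.nanmedian(self.residual_norm):.3e}",
            "-" * 40,
            f"{'parameter':<12}{'mean':>12}{'SD':>12}",
        ]
        for col in self.params.columns:
            lines.append(
                f"{col:<12}{self.params[col].mean():>12.5g}{self.params[col].std():>12.5g}"
            )
        return "\n".join(lines)


class _BatchDWIModel:
    """Shared machinery for the three voxel-batch models."""

    model_name: str

    def __init__(self, signals, scheme: BValueScheme = DEFAULT_SCHEME):
        sig = np.atleast_2d(np.asarray(signals, dtype=float))
        if sig.shape[1] != len(scheme):
            raise InvalidInputError(
                f"signals have {sig.shape[1]} b-values, scheme has {len(scheme)}"
            )
        self.signals = sig
        self.scheme = scheme

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, scheme: BValueScheme = DEFAULT_SCHEME):
        """Build from a DataFrame whose columns are the scheme's b-values."""
        cols = [float(c) for c in frame.columns]
        if cols != list(scheme.values):
            raise InvalidInputError("DataFrame columns must equal the scheme b-values in order")
        return cls(frame.to_numpy(dtype=float), scheme)

    def fit(self) -> DWIFitResults:
        fitter = _FITTERS[self.model_name]
        cols = PARAM_COLUMNS[self.model_name]
        n = self.signals.shape[0]
        rows = np.full((n, len(cols)), np.nan)
        rnorm = np.full(n, np.nan)
        conv = np.zeros(n, dtype=bool)
        n_iter = np.zeros(n, dtype=int)
        flags: list[tuple[str, ...]] = []
        for i in range(n):
            try:
                res = fitter(self.signals[i], self.scheme)
            except UnfittableVoxelError:
                flags.append(("unfittable",))
                continue
            rows[i] = _params_row(self.model_name, res)
            rnorm[i] = res.residual_norm
            conv[i] = res.converged
            n_iter[i] = res.n_iter
            flags.append(res.flags)
        return DWIFitResults(
            self.model_name, pd.DataFrame(rows, columns=cols), rnorm, conv, n_iter, flags
        )


class MonoExponentialModel(_BatchDWIModel):
    """Two-point mono-exponential ADC model over a batch of voxel signals."""

    model_name = "mono"


class IVIMModel(_BatchDWIModel):
    """Bi-exponential intravoxel-incoherent-motion model (Dt, Dp, f)."""

    model_name = "ivim"


class RSIModel(_BatchDWIModel):
    """Three-compartment restriction-spectrum model (C1, C2, C3 + fractions)."""

    model_name = "rsi"


MODELS = {"mono": MonoExponentialModel, "ivim": IVIMModel, "rsi": RSIModel}


def fit_volume(volume, scheme: BValueScheme, model: str,
               mask=None) -> dict[str, np.ndarray]:
    """Voxel-wise fit of a 4-D volume; returns one 3-D map per parameter.

    Parameters
    ----------
    volume
        Array of shape (x, y, z, n_b) with the b-dimension matching
        ``scheme``.
    model
        One of ``"mono"``, ``"ivim"``, ``"rsi"``.
    mask
        Optional 3-D binary mask; voxels outside it (and unfittable voxels)
        are set to NaN.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 4 or vol.shape[-1] != len(scheme):
        raise InvalidInputError(
            f"expected a 4-D volume with {len(scheme)} b-values, got shape {vol.shape}"
        )
    if model not in MODELS:
        raise InvalidInputError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    spatial = vol.shape[:3]
    if mask is None:
        mask_flat = np.ones(int(np.prod(spatial)), dtype=bool)
    else:
        mask = np.asarray(mask)
        if mask.shape != spatial:
            raise InvalidInputError("mask shape does not match the volume grid")
        mask_flat = mask.reshape(-1).astype(bool)

    flat = vol.reshape(-1, vol.shape[-1])
    results = MODELS[model](flat[mask_flat], scheme).fit()
    names = MAP_NAMES[model]
    maps = {}
    for col, name in zip(PARAM_COLUMNS[model], names):
        m = np.full(flat.shape[0], np.nan)
        m[mask_flat] = results.params[col].to_numpy()
        maps[name] = m.reshape(spatial)
    return maps


def grid_search_ivim(signal, scheme: BValueScheme = DEFAULT_SCHEME,
                     n: int = 50) -> tuple[np.ndarray, float]:
    """Dense grid search over the bounded (Dt, Dp, f) box.

    Brute-force reference used to check that the trust-region optimum is at
    least as good (in residual norm) as the best grid point.  Returns the best
    grid triple and its residual norm.
    """
    sig = _as_voxel(signal, scheme)
    idx = scheme.ivim_indices
    b = scheme.array[idx]
    y = sig[idx] / sig[0]
    dts = np.linspace(*IVIM_BOUNDS["dt"], n)
    dps = np.linspace(*IVIM_BOUNDS["dp"], n)
    fs = np.linspace(*IVIM_BOUNDS["f"], n)
    e_t = np.exp(-np.outer(dts, b))                       # (n, nb)
    best = (None, np.inf)
    for j, dp in enumerate(dps):
        e_p = np.exp(-np.outer(dts + dp, b))              # (n, nb)
        for k, f in enumerate(fs):
            pred = (1.0 - f) * e_t + f * e_p
            ss = np.linalg.norm(pred - y, axis=1)
            i = int(np.argmin(ss))
            if ss[i] < best[1]:
                best = (np.array([dts[i], dp, f]), float(ss[i]))
    return best
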