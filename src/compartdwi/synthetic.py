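"""Synthetic phantoms and lesion cohorts with realistic diffusion structure.

No patient data ships with this package; this module generates surrogate
data with the statistical structure the analysis layer assumes.  Three tissue
classes are modelled — malignant lesions, benign lesions and normal
fibroglandular tissue — each with published per-parameter means and SDs for
the IVIM triple (Dt, Dp, f) and the RSI contributions (C1, C2, C3).

Generative law
--------------
Per lesion, true parameters are drawn from Gaussians truncated to the
fitting bounds.  Each voxel's noiseless signal is the IVIM bi-exponential
curve scaled so that its b=0 amplitude equals C1 + C2 + C3 (the b=0 value of
the three-compartment decomposition); magnitude images are then corrupted by
Rician noise.  ADC, the signal fractions and the products are therefore
*emergent* — obtained by fitting, never drawn — which keeps a single
self-consistent signal per voxel across all three fitted models.  Because
one curve cannot lie exactly in both the bi-exponential and the fixed-rate
three-compartment families, the RSI fit of a noiseless voxel converges to
the non-negative least-squares projection of its curve, not to the drawn
contributions; the drawn (C1, C2, C3) set the amplitude and serve as
class-separating scale parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .bvalues import BValueScheme, DEFAULT_SCHEME
from .exceptions import ConfigurationError, InvalidInputError
from .fitting import IVIM_BOUNDS, IVIMModel, MonoExponentialModel, RSIModel
from .signal_models import IVIMParams, ivim_signal

#: ROI-table parameter columns, in reporting order.
PARAMETER_COLUMNS = [
    "ADC", "Dt", "Dp", "f",
    "C1", "C2", "C3", "C1C2", "F1", "F2", "F3", "F1F2",
]

#: Generative parameter names (everything else is emergent from fitting).
GENERATIVE_PARAMS = ["Dt", "Dp", "f", "C1", "C2", "C3"]

_TRUNCATION_BOUNDS = {
    "Dt": IVIM_BOUNDS["dt"],
    "Dp": IVIM_BOUNDS["dp"],
    "f": IVIM_BOUNDS["f"],
    "C1": (0.0, np.inf),
    "C2": (0.0, np.inf),
    "C3": (0.0, np.inf),
}


@dataclass(frozen=True)
class TissueClassSpec:
    """Per-class generative moments (means and SDs in model units).

    ``adc_mean``/``adc_sd`` are *reference* moments of the emergent ADC
    distribution (mm2/s), used only by closed-form oracles, never drawn.
    """

    name: str
    means: dict[str, float]
    sds: dict[str, float]
    adc_mean: float = float("nan")
    adc_sd: float = float("nan")

    def __post_init__(self) -> None:
        for p in GENERATIVE_PARAMS:
            if p not in self.means or p not in self.sds:
                raise InvalidInputError(f"class {self.name!r} missing moments for {p}")
            if self.sds[p] <= 0:
                raise InvalidInputError(f"class {self.name!r}: SD of {p} must be > 0")
            lo, hi = _TRUNCATION_BOUNDS[p]
            if not lo <= self.means[p] <= hi:
                raise InvalidInputError(
                    f"class {self.name!r}: mean of {p} outside fitting bounds"
                )


# Published group descriptives of a breast multi-b-value DWI cohort
# (41 benign / 116 malignant lesions plus contralateral normal tissue).
# Diffusivities in mm2/s.  The benign C2 SD is printed ambiguously in the
# source table ("1.00080"); 1.000 is used.
TISSUE_CLASSES: dict[str, TissueClassSpec] = {
    "malignant": TissueClassSpec(
        name="malignant",
        means={"Dt": 0.662e-3, "Dp": 0.022, "f": 0.235,
               "C1": 0.540, "C2": 1.826, "C3": 0.161},
        sds={"Dt": 0.106e-3, "Dp": 0.006, "f": 0.036,
             "C1": 0.250, "C2": 0.778, "C3": 0.159},
        adc_mean=0.955e-3, adc_sd=0.140e-3,
    ),
    "benign": TissueClassSpec(
        name="benign",
        means={"Dt": 0.940e-3, "Dp": 0.019, "f": 0.256,
               "C1": 0.233, "C2": 1.972, "C3": 0.329},
        sds={"Dt": 0.304e-3, "Dp": 0.007, "f": 0.059,
             "C1": 0.195, "C2": 1.000, "C3": 0.345},
        adc_mean=1.357e-3, adc_sd=0.367e-3,
    ),
    "normal": TissueClassSpec(
        name="normal",
        means={"Dt": 0.868e-3, "Dp": 0.025, "f": 0.213,
               "C1": 0.119, "C2": 0.894, "C3": 0.215},
        sds={"Dt": 0.420e-3, "Dp": 0.007, "f": 0.048,
             "C1": 0.102, "C2": 0.444, "C3": 0.110},
        adc_mean=1.362e-3, adc_sd=0.407e-3,
    ),
}

#: Default cohort sizes (lesion counts of the emulated study; one normal
#: control region per benign lesion).
DEFAULT_COHORT = {"malignant": 116, "benign": 41, "normal": 41}

#: Default b=0 signal-to-noise ratio, typical of breast DWI.
DEFAULT_SNR = 50.0

#: Default within-lesion multiplicative parameter jitter (heterogeneity).
DEFAULT_JITTER = 0.05


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_class_parameters(spec: TissueClassSpec, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` truncated-Gaussian parameter sets for one tissue class.

    Sampling is by rejection against the fitting bounds, so every draw is
    guaranteed fittable.
    """
    rng = _rng(seed)
    out = {}
    for p in GENERATIVE_PARAMS:
        lo, hi = _TRUNCATION_BOUNDS[p]
        mu, sd = spec.means[p], spec.sds[p]
        vals = np.empty(n)
        remaining = np.arange(n)
        while remaining.size:
            cand = rng.normal(mu, sd, size=remaining.size)
            ok = (cand >= lo) & (cand <= hi)
            vals[remaining[ok]] = cand[ok]
            remaining = remaining[~ok]
        out[p] = vals
    return pd.DataFrame(out)


def voxel_signal(dt: float, dp: float, f: float,
                 c1: float, c2: float, c3: float,
                 scheme: BValueScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Noiseless voxel signal: IVIM decay scaled to S(0) = C1 + C2 + C3."""
    s0 = c1 + c2 + c3
    return np.asarray(ivim_signal(IVIMParams(dt=dt, dp=dp, f=f), s0, scheme.array))


def add_rician_noise(signal, snr: float, seed, s0: float | None = None) -> np.ndarray:
    """Corrupt a magnitude signal with Rician noise.

    Returns ``sqrt((S + n1)^2 + n2^2)`` with n1, n2 independent zero-mean
    Gaussians of SD ``S0/snr``, where S0 is the b=0 entry (first element
    along the last axis) unless an explicit reference amplitude ``s0`` is
    given.  ``snr=inf`` returns the input unchanged.
    """
    sig = np.asarray(signal, dtype=float)
    if snr <= 0:
        raise InvalidInputError(f"snr must be > 0, got {snr}")
    if np.isinf(snr):
        return sig.copy()
    rng = _rng(seed)
    sd = np.asarray(s0, dtype=float) / snr if s0 is not None else sig[..., :1] / snr
    n1 = rng.normal(0.0, 1.0, size=sig.shape) * sd
    n2 = rng.normal(0.0, 1.0, size=sig.shape) * sd
    return np.sqrt((sig + n1) ** 2 + n2 ** 2)


@dataclass(frozen=True)
class LesionGeometry:
    """A spherical lesion: voxel-grid center, radius (voxels), tissue class."""

    center: tuple[float, float, float]
    radius: float
    tissue_class: str

    def __post_init__(self) -> None:
        if self.radius < 2:
            raise InvalidInputError("lesion radius must be >= 2 voxels")
        if self.tissue_class not in TISSUE_CLASSES:
            raise InvalidInputError(f"unknown tissue class {self.tissue_class!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, noise and seeding of a digital DWI phantom."""

    shape: tuple[int, int, int] = (32, 32, 16)
    lesions: tuple[LesionGeometry, ...] = (
        LesionGeometry(center=(10.0, 10.0, 8.0), radius=4.0, tissue_class="malignant"),
        LesionGeometry(center=(22.0, 22.0, 8.0), radius=4.0, tissue_class="benign"),
    )
    background_class: str = "normal"
    snr: float = DEFAULT_SNR
    seed: int = 0
    jitter: float = DEFAULT_JITTER
    scheme: BValueScheme = field(default_factory=BValueScheme)

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise InvalidInputError("snr must be > 0")
        for les in self.lesions:
            c, r = np.asarray(les.center), les.radius
            if np.any(c - r < 0) or np.any(c + r > np.asarray(self.shape)):
                raise ConfigurationError("lesion does not fit inside the grid")


def default_lesions(shape) -> tuple[LesionGeometry, ...]:
    """One malignant and one benign sphere placed to fit the given grid."""
    sx, sy, sz = shape
    radius = max(2.0, min(shape) / 4.0)
    return (
        LesionGeometry(center=(0.3 * sx, 0.3 * sy, 0.5 * sz), radius=radius,
                       tissue_class="malignant"),
        LesionGeometry(center=(0.7 * sx, 0.7 * sy, 0.5 * sz), radius=radius,
                       tissue_class="benign"),
    )


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


def generate_phantom(config: PhantomConfig):
    """Simulate a 4-D DWI phantom.

    Returns ``(volume, truth_maps, masks)``: the noisy 4-D volume, one 3-D
    ground-truth map per generative parameter (plus ``S0``), and one boolean
    lesion mask per lesion (keys ``lesion_00``...).  Lesions are spheres; a
    configuration with overlapping lesions is rejected.  Deterministic given
    the seed.
    """
    rng = _rng(config.seed)
    shape = tuple(config.shape)
    masks = {
        f"lesion_{i:02d}": _sphere_mask(shape, les.center, les.radius)
        for i, les in enumerate(config.lesions)
    }
    occupancy = np.zeros(shape, dtype=int)
    for m in masks.values():
        occupancy += m
    if np.any(occupancy > 1):
        raise ConfigurationError("lesions overlap")

    truth = {p: np.empty(shape) for p in GENERATIVE_PARAMS}
    regions = [(~(occupancy > 0), TISSUE_CLASSES[config.background_class])]
    regions += [
        (masks[f"lesion_{i:02d}"], TISSUE_CLASSES[les.tissue_class])
        for i, les in enumerate(config.lesions)
    ]
    for region_mask, spec in regions:
        n = int(region_mask.sum())
        base = draw_class_parameters(spec, 1, rng).iloc[0]
        for p in GENERATIVE_PARAMS:
            jit = 1.0 + config.jitter * rng.standard_normal(n)
            lo, hi = _TRUNCATION_BOUNDS[p]
            truth[p][region_mask] = np.clip(base[p] * np.abs(jit), lo, hi)

    truth["S0"] = truth["C1"] + truth["C2"] + truth["C3"]
    b = config.scheme.array
    flat = {p: truth[p].reshape(-1) for p in truth}
    decay = (
        (1.0 - flat["f"])[:, None] * np.exp(-np.outer(flat["Dt"], b))
        + flat["f"][:, None] * np.exp(-np.outer(flat["Dt"] + flat["Dp"], b))
    )
    clean = flat["S0"][:, None] * decay
    noisy = add_rician_noise(clean, config.snr, rng)
    volume = noisy.reshape(shape + (len(config.scheme),))
    return volume, truth, masks


def generate_cohort(
    n_malignant: int = DEFAULT_COHORT["malignant"],
    n_benign: int = DEFAULT_COHORT["benign"],
    n_normal: int = DEFAULT_COHORT["normal"],
    specs: dict[str, TissueClassSpec] | None = None,
    voxels_per_lesion: int = 50,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    scheme: BValueScheme = DEFAULT_SCHEME,
) -> pd.DataFrame:
    """Simulate a lesion cohort and fit all three models per lesion.

    Per lesion: draw true parameters from the class's truncated Gaussians,
    jitter them per voxel (multiplicative, emulating within-lesion
    heterogeneity), simulate Rician-noisy voxel signals, fit the
    mono-exponential, IVIM and RSI models voxel-wise, and record the
    ROI-mean fitted parameters.  Products (C1C2, F1F2) are per-voxel
    products averaged over the ROI.

    Returns a DataFrame with one row per lesion: ``lesion_id``,
    ``tissue_class``, the 12 fitted parameters, and the drawn generative
    truths as ``true_*`` columns.  Pure function of its arguments.
    """
    specs = specs or TISSUE_CLASSES
    counts = {"malignant": n_malignant, "benign": n_benign, "normal": n_normal}
    for name, n in counts.items():
        if n and n < 2:
            raise InvalidInputError(f"need >= 2 lesions of class {name!r} (or 0)")
    rng = _rng(seed)
    records = []
    lesion_id = 0
    for cls_name, n_lesions in counts.items():
        if not n_lesions:
            continue
        spec = specs[cls_name]
        drawn = draw_class_parameters(spec, n_lesions, rng)
        for i in range(n_lesions):
            base = drawn.iloc[i]
            vox = {}
            for p in GENERATIVE_PARAMS:
                jit = 1.0 + jitter * rng.standard_normal(voxels_per_lesion)
                lo, hi = _TRUNCATION_BOUNDS[p]
                vox[p] = np.clip(base[p] * np.abs(jit), lo, hi)
            s0 = vox["C1"] + vox["C2"] + vox["C3"]
            b = scheme.array
            decay = (
                (1.0 - vox["f"])[:, None] * np.exp(-np.outer(vox["Dt"], b))
                + vox["f"][:, None] * np.exp(-np.outer(vox["Dt"] + vox["Dp"], b))
            )
            signals = add_rician_noise(s0[:, None] * decay, snr, rng)

            mono = MonoExponentialModel(signals, scheme).fit().mean_params()
            ivim = IVIMModel(signals, scheme).fit().mean_params()
            rsi = RSIModel(signals, scheme).fit().mean_params()
            rec = {
                "lesion_id": f"L{lesion_id:04d}",
                "tissue_class": cls_name,
                "ADC": mono["adc"],
                "Dt": ivim["dt"], "Dp": ivim["dp"], "f": ivim["f"],
                "C1": rsi["c1"], "C2": rsi["c2"], "C3": rsi["c3"],
                "C1C2": rsi["c1c2"],
                "F1": rsi["f1"], "F2": rsi["f2"], "F3": rsi["f3"],
                "F1F2": rsi["f1f2"],
            }
            rec.update({f"true_{p}": base[p] for p in GENERATIVE_PARAMS})
            records.append(rec)
            lesion_id += 1
    return pd.DataFrame(records)


def perturb_mask(mask, boundary_flip_prob: float, seed) -> np.ndarray:
    """Emulate a second reader by flipping boundary voxels of an ROI mask.

    Boundary voxels are mask voxels adjacent to background plus background
    voxels adjacent to the mask (6-connectivity); each flips independently
    with the given probability.  Interior and far-field voxels never change.
    """
    if not 0.0 <= boundary_flip_prob <= 1.0:
        raise InvalidInputError("boundary_flip_prob must be in [0, 1]")
    mask = np.asarray(mask).astype(bool)
    rng = _rng(seed)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    inner = mask & ~ndimage.binary_erosion(mask, structure)
    outer = ndimage.binary_dilation(mask, structure) & ~mask
    boundary = inner | outer
    flips = boundary & (rng.random(mask.shape) < boundary_flip_prob)
    return mask ^ flips
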