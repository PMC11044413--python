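"""Volume and sidecar I/O (NIfTI volumes, FSL-style .bval tables, CSV)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .bvalues import BValueScheme
from .exceptions import InvalidInputError


def read_bvals(path) -> np.ndarray:
    """Read a b-value table: one whitespace-separated row or one value per line."""
    text = Path(path).read_text().split()
    if not text:
        raise InvalidInputError(f"empty b-value file: {path}")
    try:
        return np.array([float(t) for t in text])
    except ValueError as exc:
        raise InvalidInputError(f"non-numeric entry in b-value file {path}") from exc


def write_bvals(path, scheme: BValueScheme) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in scheme.values) + "\n")


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a NIfTI volume as float32 (NaN sentinel preserved)."""
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def save_mask(path, mask: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine), str(path))


def save_parameter_maps(outdir, maps: dict[str, np.ndarray], prefix: str,
                        affine: np.ndarray | None = None) -> list[Path]:
    """Write one float32 NIfTI per parameter map; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, data in maps.items():
        p = outdir / f"{prefix}_{name}.nii.gz"
        save_volume(p, data, affine)
        paths.append(p)
    return paths
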