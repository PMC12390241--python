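"""File interchange: NIfTI volumes, 16-bit PNGs, raw k-space with sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

__all__ = ["save_nifti", "load_nifti", "save_png16", "save_mask_png",
           "save_kspace", "load_kspace", "save_kspace_raw", "load_kspace_raw"]


def save_nifti(array: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), np.eye(4)),
             str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_png16(magnitude: np.ndarray, path) -> None:
    """Magnitude image as 16-bit grayscale PNG, scaled to the full range."""
    a = np.asarray(magnitude, dtype=float)
    top = a.max()
    scaled = np.zeros_like(a) if top == 0 else a / top
    img = (np.clip(scaled, 0, 1) * 65535).astype(np.uint16)
    Image.fromarray(img).save(str(path))


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(str(path))


def save_kspace(kspace_data: np.ndarray, stem) -> None:
    """Complex k-space as paired real/imag NIfTI volumes (<stem>_real.nii.gz,
    <stem>_imag.nii.gz)."""
    stem = str(stem)
    save_nifti(np.asarray(kspace_data).real, stem + "_real.nii.gz")
    save_nifti(np.asarray(kspace_data).imag, stem + "_imag.nii.gz")


def load_kspace(stem) -> np.ndarray:
    stem = str(stem)
    return load_nifti(stem + "_real.nii.gz") + 1j * load_nifti(stem + "_imag.nii.gz")


def save_kspace_raw(kspace_data: np.ndarray, path, noise_sigma: float = 0.0,
                    seed: int | None = None) -> None:
    """Raw complex64 binary plus a JSON sidecar recording shape and provenance."""
    path = Path(path)
    data = np.asarray(kspace_data, dtype=np.complex64)
    data.tofile(path)
    sidecar = {"n": int(data.shape[0]), "dtype": "complex64",
               "noise_sigma": float(noise_sigma), "seed": seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_kspace_raw(path):
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=np.complex64).reshape(meta["n"], meta["n"])
    return data, meta
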