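"""NIfTI I/O and run manifests.

All outputs are written on the input grid (same shape and affine); no
resampling happens anywhere in the package. Masks whose affine disagrees
with the DWI beyond a small tolerance are rejected rather than resampled.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

AFFINE_ATOL = 1e-4


def read_volume(path):
    """Load a NIfTI image; returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_volume(path, data, affine) -> None:
    """Write a NIfTI-1 image, preserving the array dtype."""
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.Nifti1Image(data, affine).to_filename(str(path))


def check_affine(affine_a, affine_b, what: str = "image") -> None:
    if not np.allclose(affine_a, affine_b, atol=AFFINE_ATOL):
        raise ValueError(
            f"{what} affine differs from the DWI affine by more than "
            f"{AFFINE_ATOL}; co-register inputs upstream (no resampling here)"
        )


def read_mask(path, reference_affine, shape=None):
    """Load a binary mask and verify it sits on the reference grid."""
    data, affine = read_volume(path)
    check_affine(reference_affine, affine, what=f"mask {path}")
    if shape is not None and data.shape != shape:
        raise ValueError(f"mask {path} shape {data.shape} != DWI grid {shape}")
    return data > 0


def sha256sum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: dict | None = None,
                   seed: int | None = None) -> Path:
    """Record the run configuration for reproducibility.

    Writes ``manifest.json`` with the config, the master seed, the package
    version, and a sha256 checksum per input file. Two runs with identical
    manifests produce identical outputs (fitting is deterministic).
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "fernet-fw",
        "version": __version__,
        "seed": seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in config.items()},
        "input_checksums": {
            name: sha256sum(p) for name, p in (inputs or {}).items()
            if p is not None and Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
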