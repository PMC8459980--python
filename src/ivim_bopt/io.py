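"""NIfTI / .bval / JSON-sidecar input-output for stacks and parameter maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .ivim import PARAM_NAMES, ParameterMaps
from .phantom import TraceStack

__all__ = [
    "save_stack",
    "load_stack",
    "read_bvals",
    "write_bvals",
    "save_parameter_maps",
]


def write_bvals(bvalues, path) -> None:
    """FSL-style whitespace-separated b values on a single line."""
    Path(path).write_text(" ".join(f"{b:g}" for b in np.asarray(bvalues).ravel()) + "\n")


def read_bvals(path) -> np.ndarray:
    return np.array([float(tok) for tok in Path(path).read_text().split()])


def save_stack(stack: TraceStack, prefix, metadata: dict | None = None) -> None:
    """Write <prefix>.nii.gz (x, y, z, b*rep), <prefix>.bval and <prefix>.json.

    The 4th NIfTI axis concatenates repetitions within each b value
    (b-major ordering); the sidecar records the layout plus any metadata
    (scheme, noise configuration, seed) needed to reproduce the run.
    """
    prefix = Path(prefix)
    nb, nr = stack.data.shape[3], stack.n_reps
    flat = stack.data.reshape(stack.shape + (nb * nr,))
    nib.save(nib.Nifti1Image(flat.astype(np.float32), affine=np.eye(4)),
             str(prefix) + ".nii.gz")
    write_bvals(np.repeat(stack.bvalues, nr), str(prefix) + ".bval")
    sidecar = {
        "bvalues": [float(b) for b in stack.bvalues],
        "n_reps": nr,
        "axis4_order": "b-major (all repetitions of b[0], then b[1], ...)",
    }
    sidecar.update(metadata or {})
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_stack(prefix) -> TraceStack:
    prefix = Path(prefix)
    img = nib.load(str(prefix) + ".nii.gz")
    sidecar = json.loads(Path(str(prefix) + ".json").read_text())
    bvalues = np.asarray(sidecar["bvalues"], dtype=float)
    nr = int(sidecar["n_reps"])
    data = np.asarray(img.dataobj, dtype=float)
    data = data.reshape(data.shape[:3] + (bvalues.size, nr))
    return TraceStack(data=data, bvalues=bvalues)


def save_parameter_maps(maps: ParameterMaps, prefix) -> None:
    """One NIfTI volume per parameter (f, D, Dstar, S0) plus a convergence mask."""
    prefix = Path(prefix)
    for name in PARAM_NAMES:
        nib.save(
            nib.Nifti1Image(maps.get(name).astype(np.float32), affine=np.eye(4)),
            f"{prefix}_{name}.nii.gz",
        )
    nib.save(
        nib.Nifti1Image(maps.converged.astype(np.uint8), affine=np.eye(4)),
        f"{prefix}_converged.nii.gz",
    )
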