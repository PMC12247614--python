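"""NIfTI + JSON-sidecar I/O for synthetic measurements."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .engine import SyntheticMeasurement


def save_measurement(path, meas: SyntheticMeasurement, pixel_size_mm: float = 0.25) -> None:
    """Write a measurement as an (x, y, 1, timepoint) NIfTI plus sidecar."""
    path = Path(path)
    data = np.moveaxis(meas.images, 0, -1)[:, :, None, :]  # (pe, ro, 1, t)
    affine = np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    sidecar = {
        "parity": meas.parity,
        "t_start_s": meas.t_start_s,
        "meta": {k: v for k, v in meas.meta.items() if isinstance(v, (int, float, str))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_measurement(path) -> SyntheticMeasurement:
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    images = np.moveaxis(vol[:, :, 0, :], -1, 0)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return SyntheticMeasurement(
        images=images,
        parity=sidecar["parity"],
        t_start_s=sidecar["t_start_s"],
        meta=sidecar.get("meta", {}),
    )
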