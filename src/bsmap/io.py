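"""File interchange: HDF5 FID arrays, NIfTI maps and CSV tables.

Layouts
-------
HDF5 CSI container::

    /fids            complex64, shape (nx, ny, nz, nt)
    /dwell_s         scalar
    /freq_offset_hz  scalar (receiver center offset)
    attrs            free-form protocol echo (JSON-serializable values)

NIfTI maps are float32 gamma-B1 in Hz on the CSI grid, with voxel size in mm
in the affine; a JSON sidecar carries method, omega_RF, B-tilde, thresholds
and exclusion counts.  Prior-knowledge tables are CSV with columns
``name, offset_hz, amplitude, damping_hz, phase_rad, multiplet_n, j_hz``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .estimators import B1Map, EXCLUSION_CODES
from .spectra import Peak, SpectrumModel


def write_fids_h5(path, fids: np.ndarray, dwell: float,
                  freq_offset_hz: float = 0.0, attrs: dict | None = None) -> None:
    fids = np.asarray(fids)
    if fids.ndim != 4:
        raise ValueError("fids must have shape (nx, ny, nz, nt)")
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=fids.astype(np.complex64))
        f.create_dataset("dwell_s", data=float(dwell))
        f.create_dataset("freq_offset_hz", data=float(freq_offset_hz))
        for key, val in (attrs or {}).items():
            f.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val


def read_fids_h5(path) -> tuple[np.ndarray, float, float, dict]:
    with h5py.File(path, "r") as f:
        fids = f["fids"][()]
        dwell = float(f["dwell_s"][()])
        offset = float(f["freq_offset_hz"][()])
        attrs = dict(f.attrs)
    return fids, dwell, offset, attrs


def write_b1map_nifti(path, b1_map: B1Map, voxel_size_mm=(30.0, 25.0, 15.0)) -> None:
    path = Path(path)
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(b1_map.masked_values().astype(np.float32), affine)
    nib.save(img, path)
    sidecar = dict(b1_map.meta)
    sidecar["units"] = "Hz (gamma-B1)"
    sidecar["exclusion_codes"] = {str(int(c)): name
                                  for c, name in EXCLUSION_CODES.items()}
    base = path.name[:-len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    (path.parent / f"{base}.json").write_text(json.dumps(sidecar, indent=2))


def read_b1map_nifti(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    img = nib.load(path)
    base = path.name[:-len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    sidecar_path = path.parent / f"{base}.json"
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return np.asarray(img.dataobj, dtype=float), meta


def write_prior_csv(path, model: SpectrumModel) -> None:
    rows = [{
        "name": p.name, "offset_hz": p.offset, "amplitude": p.amplitude,
        "damping_hz": p.damping, "phase_rad": p.phase,
        "multiplet_n": p.n_lines, "j_hz": p.j_hz,
    } for p in model.peaks]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prior_csv(path) -> SpectrumModel:
    df = pd.read_csv(path)
    peaks = [Peak(name=str(r["name"]), offset=float(r["offset_hz"]),
                  amplitude=float(r.get("amplitude", 1.0)),
                  damping=float(r["damping_hz"]),
                  phase=float(r.get("phase_rad", 0.0)),
                  n_lines=int(r.get("multiplet_n", 1)),
                  j_hz=float(r.get("j_hz", 0.0)))
             for _, r in df.iterrows()]
    return SpectrumModel(peaks=tuple(peaks))
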