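"""HDF5 fixture layout and NIfTI export.

Layout (one file per acquired plane or small volume):

    /shots/{i}/data   complex (n_coils, n_pe, n_x)
    /shots/{i}/mask   bool (n_pe,)
    /navigators/{i}   complex (n_coils, w, w)
    /calibration      complex (n_coils, w, w)
    /truth/image      complex (n_pe, n_x)          [optional]
    /truth/sens       complex (n_coils, n_pe, n_x) [optional]
    /truth/phases     float (n_shots, n_pe, n_x)   [optional]

Root attributes: n_seg, seg_indices, pf, ordering, nav_window.
"""

from __future__ import annotations

import h5py
import nibabel as nib
import numpy as np

from .synth import KSpaceShotSet, SamplingScheme


def save_shotset(
    path: str,
    shotset: KSpaceShotSet,
    truth_image: np.ndarray | None = None,
    truth_sens: np.ndarray | None = None,
    truth_phases: np.ndarray | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        for i in range(shotset.n_shots):
            grp = f.create_group(f"shots/{i}")
            grp.create_dataset("data", data=shotset.data[i])
            grp.create_dataset("mask", data=shotset.masks[i])
            f.create_dataset(f"navigators/{i}", data=shotset.navigators[i])
        f.create_dataset("calibration", data=shotset.calibration)
        truth = {"image": truth_image, "sens": truth_sens, "phases": truth_phases}
        for name, arr in truth.items():
            if arr is not None:
                f.create_dataset(f"truth/{name}", data=arr)
        f.attrs["n_seg"] = shotset.scheme.n_seg
        f.attrs["seg_indices"] = shotset.scheme.seg_indices
        f.attrs["pf"] = shotset.scheme.pf
        f.attrs["ordering"] = shotset.scheme.ordering
        f.attrs["nav_window"] = shotset.nav_window
        f.attrs["n_pe"] = shotset.scheme.n_pe


def load_shotset(path: str) -> tuple[KSpaceShotSet, dict]:
    """Read a fixture file; returns (shotset, truth dict of optional arrays)."""
    with h5py.File(path, "r") as f:
        n_shots = len(f["shots"])
        data = np.stack([f[f"shots/{i}/data"][()] for i in range(n_shots)])
        masks = np.stack([f[f"shots/{i}/mask"][()] for i in range(n_shots)])
        navs = np.stack([f[f"navigators/{i}"][()] for i in range(n_shots)])
        calib = f["calibration"][()]
        scheme = SamplingScheme(
            n_pe=int(f.attrs["n_pe"]),
            n_seg=int(f.attrs["n_seg"]),
            seg_indices=np.asarray(f.attrs["seg_indices"]),
            pf=float(f.attrs["pf"]),
            ordering=str(f.attrs["ordering"]),
        )
        truth = {}
        if "truth" in f:
            for name in f["truth"]:
                truth[name] = f[f"truth/{name}"][()]
        shotset = KSpaceShotSet(
            data=data,
            masks=masks.astype(bool),
            navigators=navs,
            calibration=calib,
            scheme=scheme,
            nav_window=int(f.attrs["nav_window"]),
        )
    return shotset, truth


def save_nifti(path: str, image: np.ndarray, voxel_mm: float = 1.0) -> None:
    """Write a (stack of) 2D plane(s) as NIfTI; complex input is saved as magnitude."""
    arr = np.abs(image) if np.iscomplexobj(image) else np.asarray(image)
    if arr.ndim == 2:
        arr = arr[..., None]
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), path)


def load_nifti(path: str) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj)
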