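"""File I/O: hierarchical raw-data container (HDF5) and NIfTI volumes.

The raw container is a self-describing HDF5 file loosely following ISMRMRD
naming: ``/data/kspace`` (echo x spoke x sample, complex), trajectory
arrays under ``/trajectory``, optional calibration FIDs, sequence metadata
as attributes, and a provenance block (tool version, seed, config hash).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import nibabel as nib
import numpy as np

from . import __version__
from .phantom import KSpaceData, SequenceParams
from .trajectory import RadialTrajectory

__all__ = ["RawDataContainer", "write_container", "read_container",
           "write_nifti", "read_nifti"]


@dataclass
class RawDataContainer:
    """In-memory image of the raw-data file."""

    kspace: KSpaceData
    sequence: SequenceParams
    calibration_fid: np.ndarray | None = None
    calibration_dwell_s: float | None = None
    provenance: dict | None = None


def write_container(path, container: RawDataContainer) -> None:
    k = container.kspace
    with h5py.File(path, "w") as fh:
        data = fh.create_group("data")
        data.create_dataset("kspace", data=k.data)
        data.attrs["dims"] = "echo,spoke,sample"
        traj = fh.create_group("trajectory")
        traj.create_dataset("directions", data=k.traj.directions)
        traj.create_dataset("order", data=k.traj.order)
        traj.create_dataset("k_coords", data=k.traj.k_coords)
        traj.attrs["samples_per_spoke"] = k.traj.samples_per_spoke
        traj.attrs["spoke_style"] = k.traj.spoke_style
        traj.attrs["units"] = "cycles/voxel, Nyquist at 0.5"
        seq = fh.create_group("sequence")
        for key, val in (
            ("te_ms", list(container.sequence.te_ms)),
            ("tr_ms", container.sequence.tr_ms),
            ("flip_dissolved_deg", container.sequence.flip_dissolved_deg),
            ("flip_gas_deg", container.sequence.flip_gas_deg),
            ("n_dummy", container.sequence.n_dummy),
            ("bandwidth_hz", container.sequence.bandwidth_hz),
        ):
            seq.attrs[key] = val
        if container.calibration_fid is not None:
            cal = fh.create_group("calibration")
            cal.create_dataset("fid", data=container.calibration_fid)
            cal.attrs["dwell_s"] = container.calibration_dwell_s or 0.0
        prov = dict(container.provenance or {})
        prov.setdefault("tool", "xerecon")
        prov.setdefault("version", __version__)
        fh.attrs["provenance"] = json.dumps(prov)


def read_container(path) -> RawDataContainer:
    with h5py.File(path, "r") as fh:
        data = fh["data/kspace"][()]
        tg = fh["trajectory"]
        traj = RadialTrajectory(
            directions=tg["directions"][()],
            order=tg["order"][()],
            samples_per_spoke=int(tg.attrs["samples_per_spoke"]),
            k_coords=tg["k_coords"][()],
            spoke_style=str(tg.attrs["spoke_style"]),
        )
        sa = fh["sequence"].attrs
        seq = SequenceParams(
            te_ms=tuple(float(t) for t in sa["te_ms"]),
            tr_ms=float(sa["tr_ms"]),
            flip_dissolved_deg=float(sa["flip_dissolved_deg"]),
            flip_gas_deg=float(sa["flip_gas_deg"]),
            n_dummy=int(sa["n_dummy"]),
            bandwidth_hz=float(sa["bandwidth_hz"]),
        )
        fid = dwell = None
        if "calibration" in fh:
            fid = fh["calibration/fid"][()]
            dwell = float(fh["calibration"].attrs["dwell_s"])
        prov = json.loads(fh.attrs.get("provenance", "{}"))
    kspace = KSpaceData(data=data, te_ms=seq.te_ms, traj=traj)
    return RawDataContainer(
        kspace=kspace, sequence=seq, calibration_fid=fid,
        calibration_dwell_s=dwell, provenance=prov,
    )


def write_nifti(path, volume: np.ndarray, voxel_mm=(12.5, 12.5, 12.5)) -> None:
    """Write a (possibly complex) volume as NIfTI; complex data as magnitude.

    The affine is diagonal with the FOV-derived voxel size in mm.
    """
    vol = np.asarray(volume)
    if np.iscomplexobj(vol):
        vol = np.abs(vol)
    affine = np.diag([*voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)
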