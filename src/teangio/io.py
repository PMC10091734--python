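"""HDF5 k-space containers, NIfTI series output, and YAML configuration."""

from __future__ import annotations

import numpy as np
import yaml

from .phantom import RadialKspace, RadialTrajectory
from .protocol import build_protocol, hadamard_encoding
from .recon import AngioSeries

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_series_nifti",
    "save_mask_nifti",
    "load_config",
]


def save_kspace(path: str, k: RadialKspace) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=k.samples, compression="gzip")
        g = f.create_group("trajectory")
        g.create_dataset("angles", data=k.trajectory.angles)
        g.create_dataset("kx", data=k.trajectory.kx)
        g.create_dataset("ky", data=k.trajectory.ky)
        g.attrs["spokes_per_frame"] = k.trajectory.spokes_per_frame
        f.attrs["protocol"] = k.protocol.name
        for key, val in k.meta.items():
            if val is not None:
                f.attrs[f"meta_{key}"] = val


def load_kspace(path: str) -> RadialKspace:
    import h5py

    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        traj = RadialTrajectory(
            angles=f["trajectory/angles"][()],
            kx=f["trajectory/kx"][()],
            ky=f["trajectory/ky"][()],
            spokes_per_frame=int(f["trajectory"].attrs["spokes_per_frame"]),
        )
        protocol = build_protocol(str(f.attrs["protocol"]))
        meta = {
            key[5:]: f.attrs[key] for key in f.attrs if key.startswith("meta_")
        }
    scheme = hadamard_encoding(protocol.n_blocks)
    return RadialKspace(
        samples=samples, trajectory=traj, protocol=protocol, scheme=scheme, meta=meta
    )


def _nifti(img: np.ndarray):
    import nibabel as nib

    return nib.Nifti1Image(np.asarray(img, dtype=np.float32), affine=np.eye(4))


def save_series_nifti(path: str, series: AngioSeries) -> None:
    """Magnitude series as [x, y, 1, t] NIfTI."""
    data = np.moveaxis(series.images, 0, -1)[:, :, None, :]
    _nifti(data).to_filename(path)


def save_mask_nifti(path: str, mask: np.ndarray) -> None:
    _nifti(np.asarray(mask, dtype=np.float32)).to_filename(path)


def load_config(path: str) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}
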