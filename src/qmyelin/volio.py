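"""NIfTI-1 volume I/O with a light provenance wrapper."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeRecord", "read_volume", "write_volume", "check_same_grid"]


@dataclass
class VolumeRecord:
    """A volume plus its affine and unit/modality tags.

    The units string rides in the NIfTI ``descrip`` header field so that
    round trips preserve it without sidecar files.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    units: str = ""
    modality: str = ""
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")


def write_volume(record: VolumeRecord, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(record.data), record.affine)
    descrip = f"{record.modality}|{record.units}" if (
        record.modality or record.units) else ""
    img.header["descrip"] = descrip.encode()[:79]
    img.to_filename(str(path))
    return path


def read_volume(path) -> VolumeRecord:
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(
            "latin1")
    except Exception as exc:
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    modality, _, units = descrip.partition("|")
    return VolumeRecord(data=data, affine=affine, units=units,
                        modality=modality)


def check_same_grid(a: VolumeRecord, b: VolumeRecord, atol=1e-6) -> None:
    """Raise when two records are not on the same voxel grid."""
    if a.data.shape[:3] != b.data.shape[:3]:
        raise ValueError("volume shapes differ")
    if not np.allclose(a.affine, b.affine, atol=atol):
        raise ValueError("volume affines differ")
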