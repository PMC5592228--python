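"""MT image stacks (M0 + per-offset volumes) and their NIfTI serialization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .acquisition import MTAcquisition


class StackError(ValueError):
    """Raised for inconsistent image stacks or on-disk layouts."""


@dataclass
class MTImageStack:
    """One subject's MT experiment: M0 volume, per-offset volumes, ROI masks.

    All volumes share one grid and affine.  ``t1_map`` and ``t2f_map`` carry
    the free-pool relaxation times from separate relaxometry experiments;
    they are required by the model inversion, which fixes T1f (and by default
    T2f) per voxel.
    """

    m0_volume: np.ndarray
    offset_volumes: list[np.ndarray]
    affine: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    t1_map: np.ndarray | None = None
    t2f_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.m0_volume = np.asarray(self.m0_volume, dtype=float)
        self.offset_volumes = [np.asarray(v, dtype=float) for v in self.offset_volumes]
        self.affine = np.asarray(self.affine, dtype=float)
        if self.m0_volume.ndim != 3:
            raise StackError("volumes must be 3-D")
        if self.affine.shape != (4, 4):
            raise StackError("affine must be 4x4")
        shape = self.m0_volume.shape
        for v in self.offset_volumes:
            if v.shape != shape:
                raise StackError("all offset volumes must match the M0 volume shape")
        for name in list(self.masks):
            m = np.asarray(self.masks[name]).astype(bool)
            if m.shape != shape:
                raise StackError(f"mask {name!r} shape does not match volumes")
            self.masks[name] = m
        mask_list = list(self.masks.values())
        for i in range(len(mask_list)):
            for j in range(i + 1, len(mask_list)):
                if np.any(mask_list[i] & mask_list[j]):
                    raise StackError("ROI masks must be disjoint")
        for name, vol in (("t1_map", self.t1_map), ("t2f_map", self.t2f_map)):
            if vol is not None and np.asarray(vol).shape != shape:
                raise StackError(f"{name} shape does not match volumes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.m0_volume.shape  # type: ignore[return-value]

    @property
    def n_offsets(self) -> int:
        return len(self.offset_volumes)

    def voxel_signal(self, idx: tuple[int, int, int]) -> tuple[float, np.ndarray]:
        """(m0, per-offset values) at a voxel index."""
        m0 = float(self.m0_volume[idx])
        vals = np.array([v[idx] for v in self.offset_volumes], dtype=float)
        return m0, vals


def _save(vol: np.ndarray, affine: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine), str(path))


def write_stack(stack: MTImageStack, acq: MTAcquisition, out_dir: str | Path) -> Path:
    """Write a stack as NIfTI volumes plus the acquisition JSON.

    Layout: ``m0.nii.gz``, ``mt_offset_<i>.nii.gz`` (aligned to the
    acquisition offsets), ``mask_<name>.nii.gz``, ``t1_map.nii.gz``,
    ``t2f_map.nii.gz``, ``acquisition.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save(stack.m0_volume, stack.affine, out / "m0.nii.gz")
    for i, vol in enumerate(stack.offset_volumes):
        _save(vol, stack.affine, out / f"mt_offset_{i}.nii.gz")
    for name, mask in stack.masks.items():
        _save(mask.astype(np.uint8), stack.affine, out / f"mask_{name}.nii.gz")
    if stack.t1_map is not None:
        _save(stack.t1_map, stack.affine, out / "t1_map.nii.gz")
    if stack.t2f_map is not None:
        _save(stack.t2f_map, stack.affine, out / "t2f_map.nii.gz")
    acq.to_json(out / "acquisition.json")
    return out


def read_stack(stack_dir: str | Path, acq: MTAcquisition | None = None) -> tuple[MTImageStack, MTAcquisition]:
    """Read a stack written by :func:`write_stack`, validating consistency.

    The offset-volume count must match the acquisition descriptor; shape or
    affine mismatches raise :class:`StackError` naming the offending file.
    """
    d = Path(stack_dir)
    if acq is None:
        acq_path = d / "acquisition.json"
        if not acq_path.exists():
            raise StackError(f"missing acquisition descriptor {acq_path}")
        acq = MTAcquisition.from_json(acq_path)

    m0_path = d / "m0.nii.gz"
    if not m0_path.exists():
        raise StackError(f"missing M0 volume {m0_path}")
    m0_img = nib.load(str(m0_path))
    affine = m0_img.affine
    shape = m0_img.shape

    def load(path: Path) -> np.ndarray:
        if not path.exists():
            raise StackError(f"missing volume {path}")
        img = nib.load(str(path))
        if img.shape != shape:
            raise StackError(f"shape mismatch in {path}")
        if not np.allclose(img.affine, affine):
            raise StackError(f"affine mismatch in {path}")
        return np.asarray(img.get_fdata(), dtype=float)

    offset_paths = sorted(d.glob("mt_offset_*.nii.gz"), key=lambda p: int(p.stem.split("_")[-1].split(".")[0]))
    if len(offset_paths) != acq.n_offsets:
        raise StackError(
            f"{d}: found {len(offset_paths)} offset volumes but the acquisition "
            f"defines {acq.n_offsets} offsets"
        )
    offset_volumes = [load(p) for p in offset_paths]
    masks = {
        p.name[len("mask_"):].split(".")[0]: load(p) > 0.5
        for p in sorted(d.glob("mask_*.nii.gz"))
    }
    t1 = load(d / "t1_map.nii.gz") if (d / "t1_map.nii.gz").exists() else None
    t2f = load(d / "t2f_map.nii.gz") if (d / "t2f_map.nii.gz").exists() else None
    stack = MTImageStack(
        m0_volume=np.asarray(m0_img.get_fdata(), dtype=float),
        offset_volumes=offset_volumes,
        affine=affine,
        masks=masks,
        t1_map=t1,
        t2f_map=t2f,
    )
    return stack, acq
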