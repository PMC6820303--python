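"""NIfTI volume IO, grid-compatibility checks, and cohort intensity normalization.

A subject is four co-registered modality volumes (T1-weighted, T2-weighted,
FLAIR, DWI) plus a binary brain mask on a common grid.  Registration to a
common space is a precondition of this package, not an operation it performs:
``read_subject`` refuses inputs whose shapes or voxel sizes disagree.

Cohort normalization makes per-modality intensities comparable across
subjects by a pure global rescale: each subject's within-mask mean is matched
to the cohort grand mean of within-mask means.  Relative contrast within a
subject is untouched.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

MODALITIES = ("t1", "t2", "flair", "dwi")

MODALITY_FILENAMES = {
    "t1": "T1.nii.gz",
    "t2": "T2.nii.gz",
    "flair": "FLAIR.nii.gz",
    "dwi": "DWI.nii.gz",
}
MASK_FILENAME = "mask.nii.gz"


@dataclass
class MultiModalVolume:
    """One subject's four registered intensity volumes plus brain mask.

    All five arrays share one shape; ``voxel_size_mm`` is the physical edge
    length of a voxel along each axis (1 mm isotropic for registered data).
    """

    t1: np.ndarray
    t2: np.ndarray
    flair: np.ndarray
    dwi: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        shapes = {m: self.modality(m).shape for m in MODALITIES}
        shapes["brain_mask"] = self.brain_mask.shape
        if len(set(shapes.values())) != 1:
            raise ValueError(f"volumes do not share one shape: {shapes}")
        if self.brain_mask.dtype != bool:
            self.brain_mask = self.brain_mask.astype(bool)
        if not self.brain_mask.any():
            raise ValueError(f"subject {self.subject_id!r}: brain mask is empty")
        for m in MODALITIES:
            if not np.all(np.isfinite(self.modality(m))):
                raise ValueError(f"subject {self.subject_id!r}: non-finite voxels in {m}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_mm}")

    def modality(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape

    def equals(self, other: "MultiModalVolume") -> bool:
        """Voxelwise equality of all arrays plus voxel size."""
        return (
            all(np.array_equal(self.modality(m), other.modality(m)) for m in MODALITIES)
            and np.array_equal(self.brain_mask, other.brain_mask)
            and self.voxel_size_mm == other.voxel_size_mm
        )


def _voxel_size_from_affine(img: nib.Nifti1Image) -> tuple[float, float, float]:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_subject(
    modality_paths: dict[str, str | os.PathLike],
    mask_path: str | os.PathLike | None = None,
    subject_id: str = "",
    mask_mode: str = "file",
) -> MultiModalVolume:
    """Load one subject from per-modality NIfTI files.

    Parameters
    ----------
    modality_paths
        Mapping with keys ``t1, t2, flair, dwi`` to NIfTI paths.
    mask_path
        Path to the binary brain-mask NIfTI.  Required for ``mask_mode="file"``.
    mask_mode
        ``"file"`` reads the mask from ``mask_path``; ``"nonzero"`` derives it
        as the voxels where all four modalities are nonzero.

    Raises
    ------
    ValueError
        On shape or voxel-size mismatch (naming the offending file) or on
        non-finite voxels.
    """
    missing = [m for m in MODALITIES if m not in modality_paths]
    if missing:
        raise ValueError(f"missing modality paths: {missing}")

    arrays: dict[str, np.ndarray] = {}
    zooms: dict[str, tuple[float, float, float]] = {}
    ref_shape = None
    ref_name = None
    for m in MODALITIES:
        img = nib.load(str(modality_paths[m]))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if ref_shape is None:
            ref_shape, ref_name = data.shape, str(modality_paths[m])
        elif data.shape != ref_shape:
            raise ValueError(
                f"shape mismatch: {ref_name} has {ref_shape} but "
                f"{modality_paths[m]} has {data.shape}"
            )
        zooms[m] = _voxel_size_from_affine(img)
        arrays[m] = data
    if len(set(zooms.values())) != 1:
        raise ValueError(f"voxel-size mismatch across modalities: {zooms}")

    if mask_mode == "file":
        if mask_path is None:
            raise ValueError("mask_mode='file' requires mask_path")
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
        if mask.shape != ref_shape:
            raise ValueError(
                f"shape mismatch: {ref_name} has {ref_shape} but mask "
                f"{mask_path} has {mask.shape}"
            )
    elif mask_mode == "nonzero":
        mask = np.ones(ref_shape, dtype=bool)
        for m in MODALITIES:
            mask &= arrays[m] != 0
    else:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")

    return MultiModalVolume(
        t1=arrays["t1"],
        t2=arrays["t2"],
        flair=arrays["flair"],
        dwi=arrays["dwi"],
        brain_mask=mask,
        voxel_size_mm=zooms["t1"],
        subject_id=subject_id,
    )


def read_subject_dir(subject_dir: str | os.PathLike, subject_id: str | None = None) -> MultiModalVolume:
    """Load a subject from a directory using the standard file names."""
    d = str(subject_dir)
    paths = {m: os.path.join(d, fn) for m, fn in MODALITY_FILENAMES.items()}
    sid = subject_id if subject_id is not None else os.path.basename(os.path.normpath(d))
    return read_subject(paths, mask_path=os.path.join(d, MASK_FILENAME), subject_id=sid)


def write_subject(
    v: MultiModalVolume,
    out_dir: str | os.PathLike,
    truth_labels: np.ndarray | None = None,
) -> str:
    """Write a subject's modalities and mask as NIfTI-1, affine encoding voxel size.

    The brain mask is written to ``mask.nii.gz``; if ``truth_labels`` is given
    it is written to ``labels.nii.gz`` alongside.  Returns the directory path.
    """
    out = str(out_dir)
    os.makedirs(out, exist_ok=True)
    affine = np.diag(list(v.voxel_size_mm) + [1.0])
    for m, fn in MODALITY_FILENAMES.items():
        nib.save(nib.Nifti1Image(v.modality(m).astype(np.float64), affine), os.path.join(out, fn))
    nib.save(nib.Nifti1Image(v.brain_mask.astype(np.uint8), affine), os.path.join(out, MASK_FILENAME))
    if truth_labels is not None:
        nib.save(nib.Nifti1Image(truth_labels.astype(np.uint8), affine), os.path.join(out, "labels.nii.gz"))
    return out


def write_label_volume(
    labels: np.ndarray, voxel_size_mm: tuple[float, float, float], path: str | os.PathLike
) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))


def read_label_volume(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int64)


def within_mask_mean(v: MultiModalVolume, modality: str) -> float:
    return float(v.modality(modality)[v.brain_mask].mean())


def normalize_cohort(subjects: list[MultiModalVolume]) -> list[MultiModalVolume]:
    """Match every subject's within-mask mean to the cohort grand mean, per modality.

    For modality ``m`` with subject means ``s_i``, the grand mean is
    ``g = mean_i(s_i)`` and subject ``i`` is rescaled by ``g / s_i``.  The
    transform is a pure rescale (contrast-preserving), idempotent, and
    scale-equivariant.  A subject whose within-mask mean is zero cannot be
    rescaled and is a hard error.
    """
    if not subjects:
        raise ValueError("normalize_cohort requires at least one subject")
    out = []
    scales: dict[str, np.ndarray] = {}
    for m in MODALITIES:
        means = np.array([within_mask_mean(v, m) for v in subjects])
        zero = np.nonzero(means == 0)[0]
        if zero.size:
            bad = [subjects[i].subject_id for i in zero]
            raise ValueError(f"within-mask mean of {m} is zero for subjects {bad}")
        scales[m] = means.mean() / means
    for i, v in enumerate(subjects):
        out.append(
            replace(
                v,
                t1=v.t1 * scales["t1"][i],
                t2=v.t2 * scales["t2"][i],
                flair=v.flair * scales["flair"][i],
                dwi=v.dwi * scales["dwi"][i],
            )
        )
    return out
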