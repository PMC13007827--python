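"""Voxel-domain ROI feature extraction.

Operates on pre-registered label volumes sharing one grid: gray-matter ROI
volumes, superficial-white-matter mean diffusivity under the 5-mm boundary
rule, and resection-overlap fractions.  Volumes can be plain dense arrays
with a voxel-size descriptor or NIfTI files (via nibabel, optional
dependency), so the module is testable without any imaging data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

__all__ = ["LabelVolume", "swm_mean_md", "gm_roi_volume",
           "resection_overlap_fractions", "load_nifti", "load_array"]


@dataclass
class LabelVolume:
    """Integer label volume on a common grid.

    ``labels`` holds ROI labels (0 = background); ``voxel_size_mm`` is the
    per-axis voxel edge length; ``label_table`` maps integer label to
    roi_id (defaults to the string of the label).
    """

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if np.issubdtype(self.labels.dtype, np.floating):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label volume must be integer-valued")
            self.labels = self.labels.astype(np.int64)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    def roi_name(self, label: int) -> str:
        return self.label_table.get(int(label), str(int(label)))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def _check_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: grid shapes differ {a.shape} vs {b.shape}")


def swm_mean_md(md: np.ndarray, parcellation: LabelVolume, wm_mask: np.ndarray,
                distance_mm: float = 5.0) -> pd.DataFrame:
    """Superficial-white-matter mean diffusivity per ROI.

    A white-matter voxel belongs to the superficial shell of the ROI whose
    gray matter is nearest to it (Euclidean, voxel-size aware), provided
    that distance is at most ``distance_mm``.  The returned table maps
    roi_id to the mean MD over its shell; ROIs with no qualifying voxel get
    a missing value.
    """
    md = np.asarray(md, dtype=float)
    wm = np.asarray(wm_mask, dtype=bool)
    _check_grid(md, parcellation.labels, "MD vs parcellation")
    _check_grid(wm, parcellation.labels, "WM mask vs parcellation")
    if distance_mm <= 0:
        raise ValueError("distance_mm must be positive")
    gm_any = parcellation.labels > 0
    if not gm_any.any():
        raise ValueError("parcellation has no labelled gray matter")
    dist, idx = distance_transform_edt(~gm_any, sampling=parcellation.voxel_size_mm,
                                       return_indices=True)
    nearest_label = parcellation.labels[tuple(idx)]
    shell = wm & ~gm_any & (dist <= distance_mm)
    rows = []
    for label in np.unique(parcellation.labels[gm_any]):
        sel = shell & (nearest_label == label)
        rows.append({"roi_id": parcellation.roi_name(label),
                     "value": float(md[sel].mean()) if sel.any() else np.nan,
                     "n_voxels": int(sel.sum())})
    return pd.DataFrame(rows)


def gm_roi_volume(parcellation: LabelVolume) -> pd.DataFrame:
    """ROI volumes in mm^3 (voxel count times voxel volume).  Labels listed
    in the label table but absent from the volume are reported as 0."""
    labels, counts = np.unique(parcellation.labels, return_counts=True)
    present = {int(l): int(c) for l, c in zip(labels, counts) if l != 0}
    all_labels = sorted(set(present) | set(parcellation.label_table))
    rows = [{"roi_id": parcellation.roi_name(l),
             "value": present.get(l, 0) * parcellation.voxel_volume_mm3,
             "n_voxels": present.get(l, 0)}
            for l in all_labels]
    return pd.DataFrame(rows)


def resection_overlap_fractions(parcellation: LabelVolume,
                                resection_mask: np.ndarray) -> pd.DataFrame:
    """Fraction of each ROI covered by a binary resection mask
    (|ROI ∩ mask| / |ROI| by voxel count).  Empty ROIs get a missing
    fraction."""
    mask = np.asarray(resection_mask)
    _check_grid(mask, parcellation.labels, "resection mask vs parcellation")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("resection mask must be binary")
    mask = mask.astype(bool)
    labels = np.unique(parcellation.labels)
    labels = labels[labels != 0]
    rows = []
    for label in labels:
        roi = parcellation.labels == label
        n = int(roi.sum())
        frac = float((roi & mask).sum() / n) if n else np.nan
        rows.append({"roi_id": parcellation.roi_name(label),
                     "overlap_fraction": frac, "n_voxels": n})
    return pd.DataFrame(rows)


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume and its voxel size (requires nibabel)."""
    import nibabel as nib
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def load_array(array_path, sidecar_path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a dense ``.npy``/text volume plus a JSON sidecar holding
    {"voxel_size_mm": [dx, dy, dz]}."""
    arr = np.load(array_path) if str(array_path).endswith(".npy") \
        else np.loadtxt(array_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return arr, tuple(float(v) for v in meta["voxel_size_mm"])
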