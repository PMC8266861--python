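"""Readers and writers for pipeline artifacts.

Volumes travel either as NIfTI files (via nibabel) or as ``.npz`` array
archives holding ``pre``, ``post1``, ``post2``, optional ``mask`` and a
scalar ``pixel_spacing``. Feature matrices are written as CSV (header =
global feature index) alongside a compact ``.npz``; JSON sidecars record
provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import DceSeries

__all__ = [
    "save_series_npz",
    "load_series_npz",
    "load_series_nifti",
    "save_mask_npz",
    "load_mask_npz",
    "save_feature_matrix",
    "load_feature_matrix",
]

# feature matrices wider than this skip the CSV copy (npz only)
MAX_CSV_FEATURES = 20_000


def save_series_npz(path, series: DceSeries, mask: np.ndarray | None = None,
                    **extra) -> None:
    arrays = {"pre": series.pre, "post1": series.post1, "post2": series.post2,
              "pixel_spacing": np.asarray(series.pixel_spacing)}
    if mask is not None:
        arrays["mask"] = np.asarray(mask, bool)
    arrays.update(extra)
    np.savez_compressed(path, **arrays)


def load_series_npz(path):
    """Returns ``(series, mask_or_None, extras_dict)``."""
    with np.load(path) as z:
        series = DceSeries(pre=z["pre"], post1=z["post1"], post2=z["post2"],
                           pixel_spacing=float(z["pixel_spacing"]))
        mask = z["mask"].astype(bool) if "mask" in z.files else None
        extras = {k: z[k] for k in z.files
                  if k not in ("pre", "post1", "post2", "pixel_spacing", "mask")}
    return series, mask, extras


def load_series_nifti(pre_path, post1_path, post2_path, pixel_spacing: float | None = None):
    """Build a :class:`DceSeries` from three NIfTI volumes.

    When ``pixel_spacing`` is not given it is read from the first file's
    header (in-plane spacing, assumed isotropic in-plane).
    """
    import nibabel as nib

    vols = []
    spacing = pixel_spacing
    for p in (pre_path, post1_path, post2_path):
        img = nib.load(str(p))
        vols.append(np.asarray(img.dataobj, dtype=float))
        if spacing is None:
            zooms = img.header.get_zooms()
            spacing = float(zooms[0])
    return DceSeries(pre=vols[0], post1=vols[1], post2=vols[2], pixel_spacing=spacing)


def save_mask_npz(path, mask: np.ndarray, **extra) -> None:
    np.savez_compressed(path, mask=np.asarray(mask, bool), **extra)


def load_mask_npz(path) -> np.ndarray:
    with np.load(path) as z:
        return z["mask"].astype(bool)


def save_feature_matrix(path_stem, matrix: np.ndarray, patient_ids,
                        feature_ids) -> dict:
    """Write ``<stem>.npz`` always and ``<stem>.csv`` when narrow enough."""
    path_stem = Path(path_stem)
    feature_ids = np.asarray(feature_ids, int)
    np.savez_compressed(path_stem.with_suffix(".npz"), matrix=matrix,
                        patient_ids=np.asarray(patient_ids, dtype="U32"),
                        feature_ids=feature_ids)
    written = {"npz": str(path_stem.with_suffix(".npz"))}
    if matrix.shape[1] <= MAX_CSV_FEATURES:
        df = pd.DataFrame(matrix, index=pd.Index(patient_ids, name="patient_id"),
                          columns=feature_ids)
        df.to_csv(path_stem.with_suffix(".csv"))
        written["csv"] = str(path_stem.with_suffix(".csv"))
    return written


def load_feature_matrix(path_stem):
    """Returns ``(matrix, patient_ids, feature_ids)`` from the npz archive."""
    with np.load(Path(path_stem).with_suffix(".npz")) as z:
        return z["matrix"], list(z["patient_ids"]), z["feature_ids"].astype(int)
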