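"""Scalar measurements feeding the statistics.

VOI means from labelled volumes, radioactive-decay correction, %ID/g
conversion, whole-brain (global) normalisation, hemisphere-ratio lesion
volume correction, and immunopositive pixel density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .regions import RegionSet
from .tables import UNITS_RATIO, UptakeTable

#: physical half-life of fluorine-18, minutes
F18_HALF_LIFE_MIN = 109.8


def _as_array_affine(vol) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(vol, nib.spatialimages.SpatialImage):
        return np.asarray(vol.get_fdata()), vol.affine
    return np.asarray(vol), np.eye(4)


def voi_means(intensity, label_volume, region_set: RegionSet) -> pd.DataFrame:
    """Mean intensity and voxel count per atlas region.

    Membership is exact label equality (no partial-volume weighting).
    Regions whose label is absent from the volume are flagged missing
    (``mean`` NaN) rather than silently dropped.
    """
    img, aff_i = _as_array_affine(intensity)
    lab, aff_l = _as_array_affine(label_volume)
    if img.shape != lab.shape:
        raise ValueError(
            f"intensity and label volumes differ in shape: {img.shape} vs {lab.shape}"
        )
    if not np.allclose(aff_i, aff_l, atol=1e-6):
        raise ValueError("intensity and label volumes differ in affine")
    lab = lab.astype(np.int64)

    rows = []
    for region in region_set:
        mask = lab == region.label
        n = int(mask.sum())
        if n == 0:
            warnings.warn(
                f"label {region.label} ({region.code}) absent from label volume",
                stacklevel=2,
            )
            rows.append((region.code, np.nan, 0, True))
        else:
            rows.append((region.code, float(img[mask].mean()), n, False))
    return pd.DataFrame(rows, columns=["region", "mean", "voxel_count", "missing"])


def decay_correct(activity, dt_min, half_life_min: float = F18_HALF_LIFE_MIN):
    """Back-correct measured activity to the reference (injection) time.

    ``dt_min`` is the elapsed time from reference to measurement, so the
    correction multiplies by ``2**(dt/half_life)``: an activity measured
    one half-life after injection is doubled.  Negative ``dt_min``
    undoes the correction.
    """
    if half_life_min <= 0:
        raise ValueError("half-life must be positive")
    return np.asarray(activity, float) * 2.0 ** (np.asarray(dt_min, float) / half_life_min)


def percent_id_per_gram(
    tissue_concentration_kBq_per_cc,
    injected_dose_MBq,
    tissue_density_g_per_cc: float = 1.0,
):
    """Convert a tissue concentration to percent injected dose per gram.

    %ID/g = 100 * (kBq/cc / density) / (dose in kBq).  Density defaults
    to 1 g/cc, the standard soft-tissue convention.
    """
    dose = np.asarray(injected_dose_MBq, float)
    if np.any(dose <= 0):
        raise ValueError("injected dose must be positive")
    if tissue_density_g_per_cc <= 0:
        raise ValueError("tissue density must be positive")
    conc = np.asarray(tissue_concentration_kBq_per_cc, float)
    return 100.0 * (conc / tissue_density_g_per_cc) / (dose * 1000.0)


def global_normalize(table: UptakeTable, whole_brain_means=None) -> UptakeTable:
    """Divide each subject's regional values by its whole-brain mean.

    The whole-brain mean defaults to the volume-weighted mean over the
    table's regions (uniform weights without attached region volumes);
    an explicit per-subject array can be supplied instead, e.g. from a
    whole-brain mask.  The result carries the ``ratio_to_global`` units
    tag and, by construction, per-subject weighted mean 1.
    """
    if whole_brain_means is None:
        wb = table.whole_brain_means()
    else:
        wb = np.asarray(whole_brain_means, float)
        if wb.shape != (len(table.data),):
            raise ValueError("whole_brain_means must have one value per subject")
    bad = np.asarray(wb) <= 0
    if np.any(bad):
        subjects = table.data.loc[bad, "subject_id"].tolist()
        raise ValueError(f"non-positive whole-brain mean for subjects {subjects}")
    df = table.data.copy()
    codes = table.region_set.codes
    df[codes] = df[codes].to_numpy(dtype=float) / wb[:, None]
    return UptakeTable(
        df, table.region_set, units=UNITS_RATIO, tracer=table.tracer,
        region_weights=table.region_weights,
    )


@dataclass(frozen=True)
class LesionMeasurement:
    raw_volume_mm3: float
    ipsi_hemisphere_mm3: float
    contra_hemisphere_mm3: float
    corrected_volume_mm3: float


def corrected_lesion_volume(
    raw_mm3: float, ipsi_mm3: float, contra_mm3: float, invert_ratio: bool = False
) -> LesionMeasurement:
    """Hemisphere-ratio correction of a lesion volume.

    corrected = raw * contra/ipsi, so oedema-driven swelling of the
    lesioned (ipsilesional) hemisphere deflates the estimate.  Set
    ``invert_ratio`` to use ipsi/contra instead.
    """
    if ipsi_mm3 <= 0 or contra_mm3 <= 0:
        raise ValueError("hemisphere volumes must be positive")
    if raw_mm3 < 0:
        raise ValueError("raw lesion volume must be non-negative")
    ratio = ipsi_mm3 / contra_mm3 if invert_ratio else contra_mm3 / ipsi_mm3
    return LesionMeasurement(raw_mm3, ipsi_mm3, contra_mm3, raw_mm3 * ratio)


def immunopositive_density(
    image, threshold: float | str = "otsu"
) -> tuple[float, float]:
    """Fraction of pixels strictly above an intensity threshold.

    ``threshold`` is either a fixed value or ``"otsu"`` for an automatic
    per-image histogram split.  Returns (density, threshold used); the
    threshold is always reported so counts are reproducible.  A constant
    image under automatic thresholding yields density 0 with a warning.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        if np.ptp(img) == 0:
            warnings.warn(
                "constant image: automatic threshold undefined, density set to 0",
                stacklevel=2,
            )
            return 0.0, float(img.flat[0])
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    density = float(np.count_nonzero(img > thr)) / img.size
    return density, thr
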