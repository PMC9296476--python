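"""Static PET quantification: SUVR, smoothing, partial-volume correction,
ROI extraction and normative z-score maps.

Tracer protocols carry the reference-region role and uptake window; three
are built in (SUVR windows in minutes post-injection):

=============  ========================  ============
tracer         reference role            window (min)
=============  ========================  ============
martinostat    telencephalic white matter  60-90
mk6240         cerebellar grey matter      90-110
azd4694        cerebellar grey matter      40-70
=============  ========================  ============

Partial-volume correction follows the geometric-transfer-matrix (GTM) /
region-based voxel-wise (RBV) scheme: regional true means are recovered by
inverting the matrix of PSF cross-contamination between regions, a synthetic
piecewise-constant image is built from them, and the observed image is
rescaled voxel-wise by synthetic / PSF-blurred-synthetic.

Convolution boundary handling: plain smoothing (``smooth_to_fwhm``) uses
zero padding, so the total image sum is conserved.  The GTM matrix and the
RBV denominator divide out the blurred all-ones volume, which removes the
mass the zero-padded kernel pushes outside the grid; without this the
correction would over-shoot at the volume boundary and a uniform image would
not be a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import DynamicImage, LabelMap, StatImage, check_same_grid

__all__ = [
    "TracerProtocol",
    "TRACER_PROTOCOLS",
    "compute_suvr",
    "smooth_to_fwhm",
    "gtm_means",
    "rbv_correct",
    "RbvResult",
    "roi_extract",
    "zscore_map",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class TracerProtocol:
    """Tracer name, reference-region role and uptake window (minutes)."""

    tracer: str
    reference_role: str
    window_min: tuple

    def __post_init__(self):
        if not self.window_min[0] < self.window_min[1]:
            raise ValueError("window start must precede window end")


TRACER_PROTOCOLS = {
    "martinostat": TracerProtocol("martinostat", "reference_white_matter", (60.0, 90.0)),
    "mk6240": TracerProtocol("mk6240", "reference_cerebellar_gray", (90.0, 110.0)),
    "azd4694": TracerProtocol("azd4694", "reference_cerebellar_gray", (40.0, 70.0)),
}


def _blur(arr: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    if fwhm_mm <= 0:
        return np.asarray(arr, dtype=float).copy()
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    # truncate at 6 sigma: keeps sequential-smoothing variance additivity
    # below 1e-7 RMS away from the volume boundary
    return gaussian_filter(
        np.asarray(arr, dtype=float), sigma=sigma_vox, mode="constant", truncate=6.0
    )


def compute_suvr(
    frames_in_window: DynamicImage,
    protocol: TracerProtocol,
    labelmap: LabelMap,
    reference_labels,
) -> StatImage:
    """Standardized uptake value ratio image.

    The duration-weighted mean image over the uptake window is divided by its
    scalar mean over the reference region, so the reference-region mean SUVR
    is exactly 1.  All supplied frames must fall inside the protocol window.
    """
    check_same_grid(frames_in_window, labelmap)
    sched = frames_in_window.schedule
    w0, w1 = (60.0 * m for m in protocol.window_min)
    eps = 1e-6
    if np.any(sched.starts < w0 - eps) or np.any(sched.ends > w1 + eps):
        raise ValueError(
            f"frames [{sched.starts[0]}, {sched.ends[-1]}] s fall outside the "
            f"{protocol.tracer} uptake window [{w0}, {w1}] s"
        )
    ref_mask = labelmap.mask(reference_labels)
    if not ref_mask.any():
        raise ValueError("reference region is empty")
    mean_img = frames_in_window.frame_weighted_mean()
    ref_mean = mean_img[ref_mask].mean()
    if ref_mean == 0:
        raise ValueError("reference-region mean activity is zero")
    return StatImage(mean_img / ref_mean, frames_in_window.affine, tag="SUVR")


def smooth_to_fwhm(
    image: StatImage, target_fwhm_mm: float, intrinsic_fwhm_mm: float = 0.0
) -> StatImage:
    """Gaussian-smooth to a final target resolution.

    The applied kernel has FWHM = sqrt(target^2 - intrinsic^2) mm (variance
    additivity of Gaussian PSFs); target below intrinsic is an error.
    Zero-padded boundaries: the total image sum is conserved.
    """
    if target_fwhm_mm < intrinsic_fwhm_mm:
        raise ValueError("target FWHM must be >= intrinsic FWHM")
    applied = float(np.sqrt(target_fwhm_mm**2 - intrinsic_fwhm_mm**2))
    data = np.where(image.mask, image.data, 0.0)
    out = _blur(data, applied, image.voxel_size_mm)
    return StatImage(out, image.affine, tag=image.tag, mask=np.isfinite(out))


def _region_indicators(labelmap: LabelMap):
    labels = labelmap.labels
    return labels, [(labelmap.data == l) for l in labels]


def gtm_means(
    pet: StatImage,
    labelmap: LabelMap,
    psf_fwhm_mm: float,
    cond_limit: float = 1e8,
) -> pd.Series:
    """Geometric-transfer-matrix estimate of regional true means.

    Solves W m = o where W[i, j] is the mean over region i of the PSF-blurred
    indicator of region j and o the observed regional means.  A
    near-singular W (indistinguishable regions at the given PSF) raises with
    the condition number in the message.
    """
    check_same_grid(pet, labelmap)
    labels, indicators = _region_indicators(labelmap)
    if labels.size == 0:
        raise ValueError("label map has no regions")
    if psf_fwhm_mm < 0:
        raise ValueError("PSF FWHM must be >= 0")
    vox = labelmap.voxel_size_mm
    norm = _blur(np.ones(labelmap.data.shape), psf_fwhm_mm, vox)
    blurred = [_blur(ind.astype(float), psf_fwhm_mm, vox) / norm for ind in indicators]
    W = np.empty((labels.size, labels.size))
    o = np.empty(labels.size)
    data = np.where(pet.mask, pet.data, 0.0)
    for i, ind in enumerate(indicators):
        o[i] = data[ind].mean()
        for j, bl in enumerate(blurred):
            W[i, j] = bl[ind].mean()
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(
            f"GTM matrix is numerically singular (condition number {cond:.3g}); "
            "regions are indistinguishable at this PSF"
        )
    m = np.linalg.solve(W, o)
    return pd.Series(m, index=labels.astype(int), name="gtm_mean")


@dataclass
class RbvResult:
    """RBV-corrected image plus the GTM solution and guard-rail report."""

    image: StatImage
    gtm: pd.Series
    n_floored: int


def rbv_correct(
    pet: StatImage,
    labelmap: LabelMap,
    psf_fwhm_mm: float,
    floor_frac: float = 1e-6,
) -> RbvResult:
    """Region-based voxel-wise partial-volume correction.

    corrected = pet * s / (s (x) PSF), with s the piecewise-constant image of
    GTM regional means.  The denominator is floored at ``floor_frac`` times
    max(s) to avoid division blow-up at region edges; floored voxels are
    counted in the result.  Exact on piecewise-constant images whose pieces
    are the label map's regions.
    """
    gtm = gtm_means(pet, labelmap, psf_fwhm_mm)
    labels, indicators = _region_indicators(labelmap)
    s = np.zeros(labelmap.data.shape)
    for label, ind in zip(labels, indicators):
        s[ind] = gtm.loc[int(label)]
    if psf_fwhm_mm == 0:
        return RbvResult(
            StatImage(pet.data.copy(), pet.affine, tag=pet.tag, mask=pet.mask.copy()),
            gtm,
            0,
        )
    vox = labelmap.voxel_size_mm
    norm = _blur(np.ones_like(s), psf_fwhm_mm, vox)
    denom = _blur(s, psf_fwhm_mm, vox) / norm
    floor = floor_frac * np.abs(s).max()
    floored = np.abs(denom) < floor
    denom = np.where(floored, np.where(denom < 0, -floor, floor), denom)
    corrected = np.where(pet.mask, pet.data, np.nan) * s / denom
    in_region = labelmap.data > 0
    n_floored = int((floored & in_region & pet.mask).sum())
    return RbvResult(
        StatImage(corrected, pet.affine, tag=pet.tag, mask=pet.mask & np.isfinite(corrected)),
        gtm,
        n_floored,
    )


def roi_extract(image: StatImage, labelmap: LabelMap, names: dict) -> pd.DataFrame:
    """Per-region mean, SD and voxel count; missing voxels excluded.

    ``names`` maps region name -> label (or list of labels); a label absent
    from the map raises.
    """
    check_same_grid(image, labelmap)
    present = set(np.unique(labelmap.data).tolist())
    rows = []
    for name, label in names.items():
        labels = np.atleast_1d(label)
        missing = [int(l) for l in labels if int(l) not in present]
        if missing:
            raise ValueError(f"label(s) {missing} for region {name!r} absent from map")
        m = labelmap.mask(labels) & image.mask
        vals = image.data[m]
        rows.append(
            {
                "region": name,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def zscore_map(
    image: StatImage, normative_mean: StatImage, normative_sd: StatImage
) -> tuple[StatImage, int]:
    """Deviation map in normative SD units: (image - mean) / sd voxel-wise.

    Voxels with zero (or negative) normative SD are flagged missing; the
    count of such voxels is returned alongside the map.
    """
    check_same_grid(image, normative_mean, normative_sd)
    mask = image.mask & normative_mean.mask & normative_sd.mask
    bad = mask & ~(normative_sd.data > 0)
    ok = mask & ~bad
    z = np.full(image.data.shape, np.nan)
    z[ok] = (image.data[ok] - normative_mean.data[ok]) / normative_sd.data[ok]
    return StatImage(z, image.affine, tag="z", mask=ok), int(bad.sum())
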