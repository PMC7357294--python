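"""White matter hyperintensity quantification and SVD feature assembly.

WMH segmentation follows the intensity-outlier rule: voxels with a FLAIR
z score >= 1.5 relative to the within-white-matter mean/SD are candidate
hyperintensities; the binary candidate map is Gaussian-smoothed (partial
volume / noise suppression) and re-thresholded at 0.5, and stroke lesions
are removed before the volume is computed.

Visual scores (Fazekas, perivascular spaces, lacunes, microbleeds,
atrophy) are inputs, never computed from images; this module only applies
their arithmetic combinations (Fazekas sum, total SVD score 0-4) and the
log10 transforms used by the association models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import (
    DegenerateImageError,
    EmptyMaskError,
    MissingFeatureError,
    TransformError,
)

#: sex coding recorded in every output that carries the covariate
SEX_CODING = {"male": 1, "female": 0}


@dataclass
class SVDFeatures:
    """Per-subject small vessel disease feature set.

    ``wmh_volume`` (mL) comes from :func:`segment_wmh`; the remaining
    components are visual ratings: Fazekas 0-3 per region, perivascular
    space (PVS) scores 0-4 per region, lacune and microbleed counts, and a
    template-referenced atrophy score.
    """

    wmh_volume: float
    fazekas_periventricular: int
    fazekas_deep: int
    pvs_basal_ganglia: int
    pvs_centrum_semiovale: int
    lacunes_count: int
    microbleeds_count: int
    atrophy_score: float

    def __post_init__(self) -> None:
        for name, hi in (("fazekas_periventricular", 3), ("fazekas_deep", 3),
                         ("pvs_basal_ganglia", 4), ("pvs_centrum_semiovale", 4)):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise ValueError(f"{name} must be in 0..{hi}, got {v}")
        if self.lacunes_count < 0 or self.microbleeds_count < 0:
            raise ValueError("lesion counts must be nonnegative")

    @property
    def fazekas_total(self) -> int:
        return self.fazekas_periventricular + self.fazekas_deep

    @property
    def lacunes_present(self) -> bool:
        return self.lacunes_count >= 1

    @property
    def microbleeds_present(self) -> bool:
        return self.microbleeds_count >= 1

    @property
    def log10_wmh_volume(self) -> float:
        if self.wmh_volume <= 0:
            raise TransformError("wmh_volume must be positive for log10")
        return math.log10(self.wmh_volume)

    @property
    def log10_atrophy(self) -> float:
        if self.atrophy_score <= 0:
            raise TransformError("atrophy_score must be positive for log10")
        return math.log10(self.atrophy_score)

    @property
    def svd_score_total(self) -> int:
        return total_svd_score(self)


def segment_wmh(
    flair: np.ndarray,
    wm_mask: np.ndarray,
    stroke_mask: np.ndarray | None = None,
    z_threshold: float = 1.5,
    smooth_sigma: float = 0.75,
    voxel_volume_ml: float = 1e-3,
) -> tuple[np.ndarray, float]:
    """Segment white matter hyperintensities on a FLAIR-like image.

    Parameters
    ----------
    flair
        3D image.
    wm_mask
        White matter mask; z statistics are computed within it and the
        output is restricted to it.
    stroke_mask
        Index/old stroke lesion voxels removed from the result.
    z_threshold
        Candidate threshold on the within-WM z score (default 1.5).
    smooth_sigma
        Gaussian sigma (voxels) applied to the binary candidate map before
        re-thresholding at 0.5; 0 disables smoothing.  The default (0.75)
        fills isolated within-lesion misses and removes isolated noise
        voxels without eroding curved lesion rims (wider kernels erode
        roughly one voxel shell; narrower ones let single-voxel false
        positives survive the re-threshold).
    voxel_volume_ml
        Volume of one voxel in mL (default 1 mm^3 = 1e-3 mL).

    Returns
    -------
    (wmh_mask, volume_ml)
    """
    flair = np.asarray(flair, dtype=float)
    wm_mask = np.asarray(wm_mask).astype(bool)
    if wm_mask.shape != flair.shape:
        raise ValueError("wm_mask shape does not match image")
    if not wm_mask.any():
        raise EmptyMaskError("white matter mask is empty")
    mu = flair[wm_mask].mean()
    sd = flair[wm_mask].std()
    if sd == 0.0:
        raise DegenerateImageError("zero FLAIR SD within white matter mask")

    z = (flair - mu) / sd
    candidate = (z >= z_threshold) & wm_mask
    if smooth_sigma > 0:
        prob = gaussian_filter(candidate.astype(float), smooth_sigma)
        wmh = (prob >= 0.5) & wm_mask
    else:
        wmh = candidate
    if stroke_mask is not None:
        wmh = wmh & ~np.asarray(stroke_mask).astype(bool)
    return wmh, float(wmh.sum()) * voxel_volume_ml


def total_svd_score(features: SVDFeatures) -> int:
    """Total SVD score (0-4): one point per marker domain.

    Points: any lacune; any microbleed; basal ganglia PVS score >= 2;
    WMH burden (deep Fazekas >= 2 or periventricular Fazekas = 3).
    """
    for comp in ("lacunes_count", "microbleeds_count", "pvs_basal_ganglia",
                 "fazekas_deep", "fazekas_periventricular"):
        if getattr(features, comp, None) is None:
            raise MissingFeatureError(f"missing SVD component: {comp}")
    score = 0
    score += features.lacunes_count >= 1
    score += features.microbleeds_count >= 1
    score += features.pvs_basal_ganglia >= 2
    score += (features.fazekas_deep >= 2) or (features.fazekas_periventricular == 3)
    return int(score)


def encode_sex(value) -> int:
    """Encode sex as male=1 / female=0 (see :data:`SEX_CODING`)."""
    if isinstance(value, str):
        key = value.strip().lower()
        key = {"m": "male", "f": "female"}.get(key, key)
        if key not in SEX_CODING:
            raise ValueError(f"cannot encode sex value {value!r}")
        return SEX_CODING[key]
    v = int(value)
    if v not in (0, 1):
        raise ValueError(f"cannot encode sex value {value!r}")
    return v


def prepare_covariates(features: SVDFeatures, clinical: dict) -> dict:
    """Assemble one analysis-ready row for the association models.

    Adds the log10-transformed WMH volume and atrophy score, passes the
    visual scores through unchanged, and encodes sex as 0/1 (coding in
    ``sex_coding`` metadata).  Raises :class:`TransformError` on
    non-positive volumes rather than silently offsetting.
    """
    row = {
        "wmh_volume": features.wmh_volume,
        "log10_wmh": features.log10_wmh_volume,
        "fazekas_periventricular": features.fazekas_periventricular,
        "fazekas_deep": features.fazekas_deep,
        "fazekas_total": features.fazekas_total,
        "pvs_basal_ganglia": features.pvs_basal_ganglia,
        "pvs_centrum_semiovale": features.pvs_centrum_semiovale,
        "lacunes_count": features.lacunes_count,
        "lacunes_present": int(features.lacunes_present),
        "microbleeds_count": features.microbleeds_count,
        "microbleeds_present": int(features.microbleeds_present),
        "atrophy_score": features.atrophy_score,
        "log10_atrophy": features.log10_atrophy,
        "svd_score_total": features.svd_score_total,
    }
    for key, val in clinical.items():
        row[key] = encode_sex(val) if key == "sex" else val
    row["sex_coding"] = "male=1,female=0"
    return row
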