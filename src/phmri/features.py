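"""Lesion VOI extraction and per-patient feature computation.

Aligns maps by translation-only mutual-information search, segments the
diffusion-hyperintense lesion, and computes the per-patient features:
10th percentile CBV ratio, 10th percentile ADC, 90th percentile K2,
infarct-core volume (ADC < 600 x 1e-6 mm^2/s), Tmax >= 6 s lesion
volume, and the global-reperfusion flag (>= 90% reduction of the
perfusion lesion at follow-up).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionVOI",
    "RegistrationResult",
    "register_translation",
    "extract_voi",
    "percentile_features",
    "core_volume",
    "tmax_volume_and_reperfusion",
    "ADC_CORE_THRESHOLD",
    "TMAX_LESION_THRESHOLD_S",
    "REPERFUSION_REDUCTION",
]

#: Infarct core: ADC strictly below this value (1e-6 mm^2/s).
ADC_CORE_THRESHOLD = 600.0
#: Perfusion lesion: Tmax at or above this value (seconds).
TMAX_LESION_THRESHOLD_S = 6.0
#: Global reperfusion: follow-up lesion volume <= (1 - 0.90) x baseline.
REPERFUSION_REDUCTION = 0.90


@dataclass
class LesionVOI:
    """Binary lesion mask plus contralateral reference mask.

    ``provenance`` records the method and parameters that produced the
    mask so feature values are traceable to a segmentation convention.
    """

    lesion_mask: np.ndarray
    contralateral_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        self.contralateral_mask = np.asarray(self.contralateral_mask, dtype=bool)
        if (self.lesion_mask & self.contralateral_mask).any():
            raise ValueError("lesion and contralateral masks must be disjoint")

    @property
    def is_empty(self) -> bool:
        return not self.lesion_mask.any()


@dataclass
class RegistrationResult:
    shift: tuple[int, int, int]
    aligned: np.ndarray
    mutual_information: float
    low_confidence: bool


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def _overlap_slices(shift: tuple[int, int, int], shape: tuple[int, ...]):
    """Index slices of fixed / moving arrays overlapping under ``shift``.

    ``shift`` is the displacement applied to the moving volume; a voxel
    at moving index i maps to fixed index i + shift.
    """
    fixed_sl, moving_sl = [], []
    for s, n in zip(shift, shape):
        f0, f1 = max(s, 0), min(n + s, n)
        if f1 <= f0:
            return None
        fixed_sl.append(slice(f0, f1))
        moving_sl.append(slice(f0 - s, f1 - s))
    return tuple(fixed_sl), tuple(moving_sl)


def register_translation(
    moving: np.ndarray,
    fixed: np.ndarray,
    search_radius: int = 3,
    bins: int = 32,
    confidence_margin: float = 1.0,
) -> RegistrationResult:
    """Integer-translation registration maximizing mutual information.

    Exhaustive search over all shifts within +/- ``search_radius`` voxels
    per axis, scoring each candidate by the mutual information of a
    ``bins``-bin joint histogram over the overlapping region. Ties are
    broken toward the smaller shift magnitude, then lexicographic axis
    order. Shifts with empty overlap score invalid. The result is
    flagged low-confidence when the winning MI does not exceed the
    median over the searched shifts by at least ``confidence_margin``
    times that median — for a pure-noise pair all shifts score at the
    finite-sample MI floor, so the margin collapses.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share a grid")

    r = int(search_radius)
    candidates = sorted(
        itertools.product(range(-r, r + 1), repeat=3),
        key=lambda s: (sum(abs(c) for c in s), s),
    )
    scores: list[float] = []
    best_shift, best_mi = (0, 0, 0), -np.inf
    for shift in candidates:
        sl = _overlap_slices(shift, moving.shape)
        if sl is None:
            continue
        fixed_sl, moving_sl = sl
        mi = _mutual_information(fixed[fixed_sl], moving[moving_sl], bins)
        scores.append(mi)
        if mi > best_mi:  # candidates pre-sorted, so ties keep the smaller shift
            best_mi, best_shift = mi, shift

    aligned = np.zeros_like(moving)
    sl = _overlap_slices(best_shift, moving.shape)
    if sl is not None:
        fixed_sl, moving_sl = sl
        aligned[fixed_sl] = moving[moving_sl]

    floor = float(np.median(scores))
    low_conf = (best_mi - floor) < confidence_margin * max(floor, 1e-12)
    return RegistrationResult(best_shift, aligned, best_mi, low_conf)


def extract_voi(
    dwi: np.ndarray,
    brain_mask: np.ndarray,
    contralateral_mask: np.ndarray,
    z_threshold: float = 2.0,
) -> LesionVOI:
    """Segment the diffusion-hyperintense lesion.

    Voxels whose DWI z-score (relative to the contralateral-mask mean and
    SD) exceeds ``z_threshold`` are candidates; the largest 26-connected
    component is retained and holes are filled. If nothing exceeds the
    threshold an empty VOI is returned (not an exception) — downstream
    feature operations refuse empty VOIs.
    """
    dwi = np.asarray(dwi, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    contralateral_mask = np.asarray(contralateral_mask, dtype=bool)
    if not contralateral_mask.any():
        raise ValueError("contralateral mask is empty")

    mu = dwi[contralateral_mask].mean()
    sd = dwi[contralateral_mask].std()
    if sd == 0:
        sd = 1.0  # uniform reference; z-scores are then just offsets
    z = (dwi - mu) / sd
    candidate = (z > z_threshold) & brain_mask & ~contralateral_mask

    provenance = {
        "method": "dwi_zscore",
        "z_threshold": z_threshold,
        "connectivity": 26,
        "reference_mean": float(mu),
        "reference_sd": float(sd),
    }
    if not candidate.any():
        return LesionVOI(candidate, contralateral_mask, provenance)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(candidate, structure=structure)
    sizes = ndimage.sum_labels(candidate, labeled, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    lesion = ndimage.binary_fill_holes(labeled == largest)
    return LesionVOI(lesion, contralateral_mask, provenance)


def percentile_features(
    cbv_ratio: np.ndarray,
    adc: np.ndarray,
    k2: np.ndarray,
    voi: LesionVOI,
    valid: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(cbv_p10, adc_p10, k2_p90) over the lesion VOI.

    Percentiles use linear interpolation between closest order
    statistics. Flagged (invalid) voxels are excluded; a VOI that is
    nonempty but entirely flagged is an input error.
    """
    if voi.is_empty:
        raise ValueError("empty lesion VOI: no features to compute")
    use = voi.lesion_mask.copy()
    if valid is not None:
        use &= np.asarray(valid, dtype=bool)
    if not use.any():
        raise ValueError("all VOI voxels are flagged invalid")

    cbv_p10 = float(np.percentile(cbv_ratio[use], 10, method="linear"))
    adc_p10 = float(np.percentile(adc[use], 10, method="linear"))
    k2_p90 = float(np.percentile(k2[use], 90, method="linear"))
    return cbv_p10, adc_p10, k2_p90


def core_volume(
    adc: np.ndarray,
    brain_mask: np.ndarray,
    voxel_volume_ml: float,
    threshold: float = ADC_CORE_THRESHOLD,
) -> float:
    """Infarct-core volume in mL: in-mask voxels with ADC strictly below threshold.

    Warns when the median in-brain ADC falls outside 200–2000, a
    heuristic for a unit mismatch (ADC expected in 1e-6 mm^2/s).
    """
    adc = np.asarray(adc, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    median = float(np.median(adc[brain_mask]))
    if not 200.0 <= median <= 2000.0:
        warnings.warn(
            f"median brain ADC {median:.1f} outside 200-2000; expected units 1e-6 mm^2/s"
        )
    return float((adc[brain_mask] < threshold).sum()) * voxel_volume_ml


def tmax_volume_and_reperfusion(
    tmax_baseline: np.ndarray,
    tmax_followup: np.ndarray | None,
    voxel_volume_ml: float,
    brain_mask: np.ndarray | None = None,
    threshold_s: float = TMAX_LESION_THRESHOLD_S,
) -> tuple[float, bool | None]:
    """Perfusion-lesion volume (Tmax >= 6 s, inclusive) and reperfusion flag.

    Reperfusion is a >= 90% reduction of the lesion volume at follow-up
    (follow-up <= 10% of baseline, boundary inclusive). Without a
    follow-up map the flag is None; a zero baseline volume with
    follow-up present leaves reperfusion undefined (None) with a
    warning.
    """

    def lesion_ml(tmax: np.ndarray) -> float:
        tmax = np.asarray(tmax, dtype=float)
        sel = tmax >= threshold_s
        if brain_mask is not None:
            sel &= np.asarray(brain_mask, dtype=bool)
        return float(np.nansum(sel)) * voxel_volume_ml

    baseline_ml = lesion_ml(tmax_baseline)
    if tmax_followup is None:
        return baseline_ml, None
    if baseline_ml == 0:
        warnings.warn("baseline perfusion lesion volume is 0; reperfusion undefined")
        return baseline_ml, None
    followup_ml = lesion_ml(tmax_followup)
    reduction = (baseline_ml - followup_ml) / baseline_ml
    # tiny tolerance keeps the inclusive >= 90% boundary robust to float error
    return baseline_ml, bool(reduction >= REPERFUSION_REDUCTION - 1e-12)
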