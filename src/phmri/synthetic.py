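"""Synthetic patient volumes and cohorts with known ground truth.

Every downstream stage (perfusion maps, VOI features, predictive
models) is testable offline against the generating parameters:

* DSC bolus passage is a gamma-variate arterial input function with a
  delayed, scaled recirculation pass, convolved with an exponential
  residue per voxel; contrast leakage adds the same normalized
  cumulative-integral term the K2 fit estimates, so the generating
  ``k2_true`` is in the fitted units by construction.
* An ellipsoidal ischemic core carries depressed ADC, depressed CBV,
  elevated K2 and a bolus-arrival delay; a mirrored contralateral box
  provides the normal-appearing reference region (mean true CBV 1).
* Cohorts draw group-separated generating features (lower CBV10/ADC10,
  higher K2_90 in the PH group) and label-independent clinical
  covariates; labels are either exact fixed counts (default 20 of 83)
  or derived from the published logistic score of the drawn features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from phmri.models import logistic_score, published_logistic
from phmri.perfusion import DscSeries
from phmri.records import PatientRecord

__all__ = [
    "AcquisitionConfig",
    "TissueTruth",
    "CohortConfig",
    "GroupFeatureParams",
    "PatientVolumes",
    "gamma_variate_aif",
    "make_tissue_truth",
    "simulate_dsc_signal",
    "generating_concentration",
    "generate_cohort",
]

# Standard normal 10th-percentile z; converts a percentile target into the
# mean of the generating normal distribution.
_Z10 = 1.2815515655446004


@dataclass
class AcquisitionConfig:
    """DSC acquisition timing and noise.

    The paper-scale default covers 60 s (40 frames at 1.5 s) with TE
    45 ms; the acquisition must span at least 45 s with at least 3
    pre-bolus baseline frames.
    """

    te: float = 0.045
    dt: float = 1.5
    n_frames: int = 40
    baseline_frames: int = 5
    noise_sigma: float = 0.0
    s0: float = 100.0
    rng_seed: int = 0
    bolus_arrival: float = 9.0
    mtt: float = 4.0
    recirc_amplitude: float = 0.3
    recirc_delay: float = 12.0

    def __post_init__(self) -> None:
        if self.te <= 0 or self.dt <= 0:
            raise ValueError("TE and frame interval must be positive")
        if self.n_frames * self.dt < 45.0:
            raise ValueError(
                f"acquisition must cover >= 45 s; got {self.n_frames * self.dt:.1f} s"
            )
        if self.baseline_frames < 3:
            raise ValueError("need at least 3 baseline frames")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class TissueTruth:
    """Per-voxel ground-truth tissue parameters on one grid.

    ``cbv_true`` is relative to the contralateral reference (mean 1 over
    that mask), ``k2_true`` in the same normalized decimal units the
    leakage fit estimates, ``adc_map`` in 1e-6 mm^2/s, ``delay_map`` in
    seconds.
    """

    adc_map: np.ndarray
    cbf_map: np.ndarray
    cbv_true: np.ndarray
    k2_true: np.ndarray
    delay_map: np.ndarray
    lesion_mask: np.ndarray
    contralateral_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 5.0)

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        self.contralateral_mask = np.asarray(self.contralateral_mask, dtype=bool)
        if (self.lesion_mask & self.contralateral_mask).any():
            raise ValueError("lesion and contralateral masks must be disjoint")
        ref_mean = self.cbv_true[self.contralateral_mask].mean()
        if abs(ref_mean - 1.0) > 0.01:
            raise ValueError(f"mean true CBV over contralateral mask must be 1 (got {ref_mean:.4f})")
        if self.lesion_mask.any():
            lesion_med = np.median(self.adc_map[self.lesion_mask])
            ref_med = np.median(self.adc_map[self.contralateral_mask])
            if lesion_med >= ref_med:
                raise ValueError("lesion ADC must be depressed relative to contralateral tissue")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.adc_map.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class GroupFeatureParams:
    """Generating feature distribution (mean, SD) for one label group."""

    cbv_p10: tuple[float, float]
    adc_p10: tuple[float, float]
    k2_p90: tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("cbv_p10", "adc_p10", "k2_p90"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0; got {sd}")


@dataclass
class CohortConfig:
    """Cohort size, label mode, and generating distributions.

    Defaults reproduce the study cohort: 83 patients of whom 20 develop
    parenchymal hemorrhage, with the PH group shifted toward lower
    CBV10/ADC10 and higher K2_90. Clinical covariates are drawn
    independently of the label. ``label_mode="published_model"``
    instead draws features from a pooled distribution and labels each
    patient by the published logistic score.
    """

    n_patients: int = 83
    n_ph: int = 20
    ph_features: GroupFeatureParams = field(
        default_factory=lambda: GroupFeatureParams((0.38, 0.10), (310.0, 50.0), (0.34, 0.07))
    )
    no_ph_features: GroupFeatureParams = field(
        default_factory=lambda: GroupFeatureParams((0.62, 0.12), (430.0, 70.0), (0.21, 0.06))
    )
    pooled_features: GroupFeatureParams = field(
        default_factory=lambda: GroupFeatureParams((0.50, 0.15), (380.0, 80.0), (0.27, 0.09))
    )
    label_mode: str = "fixed_counts"
    age: tuple[float, float] = (66.0, 15.2)
    sbp: tuple[float, float] = (145.0, 20.0)
    nihss: tuple[float, float] = (17.0, 5.0)
    p_male: float = 45.0 / 83.0
    p_hypertension: float = 0.6
    p_diabetes: float = 0.25
    p_iv_tpa: float = 31.0 / 83.0
    p_thrombectomy: float = 41.0 / 83.0
    p_penumbral: float = 0.5
    lesion_delay_s: float = 8.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_ph < self.n_patients:
            raise ValueError(f"need 0 < n_ph < n_patients; got {self.n_ph}/{self.n_patients}")
        if self.label_mode not in ("fixed_counts", "published_model"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        for t in (self.age, self.sbp, self.nihss):
            if t[1] < 0:
                raise ValueError(f"negative SD in clinical distribution: {t}")


@dataclass
class PatientVolumes:
    """Raw per-patient volumes handed to the map/feature stages."""

    dsc: DscSeries
    dwi: np.ndarray
    adc: np.ndarray
    brain_mask: np.ndarray
    truth: TissueTruth


def gamma_variate_aif(
    times: np.ndarray,
    arrival: float = 9.0,
    alpha: float = 3.0,
    beta: float = 1.5,
    amplitude: float = 5.0,
    recirc_amplitude: float = 0.3,
    recirc_delay: float = 12.0,
) -> np.ndarray:
    """Gamma-variate bolus with a delayed, scaled recirculation pass.

    First pass ``A * ((t-t0)/tp)^a * exp(a*(1 - (t-t0)/tp))`` (peak value
    ``A`` at ``t0 + tp`` where ``tp = a*b``) plus ``recirc_amplitude``
    times the same shape delayed by ``recirc_delay``; zero before
    arrival.
    """
    times = np.asarray(times, dtype=float)

    def first_pass(t0: float) -> np.ndarray:
        tp = alpha * beta
        tau = np.clip(times - t0, 0.0, None) / tp
        return amplitude * tau**alpha * np.exp(alpha * (1.0 - tau))

    return first_pass(arrival) + recirc_amplitude * first_pass(arrival + recirc_delay)


def _bolus_response(acq: AcquisitionConfig, oversample: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """(fine time grid, AIF (x) exp-residue) for a unit-CBF, unit-CBV voxel.

    Computed on an oversampled grid so trapezoidal/discrete-convolution
    error stays well below the 1% CBV round-trip tolerance.
    """
    h = acq.dt / oversample
    t_fine = np.arange(0.0, acq.n_frames * acq.dt + acq.recirc_delay, h)
    aif = gamma_variate_aif(
        t_fine,
        arrival=acq.bolus_arrival,
        recirc_amplitude=acq.recirc_amplitude,
        recirc_delay=acq.recirc_delay,
    )
    residue = np.exp(-t_fine / acq.mtt)
    conv = np.convolve(aif, residue)[: t_fine.size] * h / acq.mtt
    # division by MTT makes integral(conv) = integral(aif): unit CBV scale
    return t_fine, conv


def generating_concentration(
    truth: TissueTruth, acq: AcquisitionConfig, oversample: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless generating ΔR2* curves (4D) and the normal-tissue reference curve.

    Per voxel: ``cbv_true * q(t - delay) - k2_true * cumint(q)/totint(q)``
    where ``q`` is the unit bolus response. The reference curve is ``q``
    sampled at the frame times (the curve of a normal cbv=1, delay=0,
    k2=0 voxel).
    """
    t_fine, q = _bolus_response(acq, oversample)
    times = acq.times

    ref = np.interp(times, t_fine, q)
    # leakage shape on the frame grid, in the exact convention the K2 fit
    # uses (normalized cumulative trapezoid of the reference curve), so
    # noiseless fits recover k2_true to machine precision
    cum = cumulative_trapezoid(ref, times, initial=0.0)
    leak_shape = -cum / np.trapezoid(ref, times)

    conc = np.empty(truth.shape + (acq.n_frames,), dtype=float)
    for delay in np.unique(truth.delay_map):
        sel = truth.delay_map == delay
        shifted = np.interp(times - delay, t_fine, q, left=0.0)
        conc[sel] = truth.cbv_true[sel][:, None] * shifted[None, :]
    conc += truth.k2_true[..., None] * leak_shape[None, None, None, :]
    return conc, ref


def simulate_dsc_signal(truth: TissueTruth, acq: AcquisitionConfig) -> DscSeries:
    """Simulate the 4D DSC signal: ``S0 * exp(-TE * c(t))`` plus Gaussian noise."""
    conc, _ = generating_concentration(truth, acq)
    signal = acq.s0 * np.exp(-acq.te * conc)
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(acq.rng_seed)
        signal = signal + rng.normal(0.0, acq.noise_sigma, size=signal.shape)
    return DscSeries(signal, acq.te, acq.dt, acq.baseline_frames)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def make_tissue_truth(
    cbv_p10: float,
    adc_p10: float,
    k2_p90: float,
    shape: tuple[int, int, int] = (64, 64, 16),
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 5.0),
    lesion_delay_s: float = 8.0,
    rng: np.random.Generator | None = None,
    cbv_sd: float = 0.08,
    adc_sd: float = 45.0,
    k2_sd: float = 0.04,
) -> TissueTruth:
    """Build truth maps whose lesion-voxel distributions target the given percentiles.

    Lesion voxels are drawn from normals whose 10th (CBV, ADC) or 90th
    (K2) percentile equals the requested feature value. The lesion is an
    ellipsoid in one hemisphere; the contralateral reference is a
    mirrored block of normal tissue (CBV exactly 1, K2 0, no delay).
    """
    rng = rng or np.random.default_rng(0)
    nx, ny, nz = shape
    lesion = _ellipsoid(shape, (nx * 0.28, ny * 0.5, nz * 0.5), (nx * 0.14, ny * 0.18, nz * 0.3))
    contra = np.zeros(shape, dtype=bool)
    contra[int(nx * 0.65): int(nx * 0.85), int(ny * 0.4): int(ny * 0.6), nz // 4: 3 * nz // 4] = True
    contra &= ~lesion

    n_lesion = int(lesion.sum())
    cbv = np.ones(shape)
    cbv[lesion] = np.clip(rng.normal(cbv_p10 + _Z10 * cbv_sd, cbv_sd, n_lesion), 0.05, None)
    adc = np.clip(rng.normal(800.0, 40.0, shape), 300.0, None)
    adc[lesion] = np.clip(rng.normal(adc_p10 + _Z10 * adc_sd, adc_sd, n_lesion), 50.0, None)
    k2 = np.zeros(shape)
    k2[lesion] = rng.normal(k2_p90 - _Z10 * k2_sd, k2_sd, n_lesion)
    delay = np.zeros(shape)
    delay[lesion] = lesion_delay_s

    return TissueTruth(
        adc_map=adc,
        cbf_map=cbv.copy(),  # cbf = cbv keeps mean transit time uniform
        cbv_true=cbv,
        k2_true=k2,
        delay_map=delay,
        lesion_mask=lesion,
        contralateral_mask=contra,
        voxel_size_mm=voxel_size_mm,
    )


def _make_dwi(truth: TissueTruth, rng: np.random.Generator) -> np.ndarray:
    dwi = rng.normal(100.0, 4.0, truth.shape)
    dwi[truth.lesion_mask] += 60.0
    return dwi


def _draw_features(params: GroupFeatureParams, rng: np.random.Generator) -> tuple[float, float, float]:
    cbv = float(np.clip(rng.normal(*params.cbv_p10), 0.05, None))
    adc = float(np.clip(rng.normal(*params.adc_p10), 50.0, None))
    k2 = float(rng.normal(*params.k2_p90))
    return cbv, adc, k2


def generate_cohort(
    cfg: CohortConfig,
    acq: AcquisitionConfig | None = None,
    with_volumes: bool = False,
    volume_shape: tuple[int, int, int] = (32, 32, 12),
) -> list[tuple[PatientVolumes | None, PatientRecord]]:
    """Generate a reproducible cohort of (volumes, ground-truth record) pairs.

    Records carry the *generating* feature values (the downstream
    pipeline re-measures them from the volumes), clinical covariates
    drawn independently of the label, and the PH label. With
    ``with_volumes=False`` the volume slot is None and only the tables
    are produced. Identical configs and seeds yield identical output.
    """
    rng = np.random.default_rng(cfg.rng_seed)

    if cfg.label_mode == "fixed_counts":
        labels = np.zeros(cfg.n_patients, dtype=int)
        labels[: cfg.n_ph] = 1
        labels = rng.permutation(labels)
    else:
        labels = None  # assigned per patient from the published score

    pub = published_logistic()
    cohort: list[tuple[PatientVolumes | None, PatientRecord]] = []
    for i in range(cfg.n_patients):
        if cfg.label_mode == "fixed_counts":
            label = int(labels[i])
            params = cfg.ph_features if label else cfg.no_ph_features
            cbv, adc, k2 = _draw_features(params, rng)
        else:
            cbv, adc, k2 = _draw_features(cfg.pooled_features, rng)
            label = logistic_score({"cbv_p10": cbv, "k2_p90": k2}, pub)[1]

        record = PatientRecord(
            patient_id=f"p{i:03d}",
            cbv_p10=cbv,
            adc_p10=adc,
            k2_p90=k2,
            penumbral_pattern=int(rng.random() < cfg.p_penumbral),
            age=float(np.clip(rng.normal(*cfg.age), 18.0, 95.0)),
            sex=int(rng.random() < cfg.p_male),
            hypertension=int(rng.random() < cfg.p_hypertension),
            diabetes=int(rng.random() < cfg.p_diabetes),
            sbp=float(np.clip(rng.normal(*cfg.sbp), 80.0, 250.0)),
            nihss=int(np.clip(round(rng.normal(*cfg.nihss)), 6, 29)),
            iv_tpa=int(rng.random() < cfg.p_iv_tpa),
            thrombectomy=int(rng.random() < cfg.p_thrombectomy),
            ph_label=label,
        )

        volumes = None
        if with_volumes:
            if acq is None:
                raise ValueError("acquisition config required when generating volumes")
            truth = make_tissue_truth(
                cbv, adc, k2, shape=volume_shape, rng=rng,
                lesion_delay_s=cfg.lesion_delay_s,
            )
            patient_acq = AcquisitionConfig(
                **{
                    **acq.__dict__,
                    "rng_seed": int(rng.integers(0, 2**31 - 1)),
                }
            )
            dsc = simulate_dsc_signal(truth, patient_acq)
            record.core_volume_ml = float(
                (truth.adc_map < 600.0).sum() * truth.voxel_volume_ml
            )
            record.tmax6_volume_ml = float(
                (truth.delay_map >= 6.0).sum() * truth.voxel_volume_ml
            )
            volumes = PatientVolumes(
                dsc=dsc,
                dwi=_make_dwi(truth, rng),
                adc=truth.adc_map,
                brain_mask=np.ones(truth.shape, dtype=bool),
                truth=truth,
            )
        cohort.append((volumes, record))
    return cohort
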