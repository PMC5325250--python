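"""DSC perfusion quantification.

Converts T2*-weighted dynamic susceptibility contrast (DSC) signal to
concentration (ΔR2*) curves and derives voxelwise parameter maps:

* K2 permeability from a two-regressor linear leakage model — each voxel
  curve is regressed on the reference-tissue curve and on (minus) its
  normalized cumulative integral; the coefficient on the integral term is
  K2, a dimensionless decimal fraction.
* Leakage-corrected cerebral blood volume, normalized to the mean over a
  contralateral normal-appearing white-matter reference mask (CBV ratio).
* Tmax from truncated-SVD deconvolution of the tissue curve by the
  arterial input function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

__all__ = [
    "DscSeries",
    "ConcentrationSeries",
    "LeakageFit",
    "ParameterMaps",
    "signal_to_concentration",
    "reference_curve",
    "fit_leakage",
    "compute_cbv_ratio",
    "compute_tmax",
]


@dataclass
class DscSeries:
    """4D DSC signal volume with acquisition timing.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensities.
    te : float
        Echo time in seconds; must be positive.
    dt : float
        Interval between dynamic frames in seconds; must be positive.
    baseline_frames : int
        Number of pre-bolus frames used to estimate the baseline signal S0.
    """

    data: np.ndarray
    te: float
    dt: float
    baseline_frames: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DSC data must be 4D (x,y,z,t); got shape {self.data.shape}")
        if self.te <= 0:
            raise ValueError(f"echo time must be positive; got {self.te}")
        if self.dt <= 0:
            raise ValueError(f"frame interval must be positive; got {self.dt}")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        if self.data.shape[3] < self.baseline_frames + 10:
            raise ValueError(
                f"need at least baseline_frames + 10 = {self.baseline_frames + 10} "
                f"frames; got {self.data.shape[3]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Time of each frame in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.dt


@dataclass
class ConcentrationSeries:
    """Voxelwise ΔR2*(t) in 1/s with per-voxel validity flags.

    ``valid`` marks voxels whose signal stayed positive at every frame and
    whose baseline mean was positive; invalid voxels are excluded from all
    downstream fits.
    """

    data: np.ndarray
    times: np.ndarray
    baseline_frames: int
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.data.shape[:3], dtype=bool)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class LeakageFit:
    """Per-voxel leakage-model coefficients.

    k1 is the dimensionless scaling of the voxel curve against the
    reference curve; k2 the leakage coefficient (decimal fraction);
    rms the residual root-mean-square of the fit. ``valid`` marks
    voxels where the fit was performed.
    """

    k1: np.ndarray
    k2: np.ndarray
    rms: np.ndarray
    valid: np.ndarray


@dataclass
class ParameterMaps:
    """Voxelwise parameter maps on a shared grid.

    cbv_ratio is contralateral-normalized and dimensionless, k2 a decimal
    fraction, tmax in seconds, adc in 1e-6 mm^2/s (passed through from the
    diffusion acquisition).
    """

    cbv_ratio: np.ndarray
    k2: np.ndarray
    tmax: np.ndarray
    adc: np.ndarray
    valid: np.ndarray | None = None


def signal_to_concentration(series: DscSeries, brain_mask: np.ndarray | None = None) -> ConcentrationSeries:
    """Convert DSC signal to ΔR2*(t) = -ln(S(t)/S0)/TE.

    S0 is the per-voxel mean over the baseline frames. Voxels with a
    non-positive S0 or any non-positive S(t) are flagged invalid rather
    than raising; they produce NaN curves.

    Raises
    ------
    ValueError
        If ``brain_mask`` is given and empty.
    """
    if brain_mask is not None:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if not brain_mask.any():
            raise ValueError("brain mask is empty")

    s = series.data
    s0 = s[..., : series.baseline_frames].mean(axis=3)
    valid = (s0 > 0) & (s > 0).all(axis=3)
    if brain_mask is not None:
        valid &= brain_mask

    with np.errstate(divide="ignore", invalid="ignore"):
        conc = -np.log(s / s0[..., None]) / series.te
    conc[~valid] = np.nan
    return ConcentrationSeries(conc, series.times, series.baseline_frames, valid)


def reference_curve(conc: ConcentrationSeries, reference_mask: np.ndarray) -> np.ndarray:
    """Mean ΔR2*(t) over the (valid voxels of the) reference mask."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    use = reference_mask & conc.valid
    if not use.any():
        raise ValueError("no valid voxels in reference mask")
    return conc.data[use].mean(axis=0)


def _leakage_regressors(ref: np.ndarray, times: np.ndarray, baseline_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Post-baseline design columns: (ref, -cumtrapz(ref)/trapz(ref))."""
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(ref, times, initial=0.0)
    total = np.trapezoid(ref, times)
    if total == 0:
        raise ValueError("reference curve integrates to zero")
    x1 = ref[baseline_frames:]
    x2 = -cum[baseline_frames:] / total
    return x1, x2


def fit_leakage(conc: ConcentrationSeries, ref: np.ndarray, mask: np.ndarray | None = None) -> LeakageFit:
    """Fit the two-regressor leakage model per voxel by ordinary least squares.

    Over the post-baseline frames each voxel curve is modeled as
    ``K1 * ref(t) + K2 * (-cumint(ref)(t) / totint(ref))``; normalizing
    the integral regressor by the total reference integral makes K2 a
    dimensionless decimal fraction. Voxels where the 2x2 normal-equation
    system is singular are flagged invalid.
    """
    ref = np.asarray(ref, dtype=float)
    if not np.any(ref != 0):
        raise ValueError("reference curve is identically zero")

    shape = conc.data.shape[:3]
    use = conc.valid.copy()
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)

    x1, x2 = _leakage_regressors(ref, conc.times, conc.baseline_frames)
    X = np.column_stack([x1, x2])
    gram = X.T @ X
    if np.linalg.cond(gram) > 1e12:
        # ref proportional to its own integral cannot happen for a peaked
        # bolus; treat as a global degenerate input.
        k1 = np.full(shape, np.nan)
        return LeakageFit(k1, k1.copy(), k1.copy(), np.zeros(shape, dtype=bool))

    y = conc.data[use][:, conc.baseline_frames:]
    coef = np.linalg.solve(gram, X.T @ y.T)  # (2, n_voxels)
    resid = y - (X @ coef).T
    rms_vals = np.sqrt((resid**2).mean(axis=1))

    k1 = np.full(shape, np.nan)
    k2 = np.full(shape, np.nan)
    rms = np.full(shape, np.nan)
    k1[use] = coef[0]
    k2[use] = coef[1]
    rms[use] = rms_vals
    return LeakageFit(k1, k2, rms, use)


def compute_cbv_ratio(
    conc: ConcentrationSeries,
    fit: LeakageFit,
    reference_mask: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Leakage-corrected CBV as a ratio to the reference-mask mean.

    The fitted K2 leakage term is subtracted from each voxel curve before
    trapezoidal integration over the post-baseline frames. Negative
    corrected integrals are retained, not clipped.

    Raises
    ------
    ValueError
        If the mean corrected CBV over the reference mask is non-positive.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    use = conc.valid & fit.valid
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
        use |= reference_mask & conc.valid & fit.valid

    b = conc.baseline_frames
    ref = reference_curve(conc, reference_mask)
    _, x2 = _leakage_regressors(ref, conc.times, b)

    t_post = conc.times[b:]
    curves = conc.data[use][:, b:]
    corrected = curves - fit.k2[use][:, None] * x2[None, :]
    cbv = np.trapezoid(corrected, t_post, axis=1)

    cbv_map = np.full(conc.data.shape[:3], np.nan)
    cbv_map[use] = cbv

    ref_vals = cbv_map[reference_mask & use]
    ref_mean = ref_vals.mean()
    if not np.isfinite(ref_mean) or ref_mean <= 0:
        raise ValueError(f"reference-mask mean CBV is non-positive ({ref_mean}); cannot normalize")
    return cbv_map / ref_mean


def compute_tmax(
    conc: ConcentrationSeries,
    aif: np.ndarray,
    mask: np.ndarray | None = None,
    sv_threshold: float = 0.15,
) -> np.ndarray:
    """Tmax map by truncated-SVD deconvolution of voxel curves by the AIF.

    A lower-triangular Toeplitz convolution matrix is built from the AIF
    (post-baseline frames, resampled to interval midpoints so the
    quadrature carries no half-frame phase lag), inverted with singular
    values below ``sv_threshold * max(sv)`` discarded, and applied to
    each voxel curve. Tmax is the time of the maximum of the recovered
    residue function, quantized to the frame interval.

    Raises
    ------
    ValueError
        If the AIF is flat (no bolus peak).
    """
    aif = np.asarray(aif, dtype=float)
    if np.ptp(aif) == 0:
        raise ValueError("AIF is flat; cannot deconvolve")

    b = conc.baseline_frames
    a_post = aif[b:]
    n = a_post.size
    t_rel = np.arange(n) * conc.dt
    a_mid = np.interp(t_rel - conc.dt / 2.0, t_rel, a_post, left=0.0)
    A = conc.dt * toeplitz(a_mid, np.zeros(n))

    u, s, vt = np.linalg.svd(A)
    keep = s >= sv_threshold * s.max()
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    A_inv = (vt.T * s_inv) @ u.T

    use = conc.valid.copy()
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)

    curves = conc.data[use][:, b:]
    residue = curves @ A_inv.T
    tmax_vals = residue.argmax(axis=1) * conc.dt

    tmax = np.full(conc.data.shape[:3], np.nan)
    tmax[use] = tmax_vals
    return tmax
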