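"""FRAP curve normalization, replicate averaging and recovery fitting.

A fluorescence-recovery-after-photobleaching measurement yields, per
bleached spot, the bleached-region intensity and the intensity of an
unbleached reference spot that tracks acquisition photobleaching.  The
double normalization divides the bleached by the reference signal
(removing acquisition bleaching), then rescales affinely so that the
pre-bleach mean maps to 1 and the first post-bleach frame to 0.  The
mean of the normalized replicate curves is fitted with

    R(t) = M * (1 - exp(-t / tau)),

where ``tau`` is the recovery lifetime and ``1 - M`` the immobile
fraction (defined from the fitted plateau, not the last measured point,
since slow exchange need not reach plateau within the imaging window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapCurve",
    "AveragedFrapCurve",
    "FrapFit",
    "normalize",
    "average_curves",
    "fit_recovery",
]


@dataclass
class FrapCurve:
    """One bleached-spot time course; t < 0 pre-bleach, t = 0 bleach floor."""

    t: np.ndarray
    bleach_roi: np.ndarray
    reference_roi: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        if len(self.t) != len(self.bleach_roi):
            raise ValueError("t and bleach_roi must have equal length")
        if self.reference_roi is not None:
            self.reference_roi = np.asarray(self.reference_roi, dtype=float)
            if len(self.reference_roi) != len(self.t):
                raise ValueError("reference_roi must match t")

    @property
    def pre_mask(self) -> np.ndarray:
        return self.t < 0

    @property
    def post_mask(self) -> np.ndarray:
        return self.t >= 0


@dataclass
class AveragedFrapCurve:
    t: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_curves: int


@dataclass
class FrapFit:
    tau: float
    mobile_amplitude: float
    tau_stderr: float = np.nan
    mobile_stderr: float = np.nan
    converged: bool = True

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_amplitude


def normalize(curve: FrapCurve) -> FrapCurve:
    """Double normalization against the unbleached reference.

    Ratio ``bleach_roi / reference_roi`` first (acquisition-bleach
    correction; frames where the reference is non-positive are dropped
    with a warning), then an affine rescale mapping the pre-bleach mean
    of the ratio to 1 and the first post-bleach point to 0.
    """
    if not np.any(curve.pre_mask):
        raise ValueError("curve has no pre-bleach frames")
    if not np.any(curve.post_mask):
        raise ValueError("curve has no post-bleach frames")

    t = curve.t
    if curve.reference_roi is not None:
        good = curve.reference_roi > 0
        if not good.all():
            warnings.warn("reference ROI non-positive in some frames; dropped")
        t = t[good]
        ratio = curve.bleach_roi[good] / curve.reference_roi[good]
        ref = curve.reference_roi[good]
    else:
        ratio = curve.bleach_roi.copy()
        ref = None
    pre = t < 0
    post = ~pre
    if not pre.any() or not post.any():
        raise ValueError("normalization frames lost while dropping bad reference")
    r_pre = float(np.mean(ratio[pre]))
    r0 = float(ratio[post][0])
    if abs(r_pre - r0) < 1e-12:
        raise ValueError("pre-bleach and first post-bleach levels coincide")
    normalized = (ratio - r0) / (r_pre - r0)
    return FrapCurve(t=t, bleach_roi=curve.bleach_roi[curve.reference_roi > 0]
                     if curve.reference_roi is not None else curve.bleach_roi,
                     reference_roi=ref, normalized=normalized)


def average_curves(curves: list) -> AveragedFrapCurve:
    """Pointwise mean and SEM of normalized curves on a common time base.

    Curves on shifted grids are resampled by linear interpolation onto
    the time base of the first curve (restricted to the overlap).
    """
    if len(curves) == 0:
        raise ValueError("no curves to average")
    for c in curves:
        if c.normalized is None:
            raise ValueError("curves must be normalized first")
    base = curves[0].t
    t_lo = max(c.t[0] for c in curves)
    t_hi = min(c.t[-1] for c in curves)
    base = base[(base >= t_lo - 1e-12) & (base <= t_hi + 1e-12)]
    stack = np.vstack([np.interp(base, c.t, c.normalized) for c in curves])
    mean = stack.mean(axis=0)
    if len(curves) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        warnings.warn("single curve; SEM undefined")
        sem = np.full_like(mean, np.nan)
    return AveragedFrapCurve(t=base, mean=mean, sem=sem, n_curves=len(curves))


def fit_recovery(curve, t: np.ndarray | None = None) -> FrapFit:
    """Fit R(t) = M (1 - exp(-t/tau)) to the post-bleach recovery.

    Accepts an :class:`AveragedFrapCurve`, a normalized
    :class:`FrapCurve`, or explicit ``(values, t)`` arrays.  Only the
    t >= 0 portion is fitted.  Standard errors come from the fit
    covariance; a mobile amplitude above 1.05 triggers a warning that
    the normalization is suspect.
    """
    if isinstance(curve, AveragedFrapCurve):
        tt, yy = curve.t, curve.mean
    elif isinstance(curve, FrapCurve):
        if curve.normalized is None:
            raise ValueError("normalize the curve first")
        tt, yy = curve.t, curve.normalized
    else:
        yy = np.asarray(curve, dtype=float)
        if t is None:
            raise ValueError("time base required with raw arrays")
        tt = np.asarray(t, dtype=float)
    post = tt >= 0
    tt, yy = tt[post], yy[post]
    if tt.size < 3:
        raise ValueError("need at least 3 post-bleach points")

    def model(x, m, tau):
        return m * (1.0 - np.exp(-x / tau))

    plateau0 = float(np.clip(np.mean(yy[-max(tt.size // 10, 1):]), 0.05, 1.5))
    tau0 = max(float(tt[-1]) / 3.0, 1e-6)
    try:
        popt, pcov = curve_fit(model, tt, yy, p0=[plateau0, tau0],
                               bounds=([0.0, 1e-9], [2.0, np.inf]), maxfev=10000)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        fit = FrapFit(tau=float(popt[1]), mobile_amplitude=float(popt[0]),
                      tau_stderr=float(se[1]), mobile_stderr=float(se[0]))
    except RuntimeError:
        return FrapFit(tau=np.nan, mobile_amplitude=np.nan, converged=False)
    if fit.mobile_amplitude > 1.05:
        warnings.warn("fitted mobile amplitude > 1.05; normalization suspect")
    return fit
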