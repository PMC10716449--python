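"""Trace extraction from two-channel single-molecule movies.

Covers the standard TIRF colocalization pipeline: morphological
background subtraction, local-maxima spot detection refined by 2-D
Gaussian fitting with PSF-width rejection, affine channel registration
from control points, stage-drift correction from the far-red reference
frames, fixed-radius intensity extraction, and edge-preserving
Chung-Kennedy trace filtering.

Coordinate convention: 0-based pixel-center coordinates, ``x`` along
columns and ``y`` along rows; all transforms operate in pixel units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.morphology import disk, opening
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageStack",
    "Spot",
    "AffineTransform",
    "subtract_background",
    "detect_spots",
    "fit_spot_gaussian",
    "estimate_transform",
    "correct_drift",
    "extract_traces",
    "ck_filter",
]


@dataclass
class ImageStack:
    """Multi-frame movie with a per-frame excitation-channel tag."""

    frames: np.ndarray
    channels: list | None = None
    pixel_size_nm: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (frame, row, col) array")
        if self.channels is not None and len(self.channels) != self.frames.shape[0]:
            raise ValueError("one channel tag per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    def channel_indices(self, tag: str) -> np.ndarray:
        if self.channels is None:
            return np.arange(self.n_frames)
        return np.flatnonzero(np.asarray(self.channels) == tag)

    def channel_frames(self, tag: str) -> np.ndarray:
        return self.frames[self.channel_indices(tag)]


@dataclass
class Spot:
    """Fitted diffraction-limited spot (x = column, y = row)."""

    x: float
    y: float
    amplitude: float = np.nan
    sigma: float = np.nan
    offset: float = 0.0
    fit_ok: bool = False


@dataclass
class AffineTransform:
    """2x3 matrix mapping source-channel to target-channel pixel coords."""

    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("matrix must be 2x3")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("linear part must be invertible")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        a = self.matrix[:, :2]
        b = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return AffineTransform(np.hstack([a_inv, (-a_inv @ b)[:, None]]))


def subtract_background(stack, radius_px: float, psf_sigma_px: float | None = None):
    """Rolling-ball-equivalent background removal.

    The background estimate is a grayscale opening with a disk of the
    given radius; subtracting it removes smooth offsets and gradients
    while preserving spots narrower than the disk.  Because the opening
    tracks the lower noise envelope, the residual is re-centered at zero
    via its median so that extracted intensities are unbiased.
    """
    if psf_sigma_px is not None and radius_px <= psf_sigma_px:
        warnings.warn("background radius <= PSF width; spots will be eroded")
    footprint = disk(int(round(radius_px)))

    def _one(frame):
        res = frame - opening(frame, footprint)
        return res - np.median(res)

    if isinstance(stack, ImageStack):
        out = np.stack([_one(f) for f in stack.frames])
        return ImageStack(frames=out, channels=stack.channels,
                          pixel_size_nm=stack.pixel_size_nm)
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        return _one(arr)
    return np.stack([_one(f) for f in arr])


def _robust_background(frame: np.ndarray) -> tuple[float, float]:
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, 1.4826 * mad


def detect_spots(
    frame: np.ndarray,
    min_separation_px: float = 4.0,
    threshold_sd: float = 5.0,
    psf_max_px: float = 2.5,
    window_px: int = 4,
    refine: bool = True,
) -> list[Spot]:
    """Local-maxima spot detection with Gaussian refinement.

    Candidate maxima must exceed the robust background level by
    ``threshold_sd`` standard deviations; non-maximum suppression is
    applied at ``min_separation_px``.  Candidates are refined by
    :func:`fit_spot_gaussian`; fits that fail or whose width exceeds
    ``psf_max_px`` (clusters, out-of-focus emitters) are rejected.
    """
    from skimage.feature import peak_local_max

    frame = np.asarray(frame, dtype=float)
    med, sd = _robust_background(frame)
    thr = med + threshold_sd * max(sd, 1e-12)
    peaks = peak_local_max(
        frame,
        min_distance=max(int(round(min_separation_px)), 1),
        threshold_abs=thr,
        exclude_border=window_px,
    )
    spots = []
    for (row, col) in peaks:
        if not refine:
            spots.append(Spot(x=float(col), y=float(row),
                              amplitude=float(frame[row, col] - med), fit_ok=True))
            continue
        spot = fit_spot_gaussian(frame, (float(col), float(row)), window_px=window_px)
        if spot.fit_ok and spot.sigma <= psf_max_px:
            spots.append(spot)
    return spots


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset).ravel()


def fit_spot_gaussian(
    frame: np.ndarray,
    seed_spot: tuple,
    window_px: int = 4,
    sigma_bounds: tuple = (0.3, 5.0),
) -> Spot:
    """Least-squares symmetric 2-D Gaussian + offset in a local window.

    ``seed_spot`` is an (x, y) starting position.  ``fit_ok`` is False on
    non-convergence, a vanishing amplitude (flat window) or a width
    outside ``sigma_bounds``.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    x0, y0 = float(seed_spot[0]), float(seed_spot[1])
    r0, c0 = int(round(y0)), int(round(x0))
    if (r0 - window_px < 0 or r0 + window_px >= h
            or c0 - window_px < 0 or c0 + window_px >= w):
        return Spot(x=x0, y=y0, fit_ok=False)
    win = frame[r0 - window_px:r0 + window_px + 1, c0 - window_px:c0 + window_px + 1]
    yy, xx = np.mgrid[r0 - window_px:r0 + window_px + 1, c0 - window_px:c0 + window_px + 1]

    offset0 = float(win.min())
    amp0 = float(win.max() - offset0)
    p0 = [max(amp0, 1e-6), x0, y0, 1.2, offset0]
    lo = [0.0, c0 - window_px, r0 - window_px, sigma_bounds[0], -np.inf]
    hi = [np.inf, c0 + window_px, r0 + window_px, sigma_bounds[1], np.inf]
    try:
        popt, _ = curve_fit(_gauss2d, (xx, yy), win.ravel(), p0=p0, bounds=(lo, hi),
                            maxfev=2000)
    except (RuntimeError, ValueError):
        return Spot(x=x0, y=y0, fit_ok=False)
    amp, xf, yf, sigma, offset = popt
    resid_sd = float(np.std(win.ravel() - _gauss2d((xx, yy), *popt)))
    ok = (amp > max(1e-6, 2.0 * resid_sd)
          and sigma_bounds[0] < sigma < sigma_bounds[1] * 0.999)
    return Spot(x=float(xf), y=float(yf), amplitude=float(amp), sigma=float(sigma),
                offset=float(offset), fit_ok=bool(ok))


def estimate_transform(src_points: np.ndarray, dst_points: np.ndarray) -> AffineTransform:
    """Least-squares affine registration from matched control points.

    Requires at least three non-collinear point pairs (in practice 4-6
    spots visible in both channels).  The RMS residual over the training
    points is stored on the returned transform.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 matched point pairs")
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("control points are collinear")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef.T  # (2, 3)
    resid = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform(matrix=matrix, residual_rms=rms)


def correct_drift(
    reference_frames: np.ndarray,
    reference_indices: np.ndarray | None = None,
    n_frames_total: int | None = None,
    upsample: int = 50,
) -> np.ndarray:
    """Per-frame (dx, dy) stage-drift offsets from reference-channel frames.

    Offsets are measured by image cross-correlation of each reference
    frame against the first one, then linearly interpolated across the
    intervening frames of the other channel.  A featureless reference
    frame carries the previous offset forward with a warning.  The
    returned offsets are the apparent displacement of the image content;
    subtracting them from frame-0 positions, or adding them to extraction
    positions, follows the drift.
    """
    ref = np.asarray(reference_frames, dtype=float)
    if ref.ndim != 3 or ref.shape[0] < 2:
        raise ValueError("need >= 2 reference frames")
    n_ref = ref.shape[0]
    if reference_indices is None:
        reference_indices = np.arange(n_ref)
    reference_indices = np.asarray(reference_indices)
    if n_frames_total is None:
        n_frames_total = int(reference_indices[-1]) + 1

    offsets_ref = np.zeros((n_ref, 2))
    prev = np.zeros(2)
    for i in range(1, n_ref):
        if np.std(ref[i]) < 1e-12:
            warnings.warn("featureless reference frame; carrying previous offset")
            offsets_ref[i] = prev
            continue
        shift, _, _ = phase_cross_correlation(ref[0], ref[i], upsample_factor=upsample,
                                              normalization=None)
        # shift = (row, col) displacement that moves frame i back onto frame 0;
        # the content itself moved by the negative of that.
        offsets_ref[i] = np.array([-shift[1], -shift[0]])
        prev = offsets_ref[i]

    all_idx = np.arange(n_frames_total)
    dx = np.interp(all_idx, reference_indices, offsets_ref[:, 0])
    dy = np.interp(all_idx, reference_indices, offsets_ref[:, 1])
    return np.column_stack([dx, dy])


def extract_traces(
    stack,
    positions: np.ndarray,
    radius_px: float = 2.0,
    offsets: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum pixel counts within a fixed radius of each (drifted) position.

    A pixel contributes when its center lies within ``radius_px`` of the
    drift-corrected position.  Returns ``(traces, edge_flags)`` where
    ``traces`` has shape (n_positions, n_frames); positions whose
    extraction disk ever leaves the frame are flagged edge-clipped (the
    available pixels are still summed).
    """
    frames = stack.frames if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_frames, h, w = frames.shape
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if offsets is None:
        offsets = np.zeros((n_frames, 2))
    offsets = np.asarray(offsets, dtype=float)

    yy, xx = np.mgrid[0:h, 0:w]
    traces = np.zeros((positions.shape[0], n_frames))
    edge = np.zeros(positions.shape[0], dtype=bool)
    for p, (x, y) in enumerate(positions):
        for i in range(n_frames):
            cx, cy = x + offsets[i, 0], y + offsets[i, 1]
            if (cx - radius_px < -0.5 or cx + radius_px > w - 0.5
                    or cy - radius_px < -0.5 or cy + radius_px > h - 0.5):
                edge[p] = True
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
            traces[p, i] = frames[i][mask].sum()
    return traces, edge


def ck_filter(trace: np.ndarray, window: int = 8, p_exponent: float = 2.0) -> np.ndarray:
    """Edge-preserving forward-backward nonlinear (Chung-Kennedy) filter.

    At each sample the output is a weighted mean of a forward running
    mean (over the preceding ``window`` samples) and a backward running
    mean (over the following ``window`` samples); the weights are the
    local mean-squared prediction errors of each predictor raised to
    ``-p_exponent``.  Near an intensity step the predictor that straddles
    the step acquires a large error and negligible weight, so plateaus
    are smoothed while the step edge is preserved.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if window < 2:
        raise ValueError("window must be >= 2")
    if n <= 2 * window:
        raise ValueError("trace must be longer than twice the window")

    csum = np.concatenate([[0.0], np.cumsum(x)])

    def running_mean_before(i):
        lo = max(i - window, 0)
        if i == 0:
            return x[0]
        return (csum[i] - csum[lo]) / (i - lo)

    def running_mean_after(i):
        hi = min(i + 1 + window, n)
        if i == n - 1:
            return x[-1]
        return (csum[hi] - csum[i + 1]) / (hi - i - 1)

    mean_f = np.array([running_mean_before(i) for i in range(n)])
    mean_b = np.array([running_mean_after(i) for i in range(n)])
    err_f = (x - mean_f) ** 2
    err_b = (x - mean_b) ** 2

    # local mean prediction error: causal window for forward, anti-causal
    # for backward, mirroring the directionality of each predictor
    csum_f = np.concatenate([[0.0], np.cumsum(err_f)])
    csum_b = np.concatenate([[0.0], np.cumsum(err_b)])
    var_f = np.empty(n)
    var_b = np.empty(n)
    for i in range(n):
        lo = max(i - window + 1, 0)
        var_f[i] = (csum_f[i + 1] - csum_f[lo]) / (i + 1 - lo)
        hi = min(i + window, n)
        var_b[i] = (csum_b[hi] - csum_b[i]) / (hi - i)

    with np.errstate(divide="ignore"):
        w_f = np.where(var_f > 0, var_f**-p_exponent, np.inf)
        w_b = np.where(var_b > 0, var_b**-p_exponent, np.inf)
    out = np.empty(n)
    both_inf = np.isinf(w_f) & np.isinf(w_b)
    only_f = np.isinf(w_f) & ~both_inf
    only_b = np.isinf(w_b) & ~both_inf
    finite = ~(both_inf | only_f | only_b)
    out[both_inf] = 0.5 * (mean_f[both_inf] + mean_b[both_inf])
    out[only_f] = mean_f[only_f]
    out[only_b] = mean_b[only_b]
    denom = w_f[finite] + w_b[finite]
    out[finite] = (w_f[finite] * mean_f[finite] + w_b[finite] * mean_b[finite]) / denom
    return out
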