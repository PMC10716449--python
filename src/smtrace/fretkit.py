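"""smFRET trace analysis.

Implements corrected FRET-efficiency computation with donor bleed-through
(beta) and detection-sensitivity (gamma) corrections, estimation of those
corrections from donor-only and acceptor-bleach traces, bleach-step
change-point detection, ALEX (alternating laser excitation) single-dye
validation, trace selection, per-trace-normalized histogramming with
Gaussian-mixture fitting, dynamic/static trace classification, and
donor-acceptor cross-correlation relaxation analysis.

The corrected efficiency is::

    E = (F_A - beta * F_D) / ((F_A - beta * F_D) + gamma * F_D)

with default calibration beta = 0.071, gamma = 0.463 (Cy3B/Alexa647 dye
pair on the reference instrument).

The mixture model fitted to efficiency histograms is::

    sum_i A_i * exp(-((x - c_i) / sigma_i)**2)

Note the exponent carries no factor 1/2: ``sigma_i`` is the conventional
fitted width on this parameterization and differs from a Gaussian
standard deviation by sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from smtrace.imaging import ck_filter

__all__ = [
    "DEFAULT_BETA",
    "DEFAULT_GAMMA",
    "FretTrace",
    "SelectionResult",
    "EfretHistogram",
    "GaussianMixture",
    "CrossCorrFit",
    "compute_efret",
    "estimate_corrections",
    "detect_bleach_steps",
    "validate_alex",
    "apply_selection",
    "build_histogram",
    "fit_mixture",
    "classify_trace",
    "cross_correlate",
]

DEFAULT_BETA = 0.071
DEFAULT_GAMMA = 0.463


# ---------------------------------------------------------------------------
# core types


@dataclass
class FretTrace:
    """Framewise donor/acceptor intensities plus ALEX check frames."""

    time_s: np.ndarray
    F_D: np.ndarray
    F_A: np.ndarray
    alex_A: np.ndarray | None = None
    alex_times: np.ndarray | None = None
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    background_mean: float = 0.0
    background_sd: float = 0.0
    edge_clipped: bool = False
    clustered: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.F_D = np.asarray(self.F_D, dtype=float)
        self.F_A = np.asarray(self.F_A, dtype=float)
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (len(self.time_s) == len(self.F_D) == len(self.F_A)):
            raise ValueError("time, donor and acceptor arrays must match")

    @classmethod
    def from_simulated(cls, sim, beta: float = DEFAULT_BETA,
                       gamma: float = DEFAULT_GAMMA) -> "FretTrace":
        """Wrap a simulator trace, subtracting its known background level."""
        return cls(
            time_s=sim.frame_times,
            F_D=sim.donor_counts - sim.background_mean,
            F_A=sim.acceptor_counts - sim.background_mean,
            alex_A=(None if sim.alex_acceptor_counts is None or
                    len(sim.alex_acceptor_counts) == 0
                    else sim.alex_acceptor_counts - sim.background_mean),
            alex_times=(None if sim.alex_times is None or len(sim.alex_times) == 0
                        else sim.alex_times),
            beta=beta,
            gamma=gamma,
            background_mean=0.0,
            background_sd=sim.background_sd,
        )

    @property
    def frame_interval(self) -> float:
        if len(self.time_s) < 2:
            return np.nan
        return float(np.median(np.diff(self.time_s)))

    def noise_sd(self, channel: str = "donor") -> float:
        """Robust frame-to-frame noise estimate from first differences."""
        x = self.F_D if channel == "donor" else self.F_A
        d = np.diff(x)
        if d.size == 0:
            return 0.0
        return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))

    def total_intensity(self) -> np.ndarray:
        """Donor plus gamma-corrected acceptor.

        Invariant under FRET-state changes (always the full emission rate
        of the molecule), so a downward step here reports a donor bleach
        even on conformationally dynamic traces.
        """
        return self.F_D + (self.F_A - self.beta * self.F_D) / self.gamma

    def corrected_acceptor(self) -> np.ndarray:
        """Bleed-through-corrected acceptor channel (zero after acceptor bleach)."""
        return self.F_A - self.beta * self.F_D

    def dye_bleach_steps(self) -> tuple[list[int], list[int]]:
        """Frame indices of donor and acceptor bleach events.

        Donor bleaches are steps in the total-intensity channel that fall
        to background; acceptor bleaches are steps in the corrected
        acceptor channel that are not coincident with a donor bleach (a
        donor bleach darkens both channels at once).
        """
        def filt(x):
            return ck_filter(x, window=4) if len(x) > 8 else x

        # no background gate on the total channel: it is flat under
        # conformational dynamics, and a second donor shows up as an
        # intermediate plateau that must still be counted
        total = filt(self.total_intensity())
        donor_steps = detect_bleach_steps(total)
        # an acceptor bleach is permanent: the corrected acceptor must stay
        # at background for the remainder of the trace, which separates it
        # from a transient excursion to a low-FRET conformation
        ca = filt(self.corrected_acceptor())
        noise = max(self.noise_sd("acceptor"), 1e-9)
        acceptor_steps = []
        for k in detect_bleach_steps(ca):
            if any(abs(k - kd) <= 3 for kd in donor_steps):
                continue
            pre = float(np.mean(ca[max(k - 20, 0):max(k - 1, 1)]))
            tail = ca[min(k + 2, len(ca) - 1):]
            if tail.size and float(tail.max()) < max(0.3 * pre, 4 * noise):
                acceptor_steps.append(k)
        return donor_steps, acceptor_steps

    def first_bleach_index(self) -> int | None:
        """Frame index of the earliest detected dye bleach, if any."""
        d, a = self.dye_bleach_steps()
        steps = d + a
        return min(steps) if steps else None

    def valid_slice(self) -> slice:
        """Frames up to the first bleach event (whole trace if none)."""
        idx = self.first_bleach_index()
        return slice(0, idx if idx is not None else len(self.F_D))

    def efret(self, up_to_bleach: bool = True) -> np.ndarray:
        e = compute_efret(self.F_D, self.F_A, self.beta, self.gamma)
        if up_to_bleach:
            sl = self.valid_slice()
            out = np.full_like(e, np.nan)
            out[sl] = e[sl]
            return out
        return e

    def mean_efret(self) -> float:
        e = self.efret()
        return float(np.nanmean(e)) if np.any(np.isfinite(e)) else np.nan


@dataclass
class SelectionResult:
    status: str  # "accepted" | "rejected"
    reason: str | None = None  # intensity | pre-bleach-duration | multi-step |
    #                            alex-dye-count | edge | cluster

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class EfretHistogram:
    """Per-trace-normalized efficiency histogram averaged over repeats."""

    bin_edges: np.ndarray
    mean_density: np.ndarray
    sd_across_repeats: np.ndarray
    n_traces: int
    n_repeats: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianMixture:
    """Fitted sum of A_i * exp(-((x - c_i)/sigma_i)**2) components."""

    components: list  # of (A, c, sigma), sorted by center
    k: int
    rss: float
    converged: bool = True

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for (a, c, s) in self.components:
            out += a * np.exp(-(((x - c) / s) ** 2))
        return out

    @property
    def centers(self) -> np.ndarray:
        return np.array([c for (_, c, _) in self.components])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for (a, _, _) in self.components])


@dataclass
class CrossCorrFit:
    """Averaged donor-acceptor cross-correlation and its exponential fit."""

    lags: np.ndarray
    cc_values: np.ndarray
    sem: np.ndarray
    tau_R: float = np.nan
    amplitude: float = np.nan
    offset: float = np.nan
    tau_R_stderr: float = np.nan
    n_traces: int = 0
    resolvable: bool = True
    converged: bool = True


# ---------------------------------------------------------------------------
# efficiency and corrections


def compute_efret(F_D, F_A, beta: float = DEFAULT_BETA,
                  gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Corrected FRET efficiency per frame.

    Frames with a non-positive denominator (no signal in either channel)
    are returned as NaN and excluded from downstream histograms.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    fd = np.asarray(F_D, dtype=float)
    fa = np.asarray(F_A, dtype=float)
    num = fa - beta * fd
    den = num + gamma * fd
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(np.abs(den) > 1e-12, num / den, np.nan)
    return e


def detect_bleach_steps(
    channel: np.ndarray,
    min_step: float | None = None,
    noise_sd: float | None = None,
    threshold_factor: float = 4.0,
) -> list[int]:
    """Downward intensity steps by two-plateau change-point detection.

    A single change point is placed where splitting the trace into two
    constant plateaus maximizes the likelihood (minimizes total squared
    error); it is kept if the drop exceeds ``threshold_factor`` times the
    frame-to-frame noise (or ``min_step`` if given).  The earlier segment
    is searched once more so that two-dye traces yield two steps.
    Returns sorted frame indices of the first post-step frames.
    """
    x = np.asarray(channel, dtype=float)
    n = x.size
    if n < 6:
        return []
    if noise_sd is None:
        d = np.diff(x)
        noise_sd = float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2))
    thr = min_step if min_step is not None else max(threshold_factor * noise_sd, 1e-9)

    def best_split(seg: np.ndarray) -> tuple[int | None, float]:
        m = seg.size
        if m < 6:
            return None, 0.0
        cs = np.cumsum(seg)
        css = np.cumsum(seg**2)
        ks = np.arange(2, m - 2)  # at least 2 frames per plateau
        left_n = ks.astype(float)
        right_n = m - ks
        left_mean = cs[ks - 1] / left_n
        right_mean = (cs[-1] - cs[ks - 1]) / right_n
        sse = (css[ks - 1] - left_n * left_mean**2) + (
            css[-1] - css[ks - 1] - right_n * right_mean**2)
        k = int(ks[np.argmin(sse)])
        drop = float(left_mean[k - 2] - right_mean[k - 2])
        return k, drop

    steps: list[int] = []
    k, drop = best_split(x)
    if k is not None and drop > thr:
        steps.append(k)
        # one level of recursion: a second dye gives a second step on
        # either side of the first one
        candidates = []
        k2, drop2 = best_split(x[:k])
        if k2 is not None and drop2 > thr:
            candidates.append((drop2, k2))
        k3, drop3 = best_split(x[k:])
        if k3 is not None and drop3 > thr:
            candidates.append((drop3, k + k3))
        if candidates:
            steps.append(max(candidates)[1])
    return sorted(steps)


def estimate_corrections(
    donor_only_traces: list,
    bleach_traces: list,
    plateau_frames: int = 20,
) -> tuple[float, float]:
    """Estimate (beta, gamma) from calibration traces.

    ``beta`` is the mean acceptor/donor channel ratio over donor-only
    traces (no acceptor dye present).  ``gamma`` is the mean ratio of the
    bleed-through-corrected acceptor drop to the donor rise across
    acceptor-bleach steps; traces in which no usable step is found are
    skipped.
    """
    betas = []
    for tr in donor_only_traces:
        fd, fa = np.asarray(tr.F_D, float), np.asarray(tr.F_A, float)
        sl = tr.valid_slice() if isinstance(tr, FretTrace) else slice(None)
        fd_m = np.mean(fd[sl])
        if fd_m > 0:
            betas.append(np.mean(fa[sl]) / fd_m)
    if not betas:
        raise ValueError("no usable donor-only traces")
    beta = float(np.mean(betas))

    gammas = []
    for tr in bleach_traces:
        fd, fa = np.asarray(tr.F_D, float), np.asarray(tr.F_A, float)
        fa_corr = fa - beta * fd
        steps = detect_bleach_steps(fa_corr)
        if not steps:
            continue
        k = steps[0]
        lo = max(k - plateau_frames, 0)
        hi = min(k + plateau_frames, len(fd))
        if k - lo < 3 or hi - k < 3:
            continue
        d_fa = np.mean(fa_corr[lo:k - 1]) - np.mean(fa_corr[k + 1:hi])
        d_fd = np.mean(fd[k + 1:hi]) - np.mean(fd[lo:k - 1])
        if d_fd > 0:
            gammas.append(d_fa / d_fd)
    if not gammas:
        raise ValueError("no usable acceptor-bleach steps")
    return beta, float(np.mean(gammas))


# ---------------------------------------------------------------------------
# validation and selection


def _alex_threshold(trace: FretTrace) -> float:
    sd = trace.background_sd if trace.background_sd > 0 else trace.noise_sd("acceptor")
    return trace.background_mean + 3.0 * sd


def validate_alex(trace: FretTrace) -> bool:
    """Single donor / single acceptor check via direct excitation frames.

    Passes iff the donor channel shows at most one bleach step and the
    direct-excitation acceptor signal is present at the start of the
    trace with at most one downward step (exactly one acceptor).
    """
    if trace.alex_A is None or len(trace.alex_A) == 0:
        raise ValueError("trace has no ALEX frames")
    thr = _alex_threshold(trace)
    alex = np.asarray(trace.alex_A, dtype=float)
    n_start = max(min(3, len(alex)), 1)
    acceptor_present = float(np.mean(alex[:n_start])) > thr
    alex_steps = detect_bleach_steps(alex) if len(alex) >= 6 else []
    donor_steps, _ = trace.dye_bleach_steps()
    return acceptor_present and len(alex_steps) <= 1 and len(donor_steps) <= 1


def apply_selection(
    trace: FretTrace,
    min_counts: float = 2000.0,
    min_pre_bleach_s: float = 5.0,
    initial_window_frames: int = 10,
    level_tolerance: float = 0.25,
) -> SelectionResult:
    """Accept or reject a trace by the standard smFRET criteria.

    (1) initial total fluorescence (donor plus gamma-corrected acceptor)
    above ``min_counts`` over the post-bleach baseline; (2) at least
    ``min_pre_bleach_s`` before the first bleach event; (3) a single
    bleach event per dye, with (3a) an anticorrelated donor rise to the
    pre-bleach total level when the acceptor bleaches first and (3b) a
    persistent direct-excitation acceptor signal when the donor bleaches
    first.  Edge-clipped and clustered traces are rejected outright.
    The first violated criterion is reported as the rejection reason.
    """
    if trace.edge_clipped:
        return SelectionResult("rejected", "edge")
    if trace.clustered:
        return SelectionResult("rejected", "cluster")

    donor_steps, acceptor_steps = trace.dye_bleach_steps()
    all_steps = sorted(donor_steps + acceptor_steps)

    # (1) initial total over the post-donor-bleach baseline (the only
    # segment where both channels are dark); zero for traces already
    # background-subtracted during extraction
    total = trace.total_intensity()
    init = float(np.mean(total[:initial_window_frames]))
    baseline = float(np.mean(total[donor_steps[-1]:])) if donor_steps else 0.0
    if init - baseline < min_counts:
        return SelectionResult("rejected", "intensity")

    # (2) pre-bleach duration
    if all_steps:
        t_first = trace.time_s[min(all_steps)] - trace.time_s[0]
        if t_first < min_pre_bleach_s:
            return SelectionResult("rejected", "pre-bleach-duration")

    # (3) single bleaching event per dye
    if len(donor_steps) > 1 or len(acceptor_steps) > 1 or not all_steps:
        return SelectionResult("rejected", "multi-step")

    # ALEX dye-count check
    if trace.alex_A is not None and len(trace.alex_A) > 0:
        if not validate_alex(trace):
            return SelectionResult("rejected", "alex-dye-count")

    donor_first = bool(donor_steps) and (not acceptor_steps
                                         or donor_steps[0] <= acceptor_steps[0])
    if not donor_first and acceptor_steps:
        # (3a) donor must rise to the pre-bleach total level
        k = acceptor_steps[0]
        pre_total = float(np.mean(total[max(k - 20, 0):max(k - 1, 1)]))
        fd_f = ck_filter(trace.F_D, window=4) if len(trace.F_D) > 8 else trace.F_D
        hi = min(k + 21, donor_steps[0] if donor_steps else len(fd_f))
        post_donor = float(np.mean(fd_f[k + 1:hi])) if hi > k + 1 else pre_total
        if pre_total > 0 and abs(post_donor - pre_total) > level_tolerance * pre_total:
            return SelectionResult("rejected", "alex-dye-count")
    elif donor_first and trace.alex_A is not None and len(trace.alex_A) > 0:
        # (3b) acceptor still fluorescent under direct excitation
        t_bleach = trace.time_s[donor_steps[0]]
        after = np.asarray(trace.alex_A)[np.asarray(trace.alex_times) > t_bleach]
        if after.size and float(np.mean(after[:3])) < _alex_threshold(trace):
            return SelectionResult("rejected", "alex-dye-count")

    return SelectionResult("accepted")


# ---------------------------------------------------------------------------
# histogramming and mixture fitting


HIST_RANGE = (-0.1, 1.1)


def _trace_efret_values(obj) -> np.ndarray:
    if isinstance(obj, FretTrace):
        e = obj.efret()
        return e[np.isfinite(e)]
    return np.asarray(obj, dtype=float)


def build_histogram(
    traces,
    bin_width: float = 0.02,
    min_duration_s: float = 5.0,
) -> EfretHistogram:
    """Per-trace-normalized efficiency histogram, averaged over repeats.

    ``traces`` is either a flat list (one repeat) or a list of lists (one
    inner list per independent repeat).  Each trace's histogram is
    normalized to unit mass before averaging so that every molecule
    carries equal weight; traces shorter than ``min_duration_s`` of valid
    signal are dropped.  Across repeats, the per-bin mean and standard
    deviation are reported.
    """
    if len(traces) == 0:
        raise ValueError("no traces given")
    nested = isinstance(traces[0], (list, tuple))
    repeats = traces if nested else [traces]

    n_bins = int(round((HIST_RANGE[1] - HIST_RANGE[0]) / bin_width))
    edges = np.linspace(HIST_RANGE[0], HIST_RANGE[1], n_bins + 1)

    repeat_means = []
    n_traces = 0
    for rep in repeats:
        per_trace = []
        for tr in rep:
            vals = _trace_efret_values(tr)
            if isinstance(tr, FretTrace) and len(tr.time_s) > 1:
                if vals.size * tr.frame_interval <= min_duration_s:
                    continue
            if vals.size == 0:
                continue
            h, _ = np.histogram(np.clip(vals, *HIST_RANGE), bins=edges)
            if h.sum() == 0:
                continue
            per_trace.append(h / h.sum())
            n_traces += 1
        if per_trace:
            repeat_means.append(np.mean(per_trace, axis=0))
    if not repeat_means:
        raise ValueError("no accepted traces contributed to the histogram")
    repeat_means = np.asarray(repeat_means)
    mean = repeat_means.mean(axis=0)
    sd = repeat_means.std(axis=0, ddof=1) if len(repeat_means) > 1 else np.zeros(n_bins)
    return EfretHistogram(bin_edges=edges, mean_density=mean, sd_across_repeats=sd,
                          n_traces=n_traces, n_repeats=len(repeat_means))


def _mixture_model(x, *params):
    out = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, c, s = params[i:i + 3]
        out = out + a * np.exp(-(((x - c) / s) ** 2))
    return out


def fit_mixture(hist: EfretHistogram, k: int | None = None) -> GaussianMixture:
    """Fit 2 or 3 Gaussian-form components to the mean histogram.

    If ``k`` is None, the 3-component fit is preferred only when it
    improves the residual sum of squares by at least 5% over the
    2-component fit.  Components are reported sorted by center.
    """
    if k is not None and k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    x = hist.bin_centers
    y = hist.mean_density

    def fit_k(kk: int) -> GaussianMixture:
        from scipy.signal import find_peaks

        peaks, props = find_peaks(y, height=np.max(y) * 0.05, distance=3)
        order = np.argsort(props["peak_heights"])[::-1] if peaks.size else np.array([], int)
        centers0 = list(x[peaks[order][:kk]])
        spread = [0.05, 0.5, 0.95]
        j = 0
        while len(centers0) < kk:
            cand = HIST_RANGE[0] + spread[j % 3] * (HIST_RANGE[1] - HIST_RANGE[0])
            if all(abs(cand - c) > 0.1 for c in centers0):
                centers0.append(cand)
            j += 1
            if j > 10:
                centers0.append(0.5)
        p0, lo, hi = [], [], []
        for i, c in enumerate(sorted(centers0)):
            near = np.argmin(np.abs(x - c))
            a0 = max(float(y[near]), 1e-4) if i < max(len(peaks), 1) else 1e-3
            p0 += [a0, float(np.clip(c, *HIST_RANGE)), 0.08]
            lo += [0.0, HIST_RANGE[0], 0.005]
            hi += [np.inf, HIST_RANGE[1], 1.0]
        try:
            popt, _ = curve_fit(_mixture_model, x, y, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
            converged = True
        except RuntimeError:
            popt, converged = np.array(p0), False
        comps = sorted(
            [tuple(popt[i:i + 3]) for i in range(0, len(popt), 3)],
            key=lambda c: c[1],
        )
        rss = float(np.sum((y - _mixture_model(x, *popt)) ** 2))
        return GaussianMixture(components=comps, k=kk, rss=rss, converged=converged)

    if k is not None:
        return fit_k(k)
    fit2 = fit_k(2)
    fit3 = fit_k(3)
    if fit3.converged and fit3.rss < 0.95 * fit2.rss:
        return fit3
    return fit2


# ---------------------------------------------------------------------------
# dynamic/static classification and cross-correlation


def classify_trace(
    trace: FretTrace,
    center_threshold: float = 0.2,
    window_s: float = 2.0,
    r_threshold: float = -0.3,
    amplitude_factor: float = 3.0,
) -> str:
    """Sort a trace into ``dynamic``, ``static_high`` or ``static_low``.

    A trace is dynamic when at least one sliding window of length
    ``window_s`` shows donor-acceptor Pearson correlation below
    ``r_threshold`` together with a filtered fluctuation amplitude above
    ``amplitude_factor`` times the (filter-attenuated) shot-noise level.
    Static traces are split at a mean efficiency of ``center_threshold``.
    """
    sl = trace.valid_slice()
    fd = trace.F_D[sl]
    fa = trace.F_A[sl]
    dt = trace.frame_interval
    win = max(int(round(window_s / dt)), 4) if np.isfinite(dt) else 20
    noise = max(trace.noise_sd("donor"), 1e-9)
    ck_win = 4
    filtered = ck_filter(fd, window=ck_win) if fd.size > 2 * ck_win else fd
    noise_filtered = noise / np.sqrt(ck_win)

    dynamic = False
    step = max(win // 2, 1)
    for start in range(0, max(fd.size - win + 1, 1), step):
        seg_d = fd[start:start + win]
        seg_a = fa[start:start + win]
        if seg_d.size < 4 or np.std(seg_d) == 0 or np.std(seg_a) == 0:
            continue
        r, _ = pearsonr(seg_d, seg_a)
        amp = np.std(filtered[start:start + win])
        if r < r_threshold and amp > amplitude_factor * noise_filtered:
            dynamic = True
            break
    if dynamic:
        return "dynamic"
    return "static_high" if trace.mean_efret() > center_threshold else "static_low"


def cross_correlate(
    traces: list,
    gate: float = 0.2,
    max_lag_s: float = 10.0,
    min_traces: int = 10,
) -> CrossCorrFit:
    """Averaged donor-acceptor cross-correlation and relaxation-time fit.

    For each trace with mean efficiency above ``gate`` the normalized
    cross-covariance ``CC(tau) = <dF_D(t) dF_A(t+tau)> / (sigma_D
    sigma_A)`` is computed on mean-subtracted channels up to the first
    bleach event; curves are averaged across traces with their SEM, and
    the mean is fitted with ``CC(tau) = -a exp(-tau/tau_R) + offset``.
    Anticorrelated conformational exchange gives a negative-amplitude
    decay whose time constant is the relaxation time of the kinetic
    scheme (``1/(k12+k21)`` for two states).
    """
    dts = [t.frame_interval for t in traces if np.isfinite(t.frame_interval)]
    if not dts:
        raise ValueError("traces carry no time information")
    dt = float(np.median(dts))
    n_lags = max(int(round(max_lag_s / dt)), 2)

    per_trace = []
    for tr in traces:
        if tr.mean_efret() <= gate:
            continue
        sl = tr.valid_slice()
        fd = tr.F_D[sl] - np.mean(tr.F_D[sl])
        fa = tr.F_A[sl] - np.mean(tr.F_A[sl])
        n = fd.size
        if n < 2 * n_lags or np.std(fd) == 0 or np.std(fa) == 0:
            continue
        norm = np.std(fd) * np.std(fa)
        cc = np.array([np.mean(fd[:n - k] * fa[k:]) for k in range(1, n_lags + 1)]) / norm
        per_trace.append(cc)
    if len(per_trace) < min_traces:
        raise ValueError(
            f"only {len(per_trace)} gated traces; need >= {min_traces}")

    per_trace = np.asarray(per_trace)
    mean_cc = per_trace.mean(axis=0)
    sem = per_trace.std(axis=0, ddof=1) / np.sqrt(per_trace.shape[0])
    lags = dt * np.arange(1, n_lags + 1)

    def model(t, a, tau, offset):
        return -a * np.exp(-t / tau) + offset

    a0 = max(-mean_cc[0], 1e-4)
    try:
        popt, pcov = curve_fit(model, lags, mean_cc, p0=[a0, max_lag_s / 5, 0.0],
                               bounds=([0.0, 1e-6, -1.0], [2.0, 1e4, 1.0]),
                               maxfev=10000)
        converged = True
        tau_se = float(np.sqrt(pcov[1, 1]))
    except RuntimeError:
        popt, converged, tau_se = (0.0, np.nan, 0.0), False, np.nan
    a_fit, tau_fit, off_fit = popt
    resolvable = bool(converged and tau_fit >= 2 * dt)
    if converged:
        # decay actually expressed over the observed lag range; a flat
        # (static) correlation fits a degenerate huge-tau exponential
        observed = a_fit * (np.exp(-lags[0] / tau_fit) - np.exp(-lags[-1] / tau_fit))
        if observed < 2 * float(np.mean(sem)):
            a_fit = 0.0
            tau_fit = np.nan
            resolvable = False
    return CrossCorrFit(
        lags=lags, cc_values=mean_cc, sem=sem,
        tau_R=float(tau_fit), amplitude=float(a_fit), offset=float(off_fit),
        tau_R_stderr=tau_se, n_traces=per_trace.shape[0],
        resolvable=resolvable, converged=converged,
    )
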