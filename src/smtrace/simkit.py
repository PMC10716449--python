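"""Synthetic-data generator for single-molecule fluorescence experiments.

Generates, with explicit seeding and retained ground truth:

* continuous-time Markov state trajectories (Gillespie) for conformational
  dynamics of chromatin fibers,
* rendered donor/acceptor FRET intensity traces with single-step
  photobleaching, alternating direct acceptor excitation (ALEX) frames and
  an EMCCD-like Gaussian noise model,
* bright/dark binding timelines and their rendered intensity traces,
* FRAP recovery curves with an immobile fraction and acquisition
  photobleaching of both regions of interest,
* two-channel movies (orange detection channel + far-red reference
  channel) for end-to-end tests of the trace-extraction pipeline.

Rendering convention: for a molecule of total emitted intensity ``I`` in
state with FRET efficiency ``E``, the detected donor counts are
``F_D = I * (1 - E)`` and the detected acceptor counts are
``F_A = gamma * I * E + beta * F_D``.  With this convention the standard
corrected-efficiency formula ``E = (F_A - beta F_D) / (F_A - beta F_D +
gamma F_D)`` is an exact inverse of the renderer for any ``beta >= 0``,
``gamma > 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from smtrace.frap import FrapCurve
from smtrace.imaging import ImageStack
from smtrace.kinetics import EventTimeline, Segment

__all__ = [
    "KineticScheme",
    "IlluminationSchedule",
    "PhotophysicsParams",
    "StatePath",
    "SimulatedTrace",
    "BindingParams",
    "FrapParams",
    "simulate_ctmc",
    "efret_from_distance",
    "render_fret_trace",
    "simulate_dwell_times",
    "simulate_binding_trace",
    "simulate_frap_curves",
    "render_movie",
]


def _rng(seed):
    """Accept an int seed, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# kinetic scheme and CTMC simulation


@dataclass
class KineticScheme:
    """States with mean FRET efficiencies and a transition-rate matrix.

    ``rates[i, j]`` is the transition rate (1/s) from state ``i`` to state
    ``j``; the diagonal is ignored.  This is the generative model for
    seconds-scale conformational exchange between, e.g., an open (low
    E_FRET) and a compacted (mid-to-high E_FRET) chromatin conformation.
    """

    state_labels: list[str]
    efret_means: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.efret_means = np.asarray(self.efret_means, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        n = len(self.state_labels)
        if n < 1:
            raise ValueError("need at least one state")
        if self.efret_means.shape != (n,):
            raise ValueError("efret_means must have one entry per state")
        if np.any((self.efret_means < 0) | (self.efret_means > 1)):
            raise ValueError("efret_means must lie in [0, 1]")
        if self.rates.shape != (n, n):
            raise ValueError("rates must be a square matrix matching states")
        off = self.rates[~np.eye(n, dtype=bool)]
        if off.size and np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def generator_matrix(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        q = self.generator_matrix()
        n = self.n_states
        if n == 1:
            return np.ones(1)
        # solve pi Q = 0, sum(pi) = 1 by least squares
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def relaxation_time(self) -> float:
        """Slowest relaxation time 1/|Re lambda_2| of the generator.

        For a two-state scheme this is the closed form 1/(k12 + k21).
        """
        ev = np.linalg.eigvals(self.generator_matrix())
        rates = np.sort(np.abs(ev.real))
        nonzero = rates[rates > 1e-12]
        if nonzero.size == 0:
            return np.inf
        return 1.0 / nonzero[0]

    @classmethod
    def two_state(cls, e_low: float, e_high: float, k12: float, k21: float) -> "KineticScheme":
        return cls(
            state_labels=["open", "compact"],
            efret_means=np.array([e_low, e_high]),
            rates=np.array([[0.0, k12], [k21, 0.0]]),
        )


@dataclass
class StatePath:
    """Piecewise-constant CTMC realization on [0, duration].

    ``jump_times[0] == 0`` and ``states[i]`` holds on
    ``[jump_times[i], jump_times[i+1])``.
    """

    jump_times: np.ndarray
    states: np.ndarray
    duration: float

    def __post_init__(self):
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.jump_times[0] != 0.0 or len(self.jump_times) != len(self.states):
            raise ValueError("path must start at t=0 with one state per segment")

    def state_at(self, t: float) -> int:
        i = np.searchsorted(self.jump_times, t, side="right") - 1
        return int(self.states[max(i, 0)])

    def dwell_durations(self) -> np.ndarray:
        ends = np.append(self.jump_times[1:], self.duration)
        return ends - self.jump_times

    def occupancy(self, n_states: int) -> np.ndarray:
        occ = np.zeros(n_states)
        np.add.at(occ, self.states, self.dwell_durations())
        return occ / self.duration

    def integrate_values(self, values: np.ndarray, a: float, b: float) -> float:
        """Integral of per-state ``values`` along the path over [a, b]."""
        if b <= a:
            return 0.0
        edges = np.concatenate([self.jump_times, [self.duration]])
        total = 0.0
        i0 = max(np.searchsorted(edges, a, side="right") - 1, 0)
        for i in range(i0, len(self.states)):
            seg_a, seg_b = edges[i], edges[i + 1]
            lo, hi = max(seg_a, a), min(seg_b, b)
            if hi > lo:
                total += values[self.states[i]] * (hi - lo)
            if seg_b >= b:
                break
        return total


def simulate_ctmc(
    scheme: KineticScheme,
    duration: float,
    seed=None,
    initial_state: int | None = None,
) -> StatePath:
    """Gillespie simulation of the kinetic scheme over [0, duration].

    The initial state is drawn from the stationary distribution unless
    ``initial_state`` is given.  A state whose outgoing rates are all zero
    is absorbing: the molecule stays there for the rest of the trajectory.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    if initial_state is None:
        state = int(rng.choice(scheme.n_states, p=scheme.stationary_distribution()))
    else:
        state = int(initial_state)
    rates = scheme.rates.copy()
    np.fill_diagonal(rates, 0.0)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        out = rates[state]
        k_tot = out.sum()
        if k_tot <= 0:
            break
        t += rng.exponential(1.0 / k_tot)
        if t >= duration:
            break
        state = int(rng.choice(scheme.n_states, p=out / k_tot))
        times.append(t)
        states.append(state)
    return StatePath(np.array(times), np.array(states), duration)


def efret_from_distance(r: float, r0: float) -> float:
    """Foerster relation E = 1 / (1 + (r/r0)^6).

    Maps a donor-acceptor distance to a mean transfer efficiency; used to
    translate structural distances into simulator state efficiencies.
    """
    if r0 <= 0:
        raise ValueError("Foerster radius must be positive")
    if np.any(np.asarray(r) < 0):
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + (np.asarray(r, dtype=float) / r0) ** 6)


# ---------------------------------------------------------------------------
# illumination, photophysics, trace rendering


@dataclass
class IlluminationSchedule:
    """Camera timing and excitation-channel cycle.

    ``cycle`` tags each frame in one repeat with its excitation channel;
    the default TIRF cycle is 99 orange frames followed by one far-red
    (direct acceptor excitation / reference) frame, repeated 40 times,
    with 100 ms integration and a 0.3 ms inter-frame gap.
    """

    t_on: float = 0.1
    t_off: float = 0.0003
    cycle: tuple = ("orange",) * 99 + ("farred",)
    n_repeats: int = 40

    def __post_init__(self):
        if self.t_on <= 0:
            raise ValueError("t_on must be positive")
        if self.t_off < 0:
            raise ValueError("t_off must be non-negative")
        if len(self.cycle) == 0:
            raise ValueError("cycle must be non-empty")

    @property
    def frame_period(self) -> float:
        return self.t_on + self.t_off

    @property
    def n_frames(self) -> int:
        return len(self.cycle) * self.n_repeats

    @property
    def channels(self) -> np.ndarray:
        return np.array(list(self.cycle) * self.n_repeats)

    @property
    def frame_start_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_period

    @classmethod
    def uniform(cls, n_frames: int, t_on: float = 0.1, t_off: float = 0.0,
                channel: str = "orange") -> "IlluminationSchedule":
        return cls(t_on=t_on, t_off=t_off, cycle=(channel,), n_repeats=n_frames)


@dataclass
class PhotophysicsParams:
    """Dye emission, bleaching and camera-noise parameters.

    The camera noise is modelled as Gaussian with variance
    ``excess_noise_factor * signal + background_sd**2``, an approximation
    to EM-multiplied detection that is adequate at the multi-thousand
    count levels simulated here.
    """

    total_intensity: float = 3000.0
    bleach_rate_donor: float = 0.01
    bleach_rate_acceptor: float = 0.01
    background_mean: float = 200.0
    background_sd: float = 30.0
    excess_noise_factor: float = 2.0

    def __post_init__(self):
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")
        if self.bleach_rate_donor < 0 or self.bleach_rate_acceptor < 0:
            raise ValueError("bleach rates must be >= 0")
        if self.background_sd < 0 or self.excess_noise_factor < 0:
            raise ValueError("noise parameters must be >= 0")

    @classmethod
    def noiseless(cls, total_intensity: float = 3000.0) -> "PhotophysicsParams":
        return cls(
            total_intensity=total_intensity,
            bleach_rate_donor=0.0,
            bleach_rate_acceptor=0.0,
            background_mean=0.0,
            background_sd=0.0,
            excess_noise_factor=0.0,
        )

    def noise(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Detected counts for a noiseless signal array (background added)."""
        signal = np.asarray(signal, dtype=float)
        var = self.excess_noise_factor * np.clip(signal, 0, None) + self.background_sd**2
        if self.background_sd == 0 and self.excess_noise_factor == 0:
            return signal + self.background_mean
        return signal + self.background_mean + rng.normal(0.0, np.sqrt(var))


@dataclass
class SimulatedTrace:
    """Rendered per-frame intensities with full ground truth attached."""

    frame_times: np.ndarray
    donor_counts: np.ndarray
    acceptor_counts: np.ndarray
    alex_times: np.ndarray
    alex_acceptor_counts: np.ndarray
    frame_interval: float
    true_state_path: StatePath | None = None
    true_efret_per_frame: np.ndarray | None = None
    bleach_time_donor: float | None = None
    bleach_time_acceptor: float | None = None
    background_mean: float = 0.0
    background_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.donor_counts) != len(self.acceptor_counts):
            raise ValueError("donor and acceptor count arrays must match")
        for t in (self.bleach_time_donor, self.bleach_time_acceptor):
            if t is not None and t < 0:
                raise ValueError("bleach times must be >= 0")


def _overlap(a: float, b: float, lo: float, hi: float) -> float:
    return max(0.0, min(b, hi) - max(a, lo))


def _draw_bleach_time(rate: float, rng: np.random.Generator) -> float:
    if rate == np.inf:
        return 0.0
    if rate <= 0:
        return np.inf
    return float(rng.exponential(1.0 / rate))


def render_fret_trace(
    path: StatePath,
    photo: PhotophysicsParams,
    sched: IlluminationSchedule,
    efret_means: np.ndarray | None = None,
    beta: float = 0.071,
    gamma: float = 0.463,
    seed=None,
    bleach_time_donor: float | None = None,
    bleach_time_acceptor: float | None = None,
) -> SimulatedTrace:
    """Render a state path into donor/acceptor/ALEX frame intensities.

    Within each integration window the state efficiency is averaged with
    time weights, since 100-ms frames straddle kinetic jumps.  Bleach
    times are drawn exponentially from the photophysics rates unless
    passed explicitly.  After donor bleach both FRET channels fall to
    background; after acceptor bleach the donor rises to the full
    intensity and the acceptor channel retains only donor bleed-through.
    ALEX frames report direct acceptor excitation until the acceptor
    bleaches.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rng = _rng(seed)
    if efret_means is None:
        raise ValueError("efret_means (per-state efficiencies) required")
    efret_means = np.asarray(efret_means, dtype=float)

    if sched.duration < path.duration - 1e-9:
        warnings.warn("illumination schedule shorter than state path; truncating")

    t_d = bleach_time_donor if bleach_time_donor is not None else _draw_bleach_time(
        photo.bleach_rate_donor, rng)
    t_a = bleach_time_acceptor if bleach_time_acceptor is not None else _draw_bleach_time(
        photo.bleach_rate_acceptor, rng)

    starts = sched.frame_start_times
    channels = sched.channels
    t_on = sched.t_on
    i_tot = photo.total_intensity

    orange = channels == "orange"
    alex = ~orange

    fd_sig = np.zeros(orange.sum())
    fa_sig = np.zeros(orange.sum())
    e_true = np.full(orange.sum(), np.nan)
    for k, a in enumerate(starts[orange]):
        b = a + t_on
        if a >= path.duration:
            break
        b_eff = min(b, path.duration)
        t_both = min(t_d, t_a)
        len_both = _overlap(a, b_eff, 0.0, t_both)
        len_donly = _overlap(a, b_eff, t_a, t_d) if t_a < t_d else 0.0
        int_e = path.integrate_values(efret_means, a, min(b_eff, t_both)) if len_both > 0 else 0.0
        fd = i_tot * ((len_both - int_e) + len_donly) / t_on
        fa = gamma * i_tot * int_e / t_on + beta * fd
        fd_sig[k] = fd
        fa_sig[k] = fa
        if len_both > 0:
            e_true[k] = int_e / len_both

    alex_sig = np.zeros(alex.sum())
    for k, a in enumerate(starts[alex]):
        b = min(a + t_on, path.duration) if a < path.duration else a
        alex_sig[k] = i_tot * _overlap(a, b, 0.0, t_a) / t_on

    return SimulatedTrace(
        frame_times=starts[orange],
        donor_counts=photo.noise(fd_sig, rng),
        acceptor_counts=photo.noise(fa_sig, rng),
        alex_times=starts[alex],
        alex_acceptor_counts=photo.noise(alex_sig, rng),
        frame_interval=sched.frame_period,
        true_state_path=path,
        true_efret_per_frame=e_true,
        bleach_time_donor=None if t_d == np.inf else t_d,
        bleach_time_acceptor=None if t_a == np.inf else t_a,
        background_mean=photo.background_mean,
        background_sd=photo.background_sd,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


# ---------------------------------------------------------------------------
# binding timelines


@dataclass
class BindingParams:
    """Generative parameters for a binding timeline.

    Dark (unbound) intervals are exponential with apparent on-rate
    ``k_on_app``; bright (bound) intervals are drawn from a mixture of
    exponentials with component weights ``fractions`` and mean residence
    times ``taus`` (seconds, ascending), the generative inverse of a
    bi-exponential residence-time distribution.
    """

    k_on_app: float = 0.02
    fractions: tuple = (0.5, 0.5)
    taus: tuple = (6.9, 61.0)

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        t = np.asarray(self.taus, dtype=float)
        if len(f) != len(t):
            raise ValueError("fractions and taus must have equal length")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("taus must be positive and strictly increasing")
        if self.k_on_app < 0:
            raise ValueError("k_on_app must be >= 0")

    @property
    def mean_bright(self) -> float:
        return float(np.dot(self.fractions, self.taus))


def simulate_dwell_times(n: int, params: BindingParams, seed=None) -> np.ndarray:
    """Draw ``n`` bright dwell times from the exponential mixture."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    comp = rng.choice(len(params.taus), size=n, p=np.asarray(params.fractions))
    return rng.exponential(np.asarray(params.taus)[comp])


def simulate_binding_trace(
    duration: float,
    params: BindingParams,
    frame_time: float = 0.1,
    photo: PhotophysicsParams | None = None,
    seed=None,
    start_bright_prob: float | None = None,
) -> tuple[SimulatedTrace, EventTimeline]:
    """Alternating dark/bright timeline rendered to framewise counts.

    Returns the rendered trace (single channel stored in
    ``donor_counts``) together with the ground-truth segment timeline.
    Frames straddling a transition receive the time-weighted intensity.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if min(params.taus) <= frame_time:
        warnings.warn("frame time >= shortest tau; discretization will censor events")
    rng = _rng(seed)
    photo = photo or PhotophysicsParams(bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)

    if start_bright_prob is None:
        mean_dark = np.inf if params.k_on_app == 0 else 1.0 / params.k_on_app
        start_bright_prob = 0.0 if np.isinf(mean_dark) else params.mean_bright / (
            params.mean_bright + mean_dark)

    segments: list[Segment] = []
    t = 0.0
    bright = bool(rng.random() < start_bright_prob)
    while t < duration:
        if bright:
            comp = rng.choice(len(params.taus), p=np.asarray(params.fractions))
            dur = rng.exponential(params.taus[comp])
        else:
            if params.k_on_app == 0:
                dur = duration - t
            else:
                dur = rng.exponential(1.0 / params.k_on_app)
        dur = min(dur, duration - t)
        segments.append(Segment(state="bright" if bright else "dark", start_s=t,
                                duration_s=dur))
        t += dur
        bright = not bright
    if segments:
        segments[0].censored = True
        segments[-1].censored = True
    timeline = EventTimeline(segments=segments)

    n_frames = int(np.floor(duration / frame_time))
    frame_times = np.arange(n_frames) * frame_time
    bright_frac = np.zeros(n_frames)
    for seg in segments:
        if seg.state != "bright":
            continue
        lo, hi = seg.start_s, seg.start_s + seg.duration_s
        i0 = max(int(np.floor(lo / frame_time)), 0)
        i1 = min(int(np.ceil(hi / frame_time)), n_frames)
        for i in range(i0, i1):
            bright_frac[i] += _overlap(frame_times[i], frame_times[i] + frame_time, lo, hi)
    bright_frac /= frame_time
    counts = photo.noise(photo.total_intensity * bright_frac, rng)

    trace = SimulatedTrace(
        frame_times=frame_times,
        donor_counts=counts,
        acceptor_counts=np.zeros(n_frames),
        alex_times=np.array([]),
        alex_acceptor_counts=np.array([]),
        frame_interval=frame_time,
        background_mean=photo.background_mean,
        background_sd=photo.background_sd,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
    return trace, timeline


# ---------------------------------------------------------------------------
# FRAP curves


@dataclass
class FrapParams:
    """Generative parameters of a FRAP recovery measurement.

    On the fully normalized scale the recovery is
    ``R(t) = (1 - immobile_fraction) * (1 - exp(-t / tau))``.
    ``bleach_depth`` is the fraction of the pre-bleach signal removed by
    the bleach pulse; ``acquisition_bleach_rate`` is a slow photobleaching
    decay applied multiplicatively to both the bleached and the reference
    region of interest.
    """

    tau: float = 971.0
    immobile_fraction: float = 0.43
    bleach_depth: float = 0.8
    frame_interval: float = 7.2
    acquisition_bleach_rate: float = 2e-4
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must lie in [0, 1]")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must lie in (0, 1]")


def simulate_frap_curves(
    params: FrapParams,
    n_curves: int = 20,
    n_pre: int = 5,
    n_post: int = 200,
    seed=None,
) -> list[FrapCurve]:
    """Simulate raw bleached-ROI / reference-ROI FRAP curve pairs.

    Pre-bleach frames are at t < 0; the first post-bleach frame is at
    t = 0 (the bleach floor).  Both ROIs decay with the acquisition
    bleach rate over elapsed imaging time and carry Gaussian noise scaled
    to the pre-bleach intensity.
    """
    if n_pre < 1 or n_post < 2:
        raise ValueError("need >= 1 pre-bleach and >= 2 post-bleach frames")
    rng = _rng(seed)
    dt = params.frame_interval
    t = np.concatenate([np.arange(-n_pre, 0) * dt, np.arange(n_post) * dt])
    elapsed = t - t[0]
    d = params.bleach_depth
    recovery = (1.0 - params.immobile_fraction) * (1.0 - np.exp(
        -np.clip(t, 0, None) / params.tau))
    ideal = np.where(t < 0, 1.0, (1.0 - d) + d * recovery)
    decay = np.exp(-params.acquisition_bleach_rate * elapsed)

    curves = []
    for _ in range(n_curves):
        bleach = ideal * decay + rng.normal(0, params.noise_sd, size=t.size)
        ref = decay + rng.normal(0, params.noise_sd, size=t.size)
        curves.append(FrapCurve(t=t.copy(), bleach_roi=bleach, reference_roi=ref))
    return curves


# ---------------------------------------------------------------------------
# movie rendering


def gaussian_spot_image(shape: tuple, x: float, y: float, sigma: float,
                        total_counts: float) -> np.ndarray:
    """Pixel-integrated symmetric Gaussian PSF (0-based pixel centers)."""
    h, w = shape
    rows = np.arange(h)
    cols = np.arange(w)
    s = sigma * np.sqrt(2.0)
    fy = 0.5 * (erf((rows + 0.5 - y) / s) - erf((rows - 0.5 - y) / s))
    fx = 0.5 * (erf((cols + 0.5 - x) / s) - erf((cols - 0.5 - x) / s))
    return total_counts * np.outer(fy, fx)


def render_movie(
    spots: list,
    frame_shape: tuple = (64, 64),
    psf_sigma_px: float = 1.0,
    sched: IlluminationSchedule | None = None,
    transform=None,
    drift_path: np.ndarray | None = None,
    photo: PhotophysicsParams | None = None,
    reference_intensity: float | None = None,
    noise: bool = True,
    seed=None,
) -> tuple[ImageStack, list[dict]]:
    """Render a two-channel movie from (x, y, intensity-trace) spots.

    ``spots`` holds tuples ``(x, y, trace)`` in far-red (reference)
    channel coordinates; ``trace`` gives the orange-channel intensity per
    orange frame.  Far-red frames render each spot at constant
    ``reference_intensity``; orange frames render the trace intensity at
    the transform-mapped position.  ``drift_path`` (n_frames, 2) arrays
    of (dx, dy) are added to all positions frame by frame.  Noise is
    Poisson shot noise plus Gaussian read noise on top of the background.

    Returns the stack and a ground-truth registry (one dict per rendered
    spot with its positions and trace).
    """
    photo = photo or PhotophysicsParams(bleach_rate_donor=0.0, bleach_rate_acceptor=0.0)
    sched = sched or IlluminationSchedule.uniform(100)
    rng = _rng(seed)
    h, w = frame_shape
    channels = sched.channels
    n_frames = len(channels)
    if drift_path is None:
        drift_path = np.zeros((n_frames, 2))
    drift_path = np.asarray(drift_path, dtype=float)
    if drift_path.shape != (n_frames, 2):
        raise ValueError("drift_path must be (n_frames, 2)")
    if reference_intensity is None:
        reference_intensity = photo.total_intensity

    registry = []
    kept = []
    for (x, y, trace) in spots:
        if transform is not None:
            xo, yo = transform.apply(np.array([[x, y]]))[0]
        else:
            xo, yo = x, y
        margin = 2 * psf_sigma_px
        dmin, dmax = drift_path.min(axis=0), drift_path.max(axis=0)
        xs, ys = np.array([x, xo]), np.array([y, yo])
        if (xs.min() + dmin[0] <= margin or xs.max() + dmax[0] >= w - 1 - margin
                or ys.min() + dmin[1] <= margin or ys.max() + dmax[1] >= h - 1 - margin):
            warnings.warn("spot out of bounds after transform/drift; dropped")
            continue
        kept.append((x, y, np.asarray(trace, dtype=float), xo, yo))
        registry.append({
            "x_ref": x, "y_ref": y, "x_orange": xo, "y_orange": yo,
            "trace": np.asarray(trace, dtype=float),
        })

    frames = np.zeros((n_frames, h, w))
    orange_idx = 0
    for i in range(n_frames):
        dx, dy = drift_path[i]
        img = np.zeros((h, w))
        if channels[i] == "orange":
            for (x, y, trace, xo, yo) in kept:
                amp = trace[orange_idx] if orange_idx < len(trace) else 0.0
                if amp > 0:
                    img += gaussian_spot_image((h, w), xo + dx, yo + dy, psf_sigma_px, amp)
            orange_idx += 1
        else:
            for (x, y, trace, xo, yo) in kept:
                img += gaussian_spot_image((h, w), x + dx, y + dy, psf_sigma_px,
                                           reference_intensity)
        if noise:
            img = rng.poisson(img + photo.background_mean).astype(float)
            if photo.background_sd > 0:
                img += rng.normal(0, photo.background_sd, size=img.shape)
        else:
            img = img + photo.background_mean
        frames[i] = img

    stack = ImageStack(frames=frames, channels=list(channels))
    return stack, registry
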