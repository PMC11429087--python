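"""Synthetic LFP recordings and neuronal arbor image stacks with ground truth.

Every generator is a pure function of (config, seed): the same inputs always
produce bit-identical output. Ground truth (injected event times, geometric
Sholl profiles) is returned alongside the artifact so the detection and
quantification stages can be validated without any external data.

The LFP generator emulates 20-minute single-channel tectal recordings: a
1/f^alpha background plus rare high-amplitude polyspike discharges whose
dominant spectral content lies above 100 Hz, the criterion the detector uses
to call an event ictal-like. The arbor generator grows stochastic branching
trees from somata and rasterizes them into confocal-like z-stacks
(z-step 0.44 um by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigError, PlacementError, SamplingError

__all__ = [
    "LFPSimConfig",
    "EventTruth",
    "TrueEvent",
    "ArborSimConfig",
    "ArborTree",
    "GroundTruthSholl",
    "LFPRecording",
    "ImageStack",
    "generate_baseline",
    "make_event_waveform",
    "simulate_recording",
    "simulate_cohort",
    "grow_arbor",
    "true_sholl",
    "render_stack",
]

# Spike rate (Hz) used for low-frequency artifact swells.  Well below the
# 100 Hz HFO floor so artifacts exercise the detector's frequency gating.
ARTIFACT_SPIKE_RATE_HZ = 5.0
# Minimum silent gap (s) enforced between injected events so that the
# detector's merge-gap rule cannot fuse two distinct true events.
EVENT_SEPARATION_S = 1.0
_PLACEMENT_ATTEMPTS = 50


# --------------------------------------------------------------------------
# Recording container (shared with the detection stage)
# --------------------------------------------------------------------------

@dataclass
class LFPRecording:
    """A sampled single-channel voltage trace.

    Attributes
    ----------
    samples : voltage samples, arbitrary uV units.
    fs : sampling rate in Hz.
    label : free-text group / subject label.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigError("recording must be a 1-D trace")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


# --------------------------------------------------------------------------
# LFP simulation
# --------------------------------------------------------------------------

@dataclass
class LFPSimConfig:
    """Parameters of the synthetic LFP recording.

    fs : sampling rate, Hz.  Must satisfy fs >= 1000 so the 250-500 Hz
        analysis band sits below Nyquist.
    duration_s : recording length in seconds (default 1200 = 20 min).
    noise_exponent : spectral slope alpha of the 1/f^alpha background.
    baseline_rms : RMS amplitude of the background, arbitrary uV.
    event_rate : expected number of true ictal-like events per recording
        (Poisson mean).
    amp_factor_range : (lo, hi) event peak amplitude as a multiple of the
        background envelope estimate.
    spike_rate_hz : intra-event spike repetition rate; >100 Hz makes the
        event HFO-bearing.
    event_duration_range_s : (lo, hi) event duration, seconds.
    artifact_rate : expected number of low-frequency non-HFO swells.
    """

    fs: float = 2000.0
    duration_s: float = 1200.0
    noise_exponent: float = 1.0
    baseline_rms: float = 10.0
    event_rate: float = 0.0
    amp_factor_range: tuple[float, float] = (4.0, 8.0)
    spike_rate_hz: float = 150.0
    event_duration_range_s: tuple[float, float] = (0.3, 1.5)
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.fs < 2 * 500.0:
            raise ConfigError(
                f"fs={self.fs} must be at least 1000 Hz to cover the "
                "250-500 Hz band"
            )
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.baseline_rms <= 0:
            raise ConfigError("baseline_rms must be positive")
        lo, hi = self.amp_factor_range
        if lo < 1 or hi < lo:
            raise ConfigError("amp_factor_range must satisfy 1 <= lo <= hi")
        dlo, dhi = self.event_duration_range_s
        if dlo <= 0 or dhi < dlo:
            raise ConfigError("event_duration_range_s must be positive, lo <= hi")
        if self.event_rate < 0 or self.artifact_rate < 0:
            raise ConfigError("rates must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass(frozen=True)
class TrueEvent:
    """One injected event: onset/duration in seconds, peak amplitude as a
    multiple of background, and whether it carries >100 Hz energy."""

    onset_s: float
    duration_s: float
    amp_factor: float
    has_hfo: bool

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class EventTruth:
    """Ground truth for one simulated recording."""

    events: list[TrueEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset_s)

    @property
    def n_true_ictal(self) -> int:
        return sum(e.has_hfo for e in self.events)

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "onset_s": e.onset_s,
                    "duration_s": e.duration_s,
                    "amp_factor": e.amp_factor,
                    "has_hfo": e.has_hfo,
                }
                for e in self.events
            ],
            "n_true_ictal": self.n_true_ictal,
        }


def generate_baseline(cfg: LFPSimConfig, seed: int) -> LFPRecording:
    """Generate the 1/f^alpha background trace.

    The spectrum is shaped in the frequency domain: unit-variance Gaussian
    noise is multiplied by f^(-alpha/2) for f >= 1 Hz (flat below 1 Hz to
    avoid the DC singularity), transformed back, and rescaled so the trace
    RMS equals ``baseline_rms`` exactly.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / cfg.fs)
    shaping = np.ones_like(freqs)
    above = freqs >= 1.0
    shaping[above] = freqs[above] ** (-cfg.noise_exponent / 2.0)
    spec *= shaping
    trace = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(trace**2))
    trace *= cfg.baseline_rms / rms
    return LFPRecording(samples=trace, fs=cfg.fs)


def make_event_waveform(
    duration_s: float,
    amp: float,
    spike_rate_hz: float,
    fs: float,
    seed: int = 0,
) -> np.ndarray:
    """Build a Hann-tapered polyspike burst.

    The carrier is a sharpened sinusoid at ``spike_rate_hz`` (cubed sine:
    90% of its energy at the fundamental, 10% at the third harmonic), so a
    150 Hz burst has essentially all of its energy above 100 Hz while a
    5-10 Hz artifact swell keeps its energy below 100 Hz.  The peak
    amplitude is normalized to ``amp``.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    # The third harmonic of the sharpened carrier must stay below Nyquist.
    if 3 * spike_rate_hz >= fs / 2:
        raise SamplingError(
            f"fs={fs} Hz cannot represent a {spike_rate_hz} Hz polyspike burst"
        )
    n = max(int(round(duration_s * fs)), 2)
    t = np.arange(n) / fs
    phase = np.random.default_rng(seed).uniform(0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * spike_rate_hz * t + phase) ** 3
    taper = np.hanning(n)
    wave = carrier * taper
    peak = np.max(np.abs(wave))
    if peak == 0 or amp == 0:
        return np.zeros(n)
    return wave * (amp / peak)


def _background_envelope_estimate(trace: np.ndarray, fs: float) -> float:
    """Median of the smoothed analytic-signal envelope of the clean baseline.

    This is the same "background" convention the detector uses, so an event
    injected at ``amp_factor`` times this value exceeds the detector's
    threshold by construction when amp_factor > threshold_factor.
    """
    env = np.abs(signal.hilbert(trace))
    env = ndimage.uniform_filter1d(env, max(int(round(0.02 * fs)), 1))
    return float(np.median(env))


def _place_events(
    rng: np.random.Generator,
    durations: Sequence[float],
    total_s: float,
    existing: list[tuple[float, float]],
) -> list[float]:
    """Uniform rejection-sampled onsets with a minimum separation margin."""
    onsets: list[float] = []
    occupied = list(existing)
    for dur in durations:
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            hi = total_s - dur
            if hi <= 0:
                break
            onset = rng.uniform(0, hi)
            ok = all(
                onset >= o1 + EVENT_SEPARATION_S
                or onset + dur + EVENT_SEPARATION_S <= o0
                for o0, o1 in occupied
            )
            if ok:
                occupied.append((onset, onset + dur))
                onsets.append(onset)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place a {dur:.2f} s event in a {total_s:.0f} s "
                "recording without overlap"
            )
    return onsets


def simulate_recording(
    cfg: LFPSimConfig, seed: int, label: str = ""
) -> tuple[LFPRecording, EventTruth]:
    """Simulate one recording: baseline + Poisson-counted injected events.

    The true ictal event count is drawn from a Poisson law with mean
    ``cfg.event_rate``; each event's peak amplitude is ``amp_factor`` times
    the analytic background estimate of the clean baseline, with amp_factor
    uniform in ``cfg.amp_factor_range``.  Low-frequency artifact swells
    (``cfg.artifact_rate``) use the same amplitude convention but a
    5 Hz carrier, so they carry no >100 Hz energy.
    """
    rng = np.random.default_rng(seed)
    baseline_seed = int(rng.integers(2**31))
    rec = generate_baseline(cfg, baseline_seed)
    background = _background_envelope_estimate(rec.samples, cfg.fs)

    n_events = int(rng.poisson(cfg.event_rate))
    n_artifacts = int(rng.poisson(cfg.artifact_rate))
    dlo, dhi = cfg.event_duration_range_s
    ev_durs = rng.uniform(dlo, dhi, size=n_events)
    art_durs = rng.uniform(max(dlo, 1.0), max(dhi, 2.0), size=n_artifacts)
    alo, ahi = cfg.amp_factor_range
    ev_amps = rng.uniform(alo, ahi, size=n_events)
    art_amps = rng.uniform(alo, ahi, size=n_artifacts)

    ev_onsets = _place_events(rng, ev_durs, cfg.duration_s, [])
    occupied = [(o, o + d) for o, d in zip(ev_onsets, ev_durs)]
    art_onsets = _place_events(rng, art_durs, cfg.duration_s, occupied)

    truth: list[TrueEvent] = []
    trace = rec.samples
    for onset, dur, af, rate, hfo in [
        *(
            (o, d, a, cfg.spike_rate_hz, cfg.spike_rate_hz > 100.0)
            for o, d, a in zip(ev_onsets, ev_durs, ev_amps)
        ),
        *(
            (o, d, a, ARTIFACT_SPIKE_RATE_HZ, False)
            for o, d, a in zip(art_onsets, art_durs, art_amps)
        ),
    ]:
        wav = make_event_waveform(
            dur, af * background, rate, cfg.fs, seed=int(rng.integers(2**31))
        )
        i0 = int(round(onset * cfg.fs))
        trace[i0 : i0 + wav.size] += wav[: trace.size - i0]
        truth.append(TrueEvent(onset, dur, af, hfo))

    rec.label = label
    return rec, EventTruth(truth)


def simulate_cohort(
    group_specs: Sequence[tuple[str, int, LFPSimConfig]], seed: int
) -> list[tuple[str, LFPRecording, EventTruth]]:
    """Simulate labelled groups of recordings with derived per-recording seeds."""
    labels = [g[0] for g in group_specs]
    if len(set(labels)) != len(labels):
        raise ConfigError("duplicate group labels")
    master = np.random.default_rng(seed)
    out: list[tuple[str, LFPRecording, EventTruth]] = []
    for lab, n_rec, cfg in group_specs:
        if n_rec < 1:
            raise ConfigError("each group needs at least one recording")
        for _ in range(n_rec):
            rec_seed = int(master.integers(2**31))
            rec, truth = simulate_recording(cfg, rec_seed, label=lab)
            out.append((lab, rec, truth))
    return out


# --------------------------------------------------------------------------
# Arbor simulation
# --------------------------------------------------------------------------

@dataclass
class ArborSimConfig:
    """Parameters of the branching-arbor / z-stack simulation.

    Lengths are in micrometres; the rendered stack has shape (z, y, x)
    with lateral pixel size ``pixel_um`` and axial step ``z_step_um``
    (0.44 um default, the confocal z-resolution being emulated).
    """

    n_neurons: int = 1
    branch_prob: float = 0.4
    n_steps: int = 6
    segment_len_um: float = 5.0
    angle_jitter: float = 0.25
    branch_angle: float = 0.9
    field_um: tuple[float, float, float] = (80.0, 80.0, 11.0)
    pixel_um: float = 0.5
    z_step_um: float = 0.44
    noise_sd: float = 0.0
    foreground: float = 200.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ConfigError("n_neurons must be >= 1")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ConfigError("branch_prob must lie in [0, 1]")
        if self.z_step_um <= 0 or self.pixel_um <= 0:
            raise ConfigError("voxel sizes must be positive")
        if self.n_steps < 1 or self.segment_len_um <= 0:
            raise ConfigError("n_steps >= 1 and segment_len_um > 0 required")


@dataclass
class ArborTree:
    """A connected tree of straight segments rooted at a soma (um units)."""

    soma: np.ndarray
    segments: list[tuple[np.ndarray, np.ndarray]]

    def tips(self) -> list[np.ndarray]:
        starts = {tuple(np.round(s, 9)) for s, _ in self.segments}
        return [e for _, e in self.segments if tuple(np.round(e, 9)) not in starts]


@dataclass
class GroundTruthSholl:
    """Geometric Sholl profile computed from segment endpoints."""

    radii: np.ndarray
    counts: np.ndarray
    n_neurons: int = 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "radii_um": [float(r) for r in self.radii],
            "counts": [int(c) for c in self.counts],
            "total": self.total,
            "n_neurons": self.n_neurons,
        }


def _jittered_direction(
    rng: np.random.Generator, direction: np.ndarray, jitter: float, z_scale: float
) -> np.ndarray:
    d = direction + rng.normal(scale=jitter, size=3) * np.array([1.0, 1.0, z_scale])
    norm = np.linalg.norm(d)
    if norm == 0:  # pathological jitter draw; keep the parent direction
        return direction
    return d / norm


def _rotate_xy(d: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * d[0] - s * d[1], s * d[0] + c * d[1], d[2]])


def grow_arbor(cfg: ArborSimConfig, seed: int) -> ArborTree:
    """Grow one stochastic branching tree.

    Each growth step, every active tip either bifurcates into two daughter
    segments (probability ``branch_prob``) or extends a single segment.
    Daughters split by +-``branch_angle``/2 in the lateral plane (so sister
    branches diverge promptly, as real dendritic bifurcations do) and every
    direction is perturbed by Gaussian angular jitter with a damped
    z-component, keeping arbors roughly planar as dorsally-viewed tectal
    arbors are.  Expected tip count after n steps is (1 + branch_prob)^n.
    """
    rng = np.random.default_rng(seed)
    soma = np.asarray(cfg.field_um, dtype=float) / 2.0
    theta = rng.uniform(0, 2 * np.pi)
    d0 = np.array([np.cos(theta), np.sin(theta), 0.0])
    tips = [(soma.copy(), d0)]
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    z_scale = 0.15
    for _ in range(cfg.n_steps):
        new_tips = []
        for pos, dirn in tips:
            n_daughters = 2 if rng.random() < cfg.branch_prob else 1
            for j in range(n_daughters):
                base = dirn
                if n_daughters == 2:
                    base = _rotate_xy(
                        dirn, (cfg.branch_angle / 2) * (1 if j == 0 else -1)
                    )
                d = _jittered_direction(rng, base, cfg.angle_jitter, z_scale)
                length = cfg.segment_len_um * rng.uniform(0.8, 1.2)
                end = pos + d * length
                # terminate tips that would leave the field (margin 1 um)
                if np.any(end < 1.0) or np.any(
                    end > np.asarray(cfg.field_um) - 1.0
                ):
                    continue
                segments.append((pos.copy(), end))
                new_tips.append((end, d))
        tips = new_tips
    return ArborTree(soma=soma, segments=segments)


def _segment_circle_crossings(
    p: np.ndarray, q: np.ndarray, center: np.ndarray, r: float
) -> int:
    """Number of points where segment pq crosses the circle/sphere |x-c|=r.

    Solves |p + t(q-p) - c|^2 = r^2 for t in [0, 1]; each distinct root in
    the open-closed interval counts as one crossing (tangency counts once).
    """
    d = q - p
    f = p - center
    a = float(d @ d)
    if a == 0:
        return 0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = b * b - 4 * a * c
    if disc < 0:
        return 0
    sq = math.sqrt(disc)
    roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    eps = 1e-12
    count = 0
    seen: list[float] = []
    for t in roots:
        if -eps <= t <= 1 + eps and all(abs(t - s) > 1e-9 for s in seen):
            seen.append(t)
            count += 1
    return count


def true_sholl(
    trees: ArborTree | Sequence[ArborTree],
    center: np.ndarray,
    radii: Sequence[float],
    projection: bool = True,
) -> GroundTruthSholl:
    """Analytic Sholl profile from segment geometry.

    counts[i] is the total number of crossings of the tree segments with the
    circle (``projection=True``, segments projected to the x-y plane) or
    sphere (``projection=False``) of radius radii[i] around ``center``.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ConfigError("radii must be non-empty")
    if np.any(np.diff(radii) <= 0) or np.any(radii <= 0):
        raise ConfigError("radii must be strictly increasing and positive")
    if isinstance(trees, ArborTree):
        trees = [trees]
    center = np.asarray(center, dtype=float)
    dims = slice(0, 2) if projection else slice(0, 3)
    c = center[dims]
    counts = np.zeros(radii.size, dtype=int)
    for tree in trees:
        for p, q in tree.segments:
            for i, r in enumerate(radii):
                counts[i] += _segment_circle_crossings(p[dims], q[dims], c, r)
    return GroundTruthSholl(radii=radii, counts=counts, n_neurons=len(trees))


@dataclass
class ImageStack:
    """3-D intensity stack, axis order (z, y, x), with physical voxel sizes."""

    voxels: np.ndarray
    pixel_um: float
    z_step_um: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ConfigError("stack must be 3-D (z, y, x)")
        if self.pixel_um <= 0 or self.z_step_um <= 0:
            raise ConfigError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


MAX_VOXELS = 50_000_000


def render_stack(
    trees: Sequence[ArborTree],
    cfg: ArborSimConfig,
    seed: int,
    radii: Sequence[float] | None = None,
) -> tuple[ImageStack, GroundTruthSholl]:
    """Rasterize trees into a noisy z-stack plus the geometric ground truth.

    Segments are sampled at quarter-voxel steps, mapped to nearest voxels at
    ``cfg.foreground`` intensity, dilated by one voxel (so 1-voxel-thin
    structures survive a 3x3x3 median filter), then Gaussian noise of SD
    ``cfg.noise_sd`` is added.  Ground truth is computed by :func:`true_sholl`
    on the un-rasterized geometry, in projection mode, centred on the soma
    centroid.
    """
    fx, fy, fz = cfg.field_um
    nx = int(round(fx / cfg.pixel_um))
    ny = int(round(fy / cfg.pixel_um))
    nz = int(round(fz / cfg.z_step_um))
    if nx * ny * nz > MAX_VOXELS:
        raise ConfigError(
            f"stack of {nx * ny * nz} voxels exceeds the {MAX_VOXELS} budget"
        )
    for tree in trees:
        for p, q in tree.segments:
            for pt in (p, q):
                if np.any(pt < 0) or np.any(pt > np.asarray(cfg.field_um)):
                    raise ConfigError("tree extends outside the field")

    mask = np.zeros((nz, ny, nx), dtype=bool)
    step = 0.25 * min(cfg.pixel_um, cfg.z_step_um)
    scale = np.array([cfg.z_step_um, cfg.pixel_um, cfg.pixel_um])
    for tree in trees:
        for p, q in tree.segments:
            length = float(np.linalg.norm(q - p))
            n_pts = max(int(np.ceil(length / step)) + 1, 2)
            ts = np.linspace(0.0, 1.0, n_pts)
            pts = p[None, :] + ts[:, None] * (q - p)[None, :]
            zyx = pts[:, ::-1] / scale  # (x,y,z) um -> (z,y,x) voxel coords
            idx = np.round(zyx).astype(int)
            np.clip(idx[:, 0], 0, nz - 1, out=idx[:, 0])
            np.clip(idx[:, 1], 0, ny - 1, out=idx[:, 1])
            np.clip(idx[:, 2], 0, nx - 1, out=idx[:, 2])
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    # face-connected (cross) dilation: thick enough to survive a 3x3x3
    # median filter, thin enough that nearby branches stay resolvable
    mask = ndimage.binary_dilation(mask)
    voxels = np.where(mask, cfg.foreground, 0.0)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(seed)
        voxels = voxels + rng.normal(scale=cfg.noise_sd, size=voxels.shape)
        np.clip(voxels, 0.0, None, out=voxels)

    somata = np.array([t.soma for t in trees])
    center = somata.mean(axis=0)
    if radii is None:
        max_r = min(
            center[0], fx - center[0], center[1], fy - center[1]
        )
        radii = np.arange(2.0, max(max_r, 4.0), 2.0)
    truth = true_sholl(list(trees), center, radii, projection=True)
    stack = ImageStack(voxels=voxels, pixel_um=cfg.pixel_um, z_step_um=cfg.z_step_um)
    return stack, truth
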