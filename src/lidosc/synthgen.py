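"""Synthetic LFP sessions, pose trajectories, and dyskinesia score sheets.

The generator emulates the statistical structure the analysis pipeline
assumes: a 1/f^chi fractal (arrhythmic) background per wire, band-limited
oscillatory bursts (theta 5-10 Hz, beta 12-35 Hz, narrowband gamma 70-110 Hz)
shared within and across structures with controllable phase lags, bundle
common-mode artifacts, 50 Hz line contamination, keypoint tables for a rat
turning in a 55-cm circular arena, and abnormal-involuntary-movement (AIM)
score sheets on the standard monitoring schedule.  Every generated artifact
comes with a ground-truth record aligned to the 4-s analysis grid for
parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import ChannelMap, LFPSession, WireInfo

BAND_RANGES_HZ = {"theta": (5.0, 10.0), "beta": (12.0, 35.0), "NBG": (70.0, 110.0)}

#: Deterministic per-wire gain profile for shared oscillatory sources.  Wires
#: at different depths project the local source with different amplitudes;
#: a fixed cycle keeps bipolar derivations from cancelling the oscillation
#: while remaining reproducible (all gains positive so monopolar phases agree).
WIRE_GAIN_CYCLE = (1.0, 0.4, 1.3, 0.7, 1.15, 0.55, 0.85, 1.45)

#: Grid of the oscillation-detection opportunities: 8-s windows, 4-s hop.
ANALYSIS_WINDOW_S = 8.0
ANALYSIS_HOP_S = 4.0


# ---------------------------------------------------------------------------
# specs


@dataclass
class FractalSpec:
    """Power-law background: PSD proportional to 1/f^chi over [fmin, fmax]."""

    exponent_chi: float = 1.0
    scale: float = 2500.0  # variance, uV^2 (~50 uV RMS broadband)
    fmin_hz: float = 1.0
    fmax_hz: float | None = None  # None -> Nyquist

    def validate(self) -> None:
        if self.exponent_chi < 0:
            raise ValueError("exponent_chi must be >= 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.fmax_hz is not None and not self.fmin_hz < self.fmax_hz:
            raise ValueError("fmin_hz must be < fmax_hz")


@dataclass
class OscBurstSpec:
    """A band-limited oscillatory source shared by one or more structures.

    The envelope gates the burst in time (values in [0, 1]); it may be a
    scalar, a per-sample array, or a callable of time in seconds.
    phase_lag_deg gives the per-structure lag of the shared source (positive
    lag = that structure's copy is delayed).
    """

    band_name: str
    center_hz: float
    width_hz: float = 5.0
    amplitude: float = 80.0  # uV, per unit wire gain
    envelope: float | np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None
    phase_lag_deg: float | Mapping[str, float] = 0.0
    structures: Sequence[str] | None = None  # None -> all structures

    def validate(self) -> None:
        if self.band_name not in BAND_RANGES_HZ:
            raise ValueError(f"unknown band {self.band_name!r}")
        lo, hi = BAND_RANGES_HZ[self.band_name]
        if not lo <= self.center_hz <= hi:
            raise ValueError(f"center_hz {self.center_hz} outside {self.band_name} range {lo}-{hi}")
        if self.width_hz <= 0:
            raise ValueError("width_hz must be > 0")

    def lag_deg_for(self, structure: str) -> float:
        if isinstance(self.phase_lag_deg, Mapping):
            return float(self.phase_lag_deg.get(structure, 0.0))
        return float(self.phase_lag_deg)

    def applies_to(self, structure: str) -> bool:
        return self.structures is None or structure in self.structures


@dataclass
class StructureSpec:
    name: str
    hemisphere: str = "lesioned"
    n_wires: int = 4
    fractal: FractalSpec = field(default_factory=FractalSpec)


@dataclass
class SessionSpec:
    """Recipe for a synthetic multi-structure LFP session."""

    fs_hz: float = 2000.0
    duration_s: float = 120.0
    structures: list[StructureSpec] = field(default_factory=list)
    bursts: list[OscBurstSpec] = field(default_factory=list)
    common_mode_amp: float = 20.0  # uV RMS of the per-bundle shared artifact
    line_noise_amp: float = 15.0  # uV amplitude of the 50 Hz sinusoid
    sensor_noise_uv: float = 2.0  # white sensor noise RMS
    wire_gain_spread: Sequence[float] = WIRE_GAIN_CYCLE
    seed: int = 0

    def validate(self) -> None:
        if not self.structures:
            raise ValueError("at least one structure required")
        for s in self.structures:
            if s.n_wires < 2:
                raise ValueError(f"structure {s.name}: n_wires must be >= 2 (bipolar pairs)")
            s.fractal.validate()
        for b in self.bursts:
            b.validate()
            if self.fs_hz < 2 * b.center_hz:
                raise ValueError("fs_hz must be >= 2x the highest oscillation frequency")


@dataclass
class TrajectorySpec:
    """Recipe for a keypoint trajectory of a rat in a circular arena."""

    arena_diameter_cm: float = 55.0
    fps: float = 25.0
    duration_s: float = 60.0
    angular_velocity_fn: Callable[[np.ndarray], np.ndarray] | float = 0.0  # deg/s, + = contralateral
    path_radius_cm: float = 15.0
    speed_cm_s: float = 5.0
    keypoint_jitter_cm: float = 0.15
    dropout_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.path_radius_cm >= self.arena_diameter_cm / 2:
            raise ValueError("path radius must fit inside the arena")


@dataclass
class GroundTruth:
    """True generating parameters aligned to the analysis grid."""

    # LFP session truth
    analysis_times_s: np.ndarray | None = None
    band_presence: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    # keyed by (structure, hemisphere, band): bool per 4-s analysis bin
    peak_params: dict[tuple[str, str, str], dict] = field(default_factory=dict)
    phase_lags_deg: dict[tuple[str, str, str], float] = field(default_factory=dict)
    # keyed by (band, structure_a, structure_b): true lag of a relative to b
    # trajectory truth
    turns_contralateral: int | None = None
    turns_ipsilateral: int | None = None
    heading_deg: np.ndarray | None = None
    # AIM truth
    aim_schedule_min: list[int] | None = None


# ---------------------------------------------------------------------------
# body-part template (cm, body frame: +x = forward); centroid is the mean of
# all 7 points, the front is the mean of nose/ears/head top.

BODY_PARTS = ("nose", "left_ear", "right_ear", "head_top", "body_center", "tail_base", "tail_tip")

_BODY_TEMPLATE = np.array(
    [
        [8.0, 0.0],  # nose
        [5.5, 1.5],  # left ear
        [5.5, -1.5],  # right ear
        [5.5, 0.0],  # head top
        [0.0, 0.0],  # body center
        [-6.0, 0.0],  # tail base
        [-12.0, 0.0],  # tail tip
    ]
)


# ---------------------------------------------------------------------------
# generators


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_fractal_series(
    spec: FractalSpec, n_samples: int, fs_hz: float, seed=0
) -> np.ndarray:
    """Generate a zero-mean series whose PSD follows a 1/f^chi power law.

    White Gaussian noise is shaped in the frequency domain with a
    f^(-chi/2) amplitude profile over [fmin, fmax] (clamped outside), giving
    exact control of the log-log PSD slope.
    """
    spec.validate()
    if n_samples < 2**12:
        raise ValueError("n_samples must be >= 4096 for a stable power-law slope")
    if spec.scale == 0:
        return np.zeros(n_samples)
    rng = _rng(seed)
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    fmax = spec.fmax_hz if spec.fmax_hz is not None else fs_hz / 2
    f_eff = np.clip(freqs, spec.fmin_hz, fmax)
    shape = f_eff ** (-spec.exponent_chi / 2.0)
    spectrum *= shape
    spectrum[0] = 0.0
    out = np.fft.irfft(spectrum, n=n_samples)
    out -= out.mean()
    std = out.std()
    if std > 0:
        out *= math.sqrt(spec.scale) / std
    return out


def _sample_envelope(
    envelope, n_samples: int, fs_hz: float
) -> np.ndarray:
    t = np.arange(n_samples) / fs_hz
    if envelope is None:
        return np.ones(n_samples)
    if callable(envelope):
        env = np.asarray(envelope(t), dtype=float)
    elif np.isscalar(envelope):
        env = np.full(n_samples, float(envelope))
    else:
        env = np.asarray(envelope, dtype=float)
        if env.shape != (n_samples,):
            raise ValueError("envelope array must have one value per sample")
    if env.min() < 0 or env.max() > 1:
        raise ValueError("envelope values must lie in [0, 1]")
    return env


def block_envelope(duration_s: float, fs_hz: float, on_blocks: Sequence[tuple[float, float]]) -> np.ndarray:
    """Build a 0/1 per-sample envelope that is on over the given (start, stop) intervals."""
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    env = np.zeros(n)
    for start, stop in on_blocks:
        env[(t >= start) & (t < stop)] = 1.0
    return env


def _oscillation_phase(
    center_hz: float, width_hz: float, n_samples: int, fs_hz: float, rng: np.random.Generator,
    jitter_tau_s: float = 0.3,
) -> np.ndarray:
    """Instantaneous phase of a sinusoid with Ornstein-Uhlenbeck frequency jitter.

    The OU deviation has stationary std = width_hz and correlation time
    jitter_tau_s; in this slow-jitter regime the ensemble spectral peak is
    approximately Gaussian with sigma ~ width_hz.
    """
    from scipy.signal import lfilter

    dt = 1.0 / fs_hz
    a = math.exp(-dt / jitter_tau_s)
    sig = width_hz * math.sqrt(1 - a * a)
    x0 = width_hz * rng.standard_normal()
    eps = rng.standard_normal(n_samples) * sig
    dev, _ = lfilter([1.0], [1.0, -a], eps, zi=np.array([a * x0]))
    inst_freq = center_hz + dev
    phase0 = rng.uniform(0, 2 * math.pi)
    return phase0 + 2 * math.pi * np.cumsum(inst_freq) * dt


def generate_oscillation(
    spec: OscBurstSpec, n_samples: int, fs_hz: float, seed=0, *, lag_deg: float = 0.0
) -> np.ndarray:
    """Generate a narrowband oscillatory series with an approximately Gaussian
    spectral peak at center_hz (sigma ~ width_hz), gated by the envelope."""
    spec.validate()
    if fs_hz <= 2 * spec.center_hz:
        raise ValueError("center_hz must lie below Nyquist")
    rng = _rng(seed)
    env = _sample_envelope(spec.envelope, n_samples, fs_hz)
    if not env.any():
        return np.zeros(n_samples)
    phase = _oscillation_phase(spec.center_hz, spec.width_hz, n_samples, fs_hz, rng)
    return spec.amplitude * env * np.sin(phase - math.radians(lag_deg))


def analysis_grid(duration_s: float) -> np.ndarray:
    """Window-center times of the 8-s / 4-s-hop analysis grid."""
    n_cols = int(math.floor((duration_s - ANALYSIS_WINDOW_S) / ANALYSIS_HOP_S)) + 1
    if n_cols < 1:
        raise ValueError("duration shorter than one analysis window")
    return ANALYSIS_WINDOW_S / 2 + ANALYSIS_HOP_S * np.arange(n_cols)


def generate_session(spec: SessionSpec) -> tuple[LFPSession, GroundTruth]:
    """Generate a multi-structure LFP session plus aligned ground truth.

    Each wire is the sum of an independent per-wire fractal background, the
    shared oscillatory sources (delayed per structure, scaled by the wire's
    gain), a per-bundle common-mode artifact, 50 Hz line noise, and white
    sensor noise.
    """
    spec.validate()
    master = np.random.default_rng(spec.seed)
    seeds = master.spawn(4)
    rng_fractal, rng_osc, rng_cm, rng_line = seeds

    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz

    # shared source phases per burst (lag applied per structure downstream)
    burst_waves = []
    for b in spec.bursts:
        env = _sample_envelope(b.envelope, n, spec.fs_hz)
        phase = _oscillation_phase(b.center_hz, b.width_hz, n, spec.fs_hz, rng_osc)
        burst_waves.append((b, env, phase))

    records = []
    wire_signals = []
    wire_id = 0
    gains = list(spec.wire_gain_spread)
    for bundle_id, st in enumerate(spec.structures):
        common = spec.common_mode_amp * _pinkish(rng_cm, n)
        line_phase = rng_line.uniform(0, 2 * math.pi)
        line = spec.line_noise_amp * np.sin(2 * math.pi * 50.0 * t + line_phase)
        for k in range(st.n_wires):
            gain = gains[k % len(gains)]
            sig = generate_fractal_series(st.fractal, n, spec.fs_hz, rng_fractal)
            for b, env, phase in burst_waves:
                if b.applies_to(st.name):
                    lag = math.radians(b.lag_deg_for(st.name))
                    sig = sig + gain * b.amplitude * env * np.sin(phase - lag)
            sig = sig + common + line
            if spec.sensor_noise_uv > 0:
                sig = sig + spec.sensor_noise_uv * rng_fractal.standard_normal(n)
            records.append((wire_id, st.name, st.hemisphere, bundle_id))
            wire_signals.append(sig)
            wire_id += 1

    session = LFPSession(
        signals=np.array(wire_signals),
        fs_hz=spec.fs_hz,
        channel_map=ChannelMap.from_records(records),
    )

    truth = GroundTruth(analysis_times_s=analysis_grid(spec.duration_s))
    win = int(ANALYSIS_WINDOW_S * spec.fs_hz)
    hop = int(ANALYSIS_HOP_S * spec.fs_hz)
    starts = [int(round((tc - ANALYSIS_WINDOW_S / 2) * spec.fs_hz)) for tc in truth.analysis_times_s]
    for st in spec.structures:
        for b, env, _ in burst_waves:
            if not b.applies_to(st.name):
                continue
            present = np.array([env[s : s + win].mean() >= 0.5 for s in starts])
            key = (st.name, st.hemisphere, b.band_name)
            truth.band_presence[key] = present
            truth.peak_params[key] = {
                "center_hz": b.center_hz,
                "width_hz": b.width_hz,
                "amplitude": b.amplitude,
            }
    for b in spec.bursts:
        applies = [s.name for s in spec.structures if b.applies_to(s.name)]
        for i, sa in enumerate(applies):
            for sb in applies[i + 1 :]:
                # positive = sa leads sb (sa's copy is less delayed)
                truth.phase_lags_deg[(b.band_name, sa, sb)] = (
                    b.lag_deg_for(sb) - b.lag_deg_for(sa)
                )
    return session, truth


def _pinkish(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f-shaped artifact used for the bundle common mode."""
    spec = FractalSpec(exponent_chi=1.0, scale=1.0)
    return generate_fractal_series(spec, n, 2000.0, rng)


# ---------------------------------------------------------------------------
# trajectories


def generate_trajectory(spec: TrajectorySpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a 7-keypoint pose table and ground-truth turning record.

    The heading integrates the signed angular-velocity function (positive =
    contralateral = counter-clockwise).  While turning, the body centre
    orbits the arena centre at path_radius_cm, tangent to its path; with zero
    angular velocity the animal sits at path_radius from the centre.  The
    rigid keypoint template is oriented along the heading, jittered, and a
    likelihood column with dropouts is attached.
    """
    spec.validate()
    rng = _rng(spec.seed)
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    if callable(spec.angular_velocity_fn):
        omega = np.asarray(spec.angular_velocity_fn(t), dtype=float)
    else:
        omega = np.full(n, float(spec.angular_velocity_fn))
    # heading after each frame interval: the last frame reaches the full
    # integrated rotation (omega * duration for constant angular velocity)
    heading = np.cumsum(omega) / spec.fps

    # body centre: orbit tied to heading (tangent motion)
    orbit_angle = np.radians(heading - 90.0)
    centre = spec.path_radius_cm * np.column_stack([np.cos(orbit_angle), np.sin(orbit_angle)])

    cos_h = np.cos(np.radians(heading))
    sin_h = np.sin(np.radians(heading))
    pts = np.empty((n, 7, 2))
    for k, (bx, by) in enumerate(_BODY_TEMPLATE):
        pts[:, k, 0] = centre[:, 0] + bx * cos_h - by * sin_h
        pts[:, k, 1] = centre[:, 1] + bx * sin_h + by * cos_h
    pts += rng.normal(scale=spec.keypoint_jitter_cm, size=pts.shape)

    likelihood = rng.uniform(0.95, 1.0, size=(n, 7))
    if spec.dropout_prob > 0:
        drop = rng.random((n, 7)) < spec.dropout_prob
        likelihood[drop] = rng.uniform(0.0, 0.9, size=drop.sum())

    cols = {}
    for k, part in enumerate(BODY_PARTS):
        cols[(part, "x")] = pts[:, k, 0]
        cols[(part, "y")] = pts[:, k, 1]
        cols[(part, "likelihood")] = likelihood[:, k]
    table = pd.DataFrame(cols)
    table.columns = pd.MultiIndex.from_tuples(
        [("synthetic", p, c) for p, c in table.columns],
        names=["scorer", "bodyparts", "coords"],
    )

    contra, ipsi = _net_rotation_turns(heading)
    truth = GroundTruth(
        turns_contralateral=contra,
        turns_ipsilateral=ipsi,
        heading_deg=heading % 360.0,
    )
    return table, truth


def _net_rotation_turns(heading_deg: np.ndarray) -> tuple[int, int]:
    """Ground-truth full-turn counts at the 45-degree sector resolution of the
    8-sector counting rule: maximal same-sense runs of sector-boundary
    crossings, floor(run / 8) turns each."""
    # 1e-7 deg guard: cumulative-sum rounding must not drop an exact
    # boundary crossing (e.g. 2160.0 reached up to float error)
    sectors = np.floor((np.asarray(heading_deg) + 1e-7) / 45.0).astype(int)
    steps = np.diff(sectors)
    # unwrap sector steps to signed shortest transitions
    steps = (steps + 4) % 8 - 4
    contra = ipsi = 0
    run = 0
    for s in steps:
        if s == 0:
            continue
        if run == 0 or (s > 0) == (run > 0):
            run += s
        else:
            run = s
        if run >= 8:
            contra += run // 8
            run = run % 8
        elif run <= -8:
            ipsi += (-run) // 8
            run = -((-run) % 8)
    return contra, ipsi


# ---------------------------------------------------------------------------
# AIM score sheets


def aim_monitoring_grid(session_min: int = 180) -> list[int]:
    """Monitoring periods: 1 min every 5 min for the first 20 min, then every
    10 min for the rest of the session."""
    grid = [5, 10, 15, 20]
    grid += list(range(30, session_min + 1, 10))
    return [m for m in grid if m <= session_min]


def generate_aim_series(
    schedule: Sequence[int] | None = None,
    severity_profile=None,
    amplitude_profile=None,
    seed=0,
):
    """Generate a tidy AIM score sheet and its scored series.

    Profiles map (period_min, subtype) -> integer score 0-4; they may be
    callables ``f(minute, subtype)``, dicts keyed by subtype of callables, or
    None (all zeros).  Returns (sheet DataFrame, AIMSeries).
    """
    from .behavior import AIM_SUBTYPES, score_aims

    schedule = list(schedule) if schedule is not None else aim_monitoring_grid()
    rows = []
    for minute in schedule:
        for subtype in AIM_SUBTYPES:
            sev = _eval_profile(severity_profile, minute, subtype)
            amp = _eval_profile(amplitude_profile, minute, subtype)
            for name, val in (("severity", sev), ("amplitude", amp)):
                if not (isinstance(val, (int, np.integer)) and 0 <= val <= 4):
                    raise ValueError(f"{name} score {val!r} outside 0-4 at {minute} min")
            rows.append({"period_min": minute, "subtype": subtype, "severity": int(sev), "amplitude": int(amp)})
    sheet = pd.DataFrame(rows)
    return sheet, score_aims(sheet)


def _eval_profile(profile, minute: int, subtype: str) -> int:
    if profile is None:
        return 0
    if callable(profile):
        return int(profile(minute, subtype))
    if isinstance(profile, Mapping):
        sub = profile.get(subtype, 0)
        return int(sub(minute)) if callable(sub) else int(sub)
    return int(profile)


def trapezoid_envelope(
    onset_min: float, peak_start_min: float, peak_end_min: float, offset_min: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-trapezoid drug-response time course (time in seconds -> [0,1]).

    Mimics the rise-plateau-fall of dyskinesia severity after injection; the
    plateau should cover the treatment's peak window (20-60 min for the D1
    agonist, 40-80 min for L-DOPA / the D2 agonist / vehicle-style controls).
    """

    def env(t_s: np.ndarray) -> np.ndarray:
        m = np.asarray(t_s) / 60.0
        return np.interp(
            m,
            [onset_min, peak_start_min, peak_end_min, offset_min],
            [0.0, 1.0, 1.0, 0.0],
        )

    return env
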