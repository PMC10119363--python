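"""Phase synchrony and functional connectivity of narrowband oscillations.

Wires are bandpass-filtered +/- 5 Hz around the median detected peak
frequency, instantaneous phases are taken from the analytic (Hilbert)
signal, and for every wire pair (i in one structure, j in another) the
circular mean phase difference

    delta_phi_ij = <phi_i(t) - phi_j(t)>   (circular mean)

and the mean resultant vector length r_ij are computed.  Structure-level
functional connectivity is the mean r over all wire pairs; the structure
phase difference averages delta_phi only over pairs passing the r > 0.5
quality filter.  A confidence-interval-based one-sample test for the mean
angle (CircStat's circ_mtest construction) assesses deviations from zero
phase difference, with Bonferroni correction across structure pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal, stats

#: Quality filter: pairs with mean resultant length below this contribute to
#: connectivity but not to the structure-level phase difference.
R_QUALITY_THRESHOLD = 0.5

EDGE_TRIM_S = 0.5  # analytic-signal edge transients discarded at both ends


# ---------------------------------------------------------------------------
# circular statistics (resultant-vector formulation)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean direction, wrapped to [-180, 180)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    mean = math.degrees(math.atan2(np.sin(a).mean(), np.cos(a).mean()))
    return _wrap_deg(mean)


def resultant_length(angles_deg: np.ndarray) -> float:
    """Mean resultant vector length in [0, 1] (1 = perfect concentration)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.hypot(np.sin(a).mean(), np.cos(a).mean()))


def _wrap_deg(x) -> float:
    return float((x + 180.0) % 360.0 - 180.0)


def mean_angle_ci_deg(angles_deg: np.ndarray, alpha: float = 0.05) -> float:
    """Half-width (degrees) of the (1-alpha) CI for the mean direction.

    Upward-corrected chi-square construction (Zar; CircStat circ_confmean).
    Returns NaN when the concentration is too low for the CI to exist.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = len(a)
    r = resultant_length(a)
    big_r = n * r
    chi2 = stats.chi2.ppf(1 - alpha, df=1)
    if r < 0.9:
        arg = 2 * n * (2 * big_r**2 - n * chi2) / (4 * n - chi2)
        if arg <= 0 or math.sqrt(arg) > big_r:
            return float("nan")
        t = math.sqrt(arg)
    else:
        arg = n**2 - (n**2 - big_r**2) * math.exp(chi2 / n)
        if arg < 0 or math.sqrt(arg) > big_r:
            return float("nan")
        t = math.sqrt(arg)
    return math.degrees(math.acos(t / big_r))


@dataclass
class MeanAngleTest:
    mean_deg: float
    ci_halfwidth_deg: float
    mu0_deg: float
    alpha: float
    conclusive: bool
    reject: bool


def mean_angle_test(
    angles_deg: np.ndarray, mu0_deg: float = 0.0, alpha: float = 0.05,
    n_comparisons: int = 1,
) -> MeanAngleTest:
    """One-sample test for the mean angle against mu0 at level alpha.

    mu0 is rejected when it falls outside the (1-alpha) confidence interval
    of the mean direction.  ``n_comparisons`` applies a Bonferroni-adjusted
    level alpha/n.  With too little concentration (CI undefined) the test is
    flagged inconclusive.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if len(angles_deg) < 8:
        raise ValueError("need at least 8 phase-difference samples")
    level = alpha / max(int(n_comparisons), 1)
    mean = circular_mean_deg(angles_deg)
    half = mean_angle_ci_deg(angles_deg, alpha=level)
    if math.isnan(half):
        return MeanAngleTest(mean, half, mu0_deg, level, conclusive=False, reject=False)
    dist = abs(_wrap_deg(mean - mu0_deg))
    return MeanAngleTest(mean, half, mu0_deg, level, conclusive=True, reject=dist > half)


# ---------------------------------------------------------------------------
# signal-level operations


def bandpass_about_median(
    signals: np.ndarray,
    fs: float,
    detections=None,
    median_freq_hz: float | None = None,
    half_width_hz: float = 5.0,
    order: int = 4,
) -> tuple[np.ndarray, float]:
    """Zero-phase bandpass at [m-5, m+5] Hz, m = median detected peak frequency.

    ``detections`` is one DetectionSeries or a list of them (all structures
    contributing to the connectivity analysis); m is the median of the fitted
    B values over positive bins.  Alternatively pass ``median_freq_hz``
    directly.  Returns (filtered signals, m).
    """
    if median_freq_hz is None:
        median_freq_hz = median_detected_frequency(detections)
    lo, hi = median_freq_hz - half_width_hz, median_freq_hz + half_width_hz
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.atleast_2d(signals), axis=-1), median_freq_hz


def median_detected_frequency(detections) -> float:
    """Median fitted peak frequency (B) across positive bins of the given
    detection series; errors if there are no detections to define it."""
    if detections is None:
        raise ValueError("no detections supplied")
    if not isinstance(detections, (list, tuple)):
        detections = [detections]
    freqs = []
    for det in detections:
        freqs.extend(p.b for p, d in zip(det.params, det.detected) if d)
    if not freqs:
        raise ValueError("no positive detections; median frequency undefined")
    return float(np.median(freqs))


def instantaneous_phase(
    narrowband: np.ndarray, fs: float, trim_s: float = EDGE_TRIM_S
) -> np.ndarray:
    """Instantaneous phase (degrees, wrapped to [-180, 180)) of the analytic
    signal; the first and last ``trim_s`` seconds are discarded as filter/
    Hilbert edge transients."""
    z = signal.hilbert(np.asarray(narrowband, dtype=float))
    phase = np.degrees(np.angle(z))
    ntrim = int(round(trim_s * fs))
    if ntrim > 0:
        phase = phase[ntrim:-ntrim] if 2 * ntrim < len(phase) else phase[:0]
    return (phase + 180.0) % 360.0 - 180.0


@dataclass
class PhasePair:
    wire_i: int
    wire_j: int
    structure_i: str
    structure_j: str
    delta_phi_deg: float  # circular mean of phi_i - phi_j; + = wire_i leads
    r: float


def pair_phase_stats(
    phi_i_deg: np.ndarray, phi_j_deg: np.ndarray,
    wire_i: int = -1, wire_j: int = -1,
    structure_i: str = "", structure_j: str = "",
) -> PhasePair:
    """Circular mean and resultant length of the phase-difference series."""
    phi_i_deg = np.asarray(phi_i_deg, dtype=float)
    phi_j_deg = np.asarray(phi_j_deg, dtype=float)
    if phi_i_deg.shape != phi_j_deg.shape:
        raise ValueError("phase series must have equal length")
    diff = phi_i_deg - phi_j_deg
    return PhasePair(
        wire_i=wire_i, wire_j=wire_j,
        structure_i=structure_i, structure_j=structure_j,
        delta_phi_deg=circular_mean_deg(diff), r=resultant_length(diff),
    )


@dataclass
class StructureCoupling:
    structure_a: str
    structure_b: str
    mean_r: float  # functional connectivity
    mean_dphi_deg: float | None  # circular mean over quality-passing pairs
    n_pairs: int
    n_pass_filter: int


def structure_coupling(
    pairs: list[PhasePair], r_threshold: float = R_QUALITY_THRESHOLD
) -> dict[tuple[str, str], StructureCoupling]:
    """Aggregate wire-pair statistics to the structure-pair level.

    Connectivity is the mean r over all wire pairs of the structure pair;
    the phase difference is the circular mean of delta_phi over pairs with
    r above the quality threshold, or None when no pair passes.
    """
    grouped: dict[tuple[str, str], list[PhasePair]] = {}
    for p in pairs:
        grouped.setdefault((p.structure_i, p.structure_j), []).append(p)
    out = {}
    for key, plist in grouped.items():
        rs = np.array([p.r for p in plist])
        passing = [p for p in plist if p.r > r_threshold]
        dphi = (
            circular_mean_deg(np.array([p.delta_phi_deg for p in passing]))
            if passing
            else None
        )
        out[key] = StructureCoupling(
            structure_a=key[0], structure_b=key[1],
            mean_r=float(rs.mean()), mean_dphi_deg=dphi,
            n_pairs=len(plist), n_pass_filter=len(passing),
        )
    return out


def phase_to_delay(delta_phi_deg: float, f_hz: float) -> float:
    """Convert a phase difference at frequency f to a delay in milliseconds
    (positive = leading structure precedes by that many ms)."""
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    return (delta_phi_deg / 360.0) / f_hz * 1000.0


# ---------------------------------------------------------------------------
# session-level driver


def session_phase_coupling(
    session,
    detections=None,
    structures: list[tuple[str, str]] | None = None,
    time_window_s: tuple[float, float] | None = None,
    r_threshold: float = R_QUALITY_THRESHOLD,
    use_bipolar: bool = False,
    median_freq_hz: float | None = None,
    detection_gated: bool = True,
    min_joint_s: float = 1.0,
) -> dict[tuple[str, str], StructureCoupling]:
    """NBG phase coupling between all structure pairs of a session.

    Phases are computed on per-wire (monopolar) series by default, restricted
    to ``time_window_s``.  The common passband is +/- 5 Hz around the median
    detected peak frequency pooled over the supplied detection series.

    When detection series are supplied and ``detection_gated`` is True, the
    phase-difference statistics of each structure pair only use samples from
    4-s analysis bins in which both structures have a positive detection
    (the phase of an absent oscillation is noise).  Pairs with less than
    ``min_joint_s`` seconds of jointly detected signal are dropped.
    """
    from .preprocess import make_bipolar_pairs

    m = median_freq_hz if median_freq_hz is not None else median_detected_frequency(detections)
    det_by_structure: dict[str, object] = {}
    if detections is not None and detection_gated:
        det_list = detections if isinstance(detections, (list, tuple)) else [detections]
        det_by_structure = {d.structure: d for d in det_list if d.structure}
    groups = structures or session.channel_map.structures()
    phases: dict[tuple[str, str], list[tuple[int, np.ndarray]]] = {}
    for group in groups:
        sources: list[tuple[int, np.ndarray]] = []
        if use_bipolar:
            bset = make_bipolar_pairs(session)
            for k, (wi, wj, series) in enumerate(bset.pairs.get(group, [])):
                sources.append((k, series))
        else:
            for w in session.included_wires_of(*group):
                sources.append((w, session.wire(w)))
        out = []
        for ident, series in sources:
            i0 = 0
            if time_window_s is not None:
                i0 = int(time_window_s[0] * session.fs_hz)
                i1 = int(time_window_s[1] * session.fs_hz)
                series = series[i0:i1]
            nb, _ = bandpass_about_median(series, session.fs_hz, median_freq_hz=m)
            phi = instantaneous_phase(nb[0], session.fs_hz)
            t0 = (i0 + int(round(EDGE_TRIM_S * session.fs_hz))) / session.fs_hz
            out.append((ident, phi))
        sample_times = t0 + np.arange(len(phi)) / session.fs_hz
        phases[group] = (out, sample_times)
    pairs: list[PhasePair] = []
    for ga, gb in combinations(sorted(phases), 2):
        (wires_a, times_a), (wires_b, _) = phases[ga], phases[gb]
        mask = np.ones(len(times_a), dtype=bool)
        for g in (ga, gb):
            det = det_by_structure.get(g[0])
            if det is not None:
                mask &= _detection_sample_mask(det, times_a)
        if mask.sum() < min_joint_s * session.fs_hz:
            continue
        for wi, pi in wires_a:
            for wj, pj in wires_b:
                pairs.append(
                    pair_phase_stats(
                        pi[mask], pj[mask], wi, wj, structure_i=ga[0], structure_j=gb[0]
                    )
                )
    return structure_coupling(pairs, r_threshold=r_threshold)


def _detection_sample_mask(det, times_s: np.ndarray, half_window_s: float = 4.0) -> np.ndarray:
    """True for samples falling inside positively detected 4-s analysis bins."""
    mask = np.zeros(len(times_s), dtype=bool)
    for t, d in zip(det.times_s, det.detected):
        if d:
            mask |= (times_s >= t - half_window_s) & (times_s < t + half_window_s)
    return mask
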