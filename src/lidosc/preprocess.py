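"""Wideband-to-LFP preprocessing: decimation, bipolar re-referencing, channel exclusion.

Multi-wire recordings are organised as bundles of wires per anatomical
structure and hemisphere.  Local sources are emphasised by forming bipolar
derivations (differences between all unique wire pairs within a structure),
which cancels volume-conducted common-mode activity and reference artifacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Structure names used by the default implant layout.
KNOWN_STRUCTURES = ("RFA", "M1FL", "M1Tr", "DMS", "DLS", "GPe", "SNr")

HEMISPHERES = ("lesioned", "intact")


@dataclass(frozen=True)
class WireInfo:
    structure: str
    hemisphere: str
    bundle: int


@dataclass
class ChannelMap:
    """Mapping of wire ids to (structure, hemisphere, bundle)."""

    wires: dict[int, WireInfo]

    @classmethod
    def from_records(cls, records) -> "ChannelMap":
        """Build from an iterable of (wire_id, structure, hemisphere, bundle)."""
        return cls({int(w): WireInfo(s, h, int(b)) for w, s, h, b in records})

    def wires_of(self, structure: str, hemisphere: str | None = None) -> list[int]:
        out = [
            w
            for w, info in self.wires.items()
            if info.structure == structure
            and (hemisphere is None or info.hemisphere == hemisphere)
        ]
        return sorted(out)

    def structures(self) -> list[tuple[str, str]]:
        """Unique (structure, hemisphere) groups in deterministic order."""
        seen = {}
        for info in self.wires.values():
            seen.setdefault((info.structure, info.hemisphere), None)
        return sorted(seen)

    def __len__(self) -> int:
        return len(self.wires)


@dataclass
class LFPSession:
    """Per-wire LFP time series (uV) with channel map and sampling rate."""

    signals: np.ndarray  # (n_wires, n_samples), row i = wire id order of wire_ids
    fs_hz: float
    channel_map: ChannelMap
    wire_ids: list[int] = field(default_factory=list)
    excluded_wires: set[int] = field(default_factory=set)

    def __post_init__(self):
        if not self.wire_ids:
            self.wire_ids = sorted(self.channel_map.wires)
        if self.signals.ndim != 2 or self.signals.shape[0] != len(self.wire_ids):
            raise ValueError("signals must be (n_wires, n_samples) matching wire_ids")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def wire(self, wire_id: int) -> np.ndarray:
        return self.signals[self.wire_ids.index(wire_id)]

    def included_wires_of(self, structure: str, hemisphere: str | None = None) -> list[int]:
        return [
            w
            for w in self.channel_map.wires_of(structure, hemisphere)
            if w not in self.excluded_wires
        ]


@dataclass
class BipolarSet:
    """Bipolar derivations per (structure, hemisphere).

    ``pairs[(structure, hemisphere)]`` is a list of ``(wire_i, wire_j, series)``
    with wire_i < wire_j and series = wire_i - wire_j, for every unique
    unordered pair of included wires in the group.
    """

    pairs: dict[tuple[str, str], list[tuple[int, int, np.ndarray]]]
    fs_hz: float
    unusable: set[tuple[str, str]] = field(default_factory=set)

    def series_of(self, structure: str, hemisphere: str) -> list[np.ndarray]:
        return [s for _, _, s in self.pairs.get((structure, hemisphere), [])]


def decimate_lfp(
    wideband: np.ndarray,
    fs_in: float,
    fs_out: float = 2000.0,
    cutoff_hz: float = 500.0,
    order: int = 8,
) -> np.ndarray:
    """Low-pass filter and downsample a wideband series to the LFP rate.

    An 8th-order Butterworth low-pass at 500 Hz is applied forward-backward
    (zero phase), then the series is downsampled.  Output length is
    ``ceil(n * fs_out / fs_in)``.
    """
    if fs_in < fs_out:
        raise ValueError("fs_in must be >= fs_out")
    if fs_out <= 2 * cutoff_hz * 0.999 and fs_out <= 2 * cutoff_hz:
        # cutoff must sit below the output Nyquist
        if cutoff_hz >= fs_out / 2:
            raise ValueError("fs_out too low for the 500 Hz anti-alias corner")
    wideband = np.asarray(wideband, dtype=float)
    if fs_in == fs_out:
        sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_in, output="sos")
        return signal.sosfiltfilt(sos, wideband)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_in, output="sos")
    filtered = signal.sosfiltfilt(sos, wideband)
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        q = int(round(ratio))
        return filtered[::q]
    warnings.warn(
        f"non-integer decimation factor {ratio:.4f}; using polyphase resampling",
        RuntimeWarning,
        stacklevel=2,
    )
    frac = _as_fraction(fs_out / fs_in)
    out = signal.resample_poly(filtered, frac[0], frac[1])
    n_target = math.ceil(len(wideband) * fs_out / fs_in)
    return out[:n_target]


def _as_fraction(x: float, max_den: int = 10000) -> tuple[int, int]:
    from fractions import Fraction

    f = Fraction(x).limit_denominator(max_den)
    return f.numerator, f.denominator


def make_bipolar_pairs(session: LFPSession) -> BipolarSet:
    """Form all unique within-structure bipolar derivations.

    Pairs are unordered combinations of the included wires of each
    (structure, hemisphere) group, ordered by ascending wire id, with the
    sign convention lower id minus higher id.  Groups with fewer than two
    included wires are flagged unusable and emit no pairs.
    """
    pairs: dict[tuple[str, str], list[tuple[int, int, np.ndarray]]] = {}
    unusable: set[tuple[str, str]] = set()
    for group in session.channel_map.structures():
        wires = session.included_wires_of(*group)
        if len(wires) < 2:
            unusable.add(group)
            continue
        out = []
        for a_idx in range(len(wires)):
            for b_idx in range(a_idx + 1, len(wires)):
                wi, wj = wires[a_idx], wires[b_idx]
                out.append((wi, wj, session.wire(wi) - session.wire(wj)))
        pairs[group] = out
    return BipolarSet(pairs=pairs, fs_hz=session.fs_hz, unusable=unusable)


@dataclass(frozen=True)
class ExclusionRules:
    """Automated surrogate for visual channel rejection.

    flat_std_uv: wires with series std below this are flat-line artifacts.
    outlier_rms_factor: wires with broadband RMS above factor x the median RMS
    of the same (structure, hemisphere) group are rejected as noise outliers.
    """

    flat_std_uv: float = 0.1
    outlier_rms_factor: float = 5.0


def exclude_noisy_channels(
    session: LFPSession, rules: ExclusionRules | None = None
) -> dict[int, str]:
    """Extend ``session.excluded_wires`` in place; returns {wire: reason}."""
    rules = rules or ExclusionRules()
    reasons: dict[int, str] = {}
    for group in session.channel_map.structures():
        wires = [w for w in session.channel_map.wires_of(*group) if w not in session.excluded_wires]
        if not wires:
            continue
        stds = {w: float(np.std(session.wire(w))) for w in wires}
        for w, s in stds.items():
            if s < rules.flat_std_uv:
                reasons[w] = "flat-line"
        survivors = [w for w in wires if w not in reasons]
        if survivors:
            rms = {w: float(np.sqrt(np.mean(session.wire(w) ** 2))) for w in survivors}
            med = float(np.median(list(rms.values())))
            for w, r in rms.items():
                if med > 0 and r > rules.outlier_rms_factor * med:
                    reasons[w] = "rms-outlier"
    session.excluded_wires.update(reasons)
    for group in session.channel_map.structures():
        if not session.included_wires_of(*group):
            warnings.warn(f"all wires of {group} excluded; structure unusable", RuntimeWarning)
    return reasons
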