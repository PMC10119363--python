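"""Time-resolved spectra and fractal/oscillation separation.

The spectrogram is a Welch short-time PSD series: 8-s Hann windows with 50%
overlap, i.e. one detection opportunity every 4 s at 0.125 Hz resolution
over 0-250 Hz.  Irregular-resampling auto-spectral analysis (IRASA)
estimates the arrhythmic (fractal, power-law) part of each windowed PSD by
resampling the segment by reciprocal factor pairs (h, 1/h): resampling
shifts rhythmic peaks along the frequency axis but leaves a power law
invariant under the geometric mean of each pair, so the median across
factors isolates the fractal component.  Power is then expressed in
dB_fractal units:

    S_dB(fractal)(f) = 10 * log10( S(f) / S_fractal(f) )

which is ~0 for purely arrhythmic activity and emphasises genuine
narrowband oscillations regardless of the background slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

#: Wen & Liu's published default resampling factors.
DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.95, 0.05), 2))

#: Line-noise excision bands: 50 +/- 2 Hz and harmonics +/- 1 Hz.
LINE_NOISE_BANDS_HZ = ((48.0, 52.0), (99.0, 101.0), (149.0, 151.0), (199.0, 201.0))


@dataclass
class SpectrogramGrid:
    """Time x frequency grid of spectral values with an excision mask.

    ``values`` has shape (n_times, n_freqs); ``unit`` is 'V^2/Hz' for PSDs or
    'dB_fractal' for normalized power.  ``mask`` flags excised bins (True =
    excluded from fitting and averaging), it never zeroes data.
    """

    times_s: np.ndarray
    freqs_hz: np.ndarray
    values: np.ndarray
    unit: str = "V^2/Hz"
    mask: np.ndarray | None = None
    window_s: float = 8.0
    overlap: float = 0.5

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.zeros_like(self.values, dtype=bool)

    @property
    def hop_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def column(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(freqs, values, mask) of time column i."""
        return self.freqs_hz, self.values[i], self.mask[i]


@dataclass
class FractalDecomposition:
    """Mixed PSD, its fractal estimate, and the dB_fractal ratio for one window."""

    freqs_hz: np.ndarray
    s: np.ndarray
    s_fractal: np.ndarray
    geomeans: np.ndarray | None = None  # per-h geometric-mean PSDs (diagnostics)

    @property
    def s_db_fractal(self) -> np.ndarray:
        return 10.0 * np.log10(self.s / self.s_fractal)


@dataclass
class StructureSpectrogram:
    """Structure-level dB_fractal spectrogram: mean over bipolar pairs."""

    structure: str
    hemisphere: str
    grid: SpectrogramGrid
    n_pairs: np.ndarray = field(default=None)  # contributing pairs per bin


def _window_starts(n_samples: int, nwin: int, hop: int) -> list[int]:
    return list(range(0, n_samples - nwin + 1, hop))


def welch_spectrogram(
    series: np.ndarray,
    fs: float,
    window_s: float = 8.0,
    overlap: float = 0.5,
    fmax_hz: float = 250.0,
    subwindows: int = 1,
) -> SpectrogramGrid:
    """Welch short-time PSD series: one column per hop of window_s*(1-overlap).

    Each column is by default a single Hann-tapered periodogram of its 8-s
    window (frequency resolution 1/window_s).  ``subwindows`` > 1 averages
    that many 50%-overlapped Hann sub-segments within each window (variance
    reduction at the cost of resolution).
    """
    series = np.asarray(series, dtype=float)
    nwin = int(round(window_s * fs))
    if len(series) < nwin:
        raise ValueError("series shorter than one analysis window")
    hop = int(round(nwin * (1.0 - overlap)))
    starts = _window_starts(len(series), nwin, hop)
    if subwindows <= 1:
        nper = nwin
    else:
        nper = int(nwin // (subwindows / 2 + 0.5))
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    keep = freqs <= fmax_hz
    cols = np.empty((len(starts), keep.sum()))
    for i, s0 in enumerate(starts):
        seg = series[s0 : s0 + nwin]
        f, p = signal.welch(
            seg, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2 if subwindows > 1 else 0,
            detrend="constant", scaling="density",
        )
        cols[i] = p[keep]
    times = (np.array(starts) + nwin / 2) / fs
    return SpectrogramGrid(
        times_s=times, freqs_hz=freqs[keep], values=cols,
        unit="V^2/Hz", window_s=window_s, overlap=overlap,
    )


def _h_fraction(h: float) -> tuple[int, int]:
    f = Fraction(h).limit_denominator(50)
    return f.numerator, f.denominator


def irasa_fractal(
    segment: np.ndarray,
    fs: float,
    hset=DEFAULT_HSET,
    fmax_hz: float = 250.0,
    fractal_subwindows: int = 8,
) -> FractalDecomposition:
    """Fractal/oscillation separation of one analysis window via IRASA.

    For each resampling factor h the segment is resampled by h and by 1/h
    (polyphase, anti-aliased), the Hann periodogram of each is evaluated on
    the original frequency grid, and the geometric mean of the (h, 1/h) pair
    is formed; the median across hset is the fractal PSD estimate.

    The fractal estimate is only valid up to Nyquist/max(h); frequencies
    above that are rejected if requested via fmax_hz.

    The resampled PSDs are estimated with ``fractal_subwindows`` overlapped
    Hann sub-segments (Welch) rather than one full-length taper: the fractal
    component is spectrally smooth, and averaging suppresses the downward
    bias that the geometric-mean and median steps would otherwise inherit
    from high-variance single-taper periodograms.  The mixed spectrum S
    keeps the full-length taper (full frequency resolution).
    """
    segment = np.asarray(segment, dtype=float)
    n = len(segment)
    hmax = max(hset)
    if fmax_hz > fs / 2 / hmax:
        raise ValueError(
            f"fmax_hz {fmax_hz} exceeds the valid IRASA range {fs / 2 / hmax:.1f} Hz "
            f"(Nyquist / max h); restrict the frequency band"
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = freqs <= fmax_hz
    freqs_out = freqs[keep]

    _, s_mixed = signal.periodogram(segment, fs=fs, window="hann", detrend="constant")
    s_mixed = s_mixed[keep]

    geomeans = np.empty((len(hset), keep.sum()))
    for k, h in enumerate(hset):
        p, q = _h_fraction(float(h))
        up = signal.resample_poly(segment, p, q)
        down = signal.resample_poly(segment, q, p)
        psd_up = _welch_on(up, fs, freqs_out, fractal_subwindows)
        psd_down = _welch_on(down, fs, freqs_out, fractal_subwindows)
        geomeans[k] = np.sqrt(psd_up * psd_down)
    s_fractal = np.median(geomeans, axis=0)
    return FractalDecomposition(
        freqs_hz=freqs_out, s=s_mixed, s_fractal=s_fractal, geomeans=geomeans
    )


def _welch_on(x: np.ndarray, fs: float, target_freqs: np.ndarray, subwindows: int) -> np.ndarray:
    """Welch PSD of x (nominal rate fs) interpolated onto target_freqs."""
    if subwindows <= 1:
        f, p = signal.periodogram(x, fs=fs, window="hann", detrend="constant")
    else:
        nper = max(int(len(x) // subwindows), 8)
        f, p = signal.welch(
            x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, detrend="constant"
        )
    return np.interp(target_freqs, f, p)


def normalized_spectrogram(
    series: np.ndarray,
    fs: float,
    window_s: float = 8.0,
    overlap: float = 0.5,
    hset=DEFAULT_HSET,
    fmax_hz: float = 250.0,
) -> SpectrogramGrid:
    """dB_fractal spectrogram of one bipolar series (IRASA per 8-s window)."""
    series = np.asarray(series, dtype=float)
    nwin = int(round(window_s * fs))
    if len(series) < nwin:
        raise ValueError("series shorter than one analysis window")
    hop = int(round(nwin * (1.0 - overlap)))
    starts = _window_starts(len(series), nwin, hop)
    cols = None
    freqs = None
    for i, s0 in enumerate(starts):
        dec = irasa_fractal(series[s0 : s0 + nwin], fs, hset=hset, fmax_hz=fmax_hz)
        if cols is None:
            freqs = dec.freqs_hz
            cols = np.empty((len(starts), len(freqs)))
        cols[i] = dec.s_db_fractal
    times = (np.array(starts) + nwin / 2) / fs
    return SpectrogramGrid(
        times_s=times, freqs_hz=freqs, values=cols,
        unit="dB_fractal", window_s=window_s, overlap=overlap,
    )


def excise_line_noise(
    grid: SpectrogramGrid, bands=LINE_NOISE_BANDS_HZ
) -> SpectrogramGrid:
    """Mask power-line bins (50 +/- 2 Hz and harmonics +/- 1 Hz) in all columns.

    Masked bins are flagged, not zeroed, and are excluded from peak fitting
    and structure averaging downstream.
    """
    mask = grid.mask.copy()
    for lo, hi in bands:
        in_band = (grid.freqs_hz >= lo) & (grid.freqs_hz <= hi)
        mask[:, in_band] = True
    return replace(grid, values=grid.values.copy(), mask=mask)


def average_structure(
    grids: list[SpectrogramGrid], structure: str = "", hemisphere: str = ""
) -> StructureSpectrogram:
    """Average dB_fractal grids of a structure's bipolar pairs bin-wise.

    Masked bins are excluded from the mean; a bin masked in every pair stays
    masked.  All grids must share time and frequency axes.
    """
    if not grids:
        raise ValueError("no contributing pair spectrograms; structure absent")
    f0, t0 = grids[0].freqs_hz, grids[0].times_s
    for g in grids[1:]:
        if not (np.array_equal(g.freqs_hz, f0) and np.array_equal(g.times_s, t0)):
            raise ValueError("pair grids must share time/frequency axes")
    stack = np.ma.stack([g.masked() for g in grids])
    mean = stack.mean(axis=0)
    n_pairs = (~stack.mask).sum(axis=0)
    out = SpectrogramGrid(
        times_s=t0, freqs_hz=f0,
        values=np.asarray(mean.filled(np.nan)),
        unit=grids[0].unit,
        mask=np.asarray(mean.mask) if mean.mask is not np.ma.nomask else None,
        window_s=grids[0].window_s, overlap=grids[0].overlap,
    )
    return StructureSpectrogram(structure=structure, hemisphere=hemisphere, grid=out, n_pairs=n_pairs)


def structure_db_spectrograms(
    bipolar_set,
    window_s: float = 8.0,
    overlap: float = 0.5,
    hset=DEFAULT_HSET,
    fmax_hz: float = 250.0,
    excise: bool = True,
) -> dict[tuple[str, str], StructureSpectrogram]:
    """Full spectral stage for a BipolarSet: per-pair dB_fractal spectrograms,
    line-noise excision, then structure averaging."""
    out = {}
    for group, pair_list in bipolar_set.pairs.items():
        grids = []
        for _, _, series in pair_list:
            g = normalized_spectrogram(
                series, bipolar_set.fs_hz, window_s=window_s, overlap=overlap,
                hset=hset, fmax_hz=fmax_hz,
            )
            if excise:
                g = excise_line_noise(g)
            grids.append(g)
        out[group] = average_structure(grids, structure=group[0], hemisphere=group[1])
    return out


def aggregate_db(decomps: list[FractalDecomposition]) -> FractalDecomposition:
    """Pool windows/realizations by averaging S and S_fractal in the linear
    power domain before the dB ratio (the unbiased way to combine windows)."""
    if not decomps:
        raise ValueError("nothing to aggregate")
    f0 = decomps[0].freqs_hz
    s = np.mean([d.s for d in decomps], axis=0)
    sf = np.mean([d.s_fractal for d in decomps], axis=0)
    return FractalDecomposition(freqs_hz=f0, s=s, s_fractal=sf)
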