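# Methods

## Signal model and preprocessing

The pipeline treats an LFP recording as a set of wires grouped into bundles
per anatomical structure and hemisphere.  Wideband input is low-pass
filtered (8th-order Butterworth at 500 Hz) and downsampled to 2000 Hz.
Filtering is applied forward-backward (zero phase): downstream phase
analysis must not inherit filter phase distortion, so the effective
magnitude order doubles relative to a literal causal 8th-order filter.
This is a deliberate deviation worth knowing about when comparing against
causal implementations.

Local activity is emphasised by bipolar re-referencing: the difference
series of every unique unordered pair of included wires within a structure
(k wires give k(k-1)/2 pairs; sign convention lower wire id minus higher).
Any signal shared by the wires of a bundle — volume conduction, reference
and movement artifacts, line pickup — cancels exactly in these differences.

Channel exclusion replaces the visual inspection used with real recordings
by two automated rules: flat-line (series std below 0.1 uV) and broadband
RMS above 5x the median RMS of the same structure.  Both thresholds are
configurable; structures left with fewer than two wires are flagged
unusable.

## Fractal/oscillation separation

Each bipolar series becomes a Welch short-time PSD series: 8-s Hann
windows, 50% overlap, one column per 4 s, 0.125 Hz resolution over
0-250 Hz.  Each column is a single full-window Hann periodogram, matching
the windowing of the detection grid literally; optional sub-averaging
within the window is available but trades away frequency resolution.

IRASA separates the arrhythmic component per window: the segment is
resampled by factor pairs (h, 1/h) for h in {1.1, 1.15, ..., 1.9}
(the published default factor set; polyphase, anti-aliased).  Resampling
shifts narrowband peaks along the frequency axis while a power law is
invariant under the geometric mean of each pair, so the median across
factors estimates the fractal PSD.  Two numerical choices matter:

- The resampled PSDs are estimated with 8 overlapped Hann sub-segments
  (Welch) rather than one full-length taper.  With single-taper estimates
  the geometric-mean and median steps inherit a Jensen-type downward bias
  from chi-square periodogram noise, which we measured at about -1.5 dB;
  sub-averaging removes it (residual < 0.1 dB).  The fractal component is
  spectrally smooth, so the coarser resolution of the fractal estimate
  costs nothing.
- The valid range of the fractal estimate ends at Nyquist/max(h); requests
  beyond it raise an error rather than silently extrapolating.

Normalized power is S_dB(fractal)(f) = 10 log10(S(f)/S_fractal(f)), with
S the full-resolution mixed periodogram.  Power-line bins (50 +/- 2 Hz,
100/150/200 +/- 1 Hz) are masked, never zeroed, and masked bins are
excluded from peak fitting and from the structure average (the bin-wise
mean of the pair spectrograms).  When pooling windows or realizations
into a single spectrum, S and S_fractal are averaged in the linear power
domain before the dB ratio; averaging dB values directly would reintroduce
the log-domain bias.

## Oscillation detection

The single-peak model y(f) = A exp(-((f-B)/C)^2) + Df + E is fitted by
bounded least squares to the band's spectral segment ([1,15] Hz for theta,
[8,48] for beta, [40,120] for NBG), with B initialized on a 5-point grid
across the band range and the best sum of squares kept (the model is
multi-modal in B).  A detection requires A >= 1.5 dB_fractal, B inside the
band range (theta 5-10, beta 12-35, NBG 70-110 Hz), C in [0.5, 15] Hz
([0.3, 4] for theta), |D| <= 0.2 dB/Hz, and R^2 >= 0.3.

The R^2 limit deserves its own note.  Single-taper dB spectra carry
chi-square noise of ~5.6 dB per bin per pair; averaged over the ~6 pairs of
a 4-wire bundle this leaves ~3 dB, so even a 10 dB genuine peak tops out
near R^2 ~ 0.55 over a 640-bin fit window.  On pure-fractal input the
fitted R^2 stays below ~0.1 (99th percentile ~0.08).  The 0.3 default
separates the two regimes with wide margins and holds the false-positive
rate far below the 5% eligibility threshold; it was calibrated on the
synthetic generator because the original limit table is not public.
Labs with more wires per bundle (lower spectral noise) can raise it.

Beta-band fitting is implemented but excluded from default reports, as
beta shows little association with dyskinesia.  Peak-dyskinesia analysis
windows are encoded as treatment presets: 20-60 min post injection for the
D1 agonist (SKF82958), 40-80 min for L-DOPA, the D2 agonist (sumanirole)
and vehicle.

## Phase synchrony

Phases are computed on monopolar wires by default (a bipolar mode exists):
zero-phase 4th-order Butterworth bandpass at +/- 5 Hz around the median
fitted peak frequency across the supplied detection series (a single
common passband keeps delta-phi comparable across pairs), Hilbert
transform, 0.5 s edge trim.  For each cross-structure wire pair the
circular mean of phi_i - phi_j and the mean resultant length r are
computed; structure connectivity is the mean r over wire pairs, and the
structure phase difference averages only pairs with r > 0.5.  Samples are
restricted to 4-s bins where both structures have positive detections —
the phase of an absent oscillation is noise, and pooling burst-off periods
collapses r even for perfectly locked sources.  Pairs with under 1 s of
jointly detected signal are dropped.

The one-sample test for the mean angle uses the chi-square
confidence-interval construction for circular means; the null mean is
rejected when it falls outside the (1-alpha) interval, with Bonferroni
alpha/n across structure pairs.  Low concentration makes the interval
undefined and the test is flagged inconclusive rather than forced.
Delays are delta-phi/360/f, reported in ms; with structure pairs listed
alphabetically, a negative delta-phi means the first-listed structure lags.

## Behaviour

Pose tables carry 7 body parts (nose, ears, head top, body centre, tail
base, tail tip) with x, y, likelihood per frame.  Frames with any
likelihood <= 0.9 are excluded.  Coordinates are smoothed with a centered
5-frame (0.2 s) NaN-aware moving average before deriving the centroid
(mean of all 7 parts), front (mean of nose, ears, head top) and heading
(tail base to front): raw keypoint jitter dithers the heading across
sector boundaries and fires spurious reversal resets in the turn counter
(measured: at 0.15 cm jitter only ~half of sessions recovered the true
turn count unsmoothed; all did with smoothing).

Full turns use fixed 45-degree sectors: 8 consecutive same-sense sector
transitions complete a turn (sectors skipped by fast rotation count as
traversed); an opposite transition resets the count, re-seeding from the
last angle; likelihood gaps longer than 1 s also reset, shorter gaps are
bridged.  A turn is therefore quantized at sector resolution — exactly
360 degrees in boundary space.  Counter-clockwise maps to contralateral by
default (lesion side is configurable metadata).  An independent
cumulative-rotation oracle (maximal same-sense runs of boundary crossings,
floor(run/8) turns each) is held in the test suite and must agree exactly.

Occupancy divides the arena into 1x1 cm squares anchored at the arena
centre; the denominator counts squares whose centre lies inside the 55-cm
circle (2348 squares; the circle, not the bounding box, since the animal
cannot visit corners).  Speed is centroid displacement across a sliding
1-s window.  AIM sheets are scored as composite = severity x amplitude per
subtype (axial, limb, orolingual; each 0-4), global per period (0-48),
session total, and peak-window totals, on the standard monitoring grid
(1 min every 5 min to 20 min, then every 10 min).

## Synthetic generator: what it does and does not emulate

Each wire is an independent 1/f^chi fractal background (spectrally shaped
white noise, default chi = 1, 50 uV RMS) plus shared band-limited
oscillatory sources, a per-bundle common-mode artifact, 50 Hz line noise,
and white sensor noise.  Oscillations are sinusoids with slow
Ornstein-Uhlenbeck frequency jitter (correlation time 0.3 s, stationary
std = width), giving an approximately Gaussian ensemble spectral peak;
bursts are gated by an envelope (drug-response time courses are modelled
as piecewise trapezoids).  Each wire projects the shared source with a
fixed positive gain from a deterministic cycle — wires at different depths
see a local source at different amplitudes — which keeps the oscillation
alive in bipolar differences without randomizing the effective peak height
between sessions, and keeps monopolar phases aligned for the synchrony
analysis.  Default NBG amplitude (80 uV at unit gain) yields
structure-averaged peaks near 11 dB_fractal, in the range of strong
dyskinesia-locked gamma.  A master seed spawns per-component substreams;
identical spec + seed reproduces sessions bit-for-bit.

Trajectories integrate a signed angular-velocity function into a heading
(positive = counter-clockwise = contralateral); while turning, the body
centre orbits the arena centre at the path radius, tangent to its path.
The rigid 7-point template is oriented along the heading, jittered
(default 0.15 cm), and likelihood dropouts are injected.  Ground truth
(per-band presence per 4-s bin, true peak parameters, pairwise lags, turn
counts, AIM schedules) is aligned to the analysis grid.

Not emulated: spikes/units, electrode drift, anaesthesia transients,
movement artifacts beyond the stationary common mode, video frames, and
cross-frequency or amplitude-amplitude dependencies between bands.  A
green synthetic test therefore establishes that the implementation
recovers known generating parameters under the stated noise model — not
that the biology behaves like the generator.

## Numerical conventions and degenerate inputs

- Angles wrap to [-180, 180); circular means use the resultant-vector
  formulation throughout.
- Masked spectrogram bins propagate as masked; a bin masked in every pair
  stays masked in the structure average.
- Peak fits with fewer than 10 usable bins, empty analysis windows,
  constant inputs to the rank correlation, undefined median frequencies
  (no detections) and upsampling requests all raise errors rather than
  returning silent defaults.
- Non-integer decimation factors fall back to polyphase resampling with a
  warning.
- Ground-truth presence of a bin is envelope mean >= 0.5 over its 8-s
  window; the truth turn counter guards sector binning with a 1e-7 degree
  epsilon against cumulative-sum rounding at exact boundaries.

## Known limitations

- IRASA is applied per 8-s window so the detection grid matches the
  spectrogram grid; whether the original analysis ran IRASA on whole
  recordings is unknown, and window-level estimates are noisier.
- Detection operates on the structure-averaged spectrogram (not per pair
  with averaged outcomes); with few wires the chi-square noise floor
  limits attainable R^2, which is why the R^2 limit is modest.
- The 8-sector rule quantizes rotation at 45 degrees; turns are detected
  only at boundary crossings, and headings hovering exactly on a boundary
  belong to the upper sector.
- Monopolar phase extraction assumes the shared source projects with
  consistent sign across wires; sign-flipping dipole geometries would
  offset delta-phi by 180 degrees for the affected pairs.
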