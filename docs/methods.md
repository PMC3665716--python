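# Methods

This note documents the models, parameter choices and numerical details
behind `nbhfsonar`, and what the synthetic scenes do and do not emulate.

## Click model

NBHF clicks are synthesized as Gaussian-envelope cosine pips

    s(t) = exp(−t² / 2σ²) · cos(2π f_c t),   σ = d₁₀ / (2·√(ln 10)),

so the −10 dB envelope duration is exactly `d₁₀` and the amplitude
spectrum is a Gaussian centred on `f_c`.  This makes duration, centroid
frequency and rms bandwidth analytically checkable, which is the point
of the generator: the pip is the cleanest waveform consistent with
published NBHF measurements (unimodal envelope, essentially no energy
below 100 kHz), not a physiological model.  One consequence worth
noting: an ideal pip of 104 µs has an rms bandwidth of ~3.3 kHz
(Q_rms ≈ 42), whereas field NBHF clicks of that duration show ~8 kHz
(Q_rms ≈ 17) — real clicks are far from time-bandwidth-optimal, and
measured bandwidth in noisy synthetic scenes lands in between.  All
bandwidth-sensitive conclusions in this package are therefore either
property checks (orderings, monotonicities) or are driven by the
centroid frequency, which the pip reproduces exactly.

## Directionality

Off-axis reception is modelled by the far-field circular-piston transfer
function applied per frequency bin,

    B(f, θ) = 2·J1(x)/x,   x = (2πf/c)·a·sin θ,

with equivalent aperture radius `a` (diameters: 10 cm for Dall's and
Danish harbour porpoises, 12 cm for BC harbour porpoises).  No
near-field corrections are applied: sources sit at ≥5 m, far beyond the
Fresnel range a²f/c ≈ 0.2 m.  Note that `B` changes sign beyond the
first Bessel null — off-axis clicks can arrive polarity-inverted, which
is why TDOA estimation works on correlation envelopes (below).

## Propagation and environment

One-way propagation applies a delay r/c, spherical spreading 1/r and a
per-bin absorption filter `10^(−α(f)·r/20)`.  Sound speed uses the
Mackenzie (1981) nine-term formula (freshwater 20 °C check: 1482 m/s).
Absorption defaults to a Fisher & Simmons (1977)-style formulation
(boric-acid and MgSO₄ relaxations plus the viscous term, pressure
factors ≈ 1 near the surface, chemical terms scaled by S/35), with
Ainslie & McColm (1998) available as an independent cross-check; the two
agree within ~20 % over 65–200 kHz at oceanic salinity, diverging most
near the MgSO₄ relaxation knee.  Source-level back-calculation uses the
*scalar* α at the click's measured centroid frequency; for NBHF
bandwidths the mismatch against the simulator's per-bin filtering is
below 0.3 dB out to 65 m (asserted in tests).

Environments: British Columbia 9.2 °C / 33.9 ‰, Denmark 15 °C / 20 ‰;
the detection-range model uses its own 14 °C / 33 ‰ profile.

## Scene rendering

Scenes are rendered at 500 kHz per channel onto the default vertical
six-element array (hydrophones at 2.0, 3.5, 4.25, 5.0, 5.75 and 6.5 m
depth: 0.75 m spacing with a 1.5 m gap at the top).  Each click is
placed with its exact fractional travel-time delay via a
frequency-domain phase ramp, so TDOAs carry sub-sample information.
White Gaussian noise at a configurable spectral level (default
55 dB re 1 µPa²/Hz, a moderate coastal value; the field studies did not
report theirs) is added per channel, and the scene is peak-normalized to
−6 dBFS and quantized to 16 bit to emulate the ADC without clipping.
A "scan" is produced by sweeping the source's acoustic axis linearly
across (and slightly beyond) the array over a click train, so exactly
one click points at a hydrophone while edge clicks arrive weaker —
off-axis-only click trains, animal movement within a train and
surface/bottom multipath are *not* modelled (a single delayed surface
echo can be injected to exercise the direct-path criterion).

## Detection, TDOAs, localization

Detection is a per-channel Hilbert-envelope peak detector with a
threshold of 20 dB above a robust (Rayleigh-median) noise-floor
estimate; detections coincident within the maximum inter-hydrophone
travel time are merged into one click event, keeping the *earliest*
envelope peak per channel so that a stronger trailing reflection stays
in the echo-inspection window rather than usurping the event.  Events
separated by more than 300 ms open a new scan (the largest analyzed ICI
band ends at 200 ms); scans with median ICI below 13 ms are excluded as
buzzes (repetition rates of some hundred clicks per second).  The
trailing window for the direct-path criterion is 20 ms with a 0.5 ms
guard.  None of these detector constants were published for the field
analysis; they are package defaults, all configurable.

TDOAs are taken from the envelope of the cross-correlation (magnitude of
its analytic signal) with parabolic sub-sample interpolation — the
envelope peak is the group delay and is immune to the polarity inversion
and carrier-phase distortion that off-axis piston filtering introduces,
which would otherwise bias raw-correlation peaks by half a carrier cycle
(3.65 µs at 137 kHz).

Localization exploits the vertical-line geometry: the source is solved
in (horizontal range, depth) — azimuth is unresolvable — by
least-squares on TDOA residuals from a 5×5 multi-start grid
(Gauss–Newton steps, tolerances 1e−12, iteration cap 400).  The
localization quality measure is the rms spread of the implied
transmission loss `20·log10 r + α·r` over leave-one-hydrophone-out
sub-solutions, about the full-array solution; clicks are accepted for
source-level work only within 65 m and with this TL error below 3 dB.
An all-zero TDOA set (source on the array's symmetry plane) is flagged
degenerate rather than solved.

## Click parameters

The envelope is the magnitude of the analytic signal; duration is the
span between the first and last crossings of peak −10 dB (linear
sub-sample interpolation), and rms/energy levels integrate over that
window only, which makes `SL_EFD = SL_RMS + 10·log10(d₁₀)` an identity.
Spectra use a 512-point rectangular window centred on the envelope peak,
zero-padded ×10.  The **centroid frequency is the median-energy
frequency** — the frequency dividing the spectrum into two halves of
equal energy — rather than the conventional energy-weighted mean; the
mean-based variant is available via `centroid="mean"` (the two coincide
for the symmetric pip spectrum).  −3/−10 dB bandwidths use the
contiguous region around the global spectral peak (a deterministic
tie-break when ripple creates multiple crossings).  Calibration is
applied before windowing.

## Beam pattern and directivity

For each accepted click within 20 m, the five off-axis received levels
are corrected by each channel's own transmission loss and expressed
relative to the on-axis channel; the acoustic axis is assumed to point
exactly at the on-axis hydrophone.  Samples below −30 dB re on-axis are
dropped (they are noise-dominated in field data, and −30 dB is the
customary display floor of composite beam plots).  The piston fit
minimizes dB residuals over the aperture radius *and* a free gain (so
only beam shape matters — DI is invariant to uniform offsets), with
samples beyond the first Bessel null down-weighted ×0.5.  The
directivity index integrates the fitted beam assuming rotational
symmetry, `DI = 10·log10(2/∫₀^π b² sinθ dθ)`, by trapezoid quadrature on
a 20001-point grid (agrees with adaptive quadrature to <1e−5 dB).  For a
10 cm aperture at 137 kHz this gives DI ≈ 26.2 dB.  Published
field-study tables pair a 10 cm aperture with DI = 25 dB, a combination
no standard piston formula reproduces (the baffled-piston
`10·log10((ka)²)` gives 29.3 dB); both quantities are computed
independently here and the ~1 dB discrepancy is left visible rather than
calibrated away.

## Species discrimination

Population parameter draws are independent truncated normals with the
study means/SDs and observed ranges (Dall's 137±3 kHz; BC harbour
141±2 kHz; Danish harbour 136±3 kHz).  For BC harbour porpoise the
observed range's lower bound (138 kHz) sits only 1.5 SD below the mean,
so truncation raises the realized mean by ~0.3 kHz; `truncate=False`
gives exact normal draws (used for the ROC analysis, where the
distributions themselves are the specification).

The ROC criterion scans thresholds on a 0.1 kHz grid for maximum overall
proportion correct (ties resolved to the midpoint of the tied range) and
reports the threshold at grid and integer resolution; for the two BC
populations it lands at 139 kHz, matching the analytic equal-likelihood
crossing at 138.8 kHz.

Monte Carlo datasets mix one on-axis click with the five off-axis
variants recorded simultaneously on the other hydrophones: for each
drawn source at a uniform random range within the 5–65 m acceptance
band, aiming at a random middle hydrophone, the five piston-filtered
variants are re-measured with the standard click metrics.  Sets of N
clicks are drawn without replacement within a set (with replacement,
flagged, when the dataset is smaller than N) and classified by mean
centroid frequency against the fixed criterion; 100 sets per species ×
10 repeats give the mean and SEM per set size.

Audiogram filtering emulates porpoise reception: clicks are convolved
with a linear-phase FIR whose magnitude is the inverted, normalized
hearing-threshold curve (0 dB at best hearing), interpolated linearly in
dB over log-frequency.  The packaged curve is a **synthetic** U-shaped
stand-in (best sensitivity 100 kHz, +30 dB at 160 kHz, +40 dB at
16 kHz); measured audiograms load from two-column CSV.  Because the
synthetic pip spectra are symmetric, audiogram filtering shifts *both*
species' centroids down by a similar ~2 kHz and does not improve
separation at a fixed 139 kHz criterion — unlike real clicks, whose
species difference lives in the low-frequency cut-off.  This is a known
limitation of the click model: the audiogram path demonstrates the
mechanics (and re-deriving the ROC criterion on filtered data restores
performance), but the quantitative filtered-set accuracies say nothing
about real data.

## Detection-range model

The active sonar equation with energy detection gives, after
normalizing to the 130 kHz / 15 kHz NBHF reference at the same range and
source energy flux density,

    ΔENR(r) = −2r·[α(f_c) − α(130)] − [N₀(f_c) − N₀(130)] − 10·log10(BW/15),

the spreading, source, target-strength, receive-DI and detection-
threshold terms cancelling by construction.  The ambient spectrum N₀ is
a committed parametric fixture (`data/noise_deep_water_ss3.csv`):
Knudsen-style sea-state-3 wind noise anchored at 60 dB re 1 µPa²/Hz at
1 kHz falling 17 dB/decade, plus thermal noise −15 + 20·log10(f/kHz)
rising above ~100 kHz, which places the low-noise window minimum at
~102 kHz.  Any two-column CSV replaces it.  Under this fixture the
3×-bandwidth penalty is the exact constant 10·log10(3) = 4.77 dB; the
200 kHz scenario never beats the reference; and the 32.5/65 kHz
broadband scenarios cross over at ~148/125 m.  The published figure this
mirrors used an unreproduced textbook noise curve and reports crossovers
of "more than 200 m", so crossover locations here are qualitative
(existence and >100 m), not calibrated values.

## Problem sizes and determinism

Default analysis sizes are chosen to keep a full run on one CPU in the
tens of seconds: ROC draws 2×20 000 clicks, Monte Carlo datasets use 60
on-axis sources (360 clicks) per species with 100 sets × 10 repeats, and
synthetic scenes hold single scans of 7 clicks.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; renders,
pipeline tables and Monte Carlo results are bit-identical under a fixed
seed, and the pipeline manifest records output SHA-256 hashes to make
replay verifiable.

## Known limitations

* The Gaussian pip understates real NBHF bandwidth (see above).
* Noise is white per channel; no flow, vessel or snapping-shrimp
  structure, and no inter-channel noise correlation.
* No refraction, multipath (beyond the optional test echo), or animal
  movement within a click train.
* The line array leaves azimuth unresolved; localization is reported in
  the (range, depth) half-plane.
* Five-channel operation (broken hydrophone 3) is supported for
  selection criteria, but all defaults assume the six-channel array.
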