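# Methods

This note documents the models behind `smsperf`, the parameters that
matter, and what the simulations can and cannot say about real
free-breathing perfusion imaging.

## Phantom

The thorax is analytic geometry rasterised on demand: an elliptic body
cylinder with a 15 mm chest wall, lungs above and liver below a diaphragm
edge (baseline 55 mm on the foot-head axis), and a heart built from
ellipsoids — an LV blood pool (radii 22 × 32 mm) inside an epicardial shell
(32 × 42 mm) plus an RV pool.  Because every structure is an analytic
indicator function, slices can be sampled at *continuous* foot-head
positions and perfect prospective tracking reproduces the motion-free image
to machine precision, which anchors the tracking tests.

Two geometric choices carry the science:

* **LV long-axis tilt** (default 0.30 mm/mm in x, −0.20 in y): the
  cross-section centre at height z is `lv_center_xy + tilt·(z − lv_center_z)`.
  Through-plane displacement therefore shifts the in-plane centre of mass,
  exactly as for oblique short-axis slices in vivo.  Without the tilt,
  concentric axis-aligned ellipsoids would change mask *area* but not mask
  *position* under foot-head motion, and the avCOM metric would be blind to
  through-plane motion.  The tilt signs are chosen so that the
  through-plane COM shift and the in-plane heart translation (below) add
  rather than cancel.
* **Slice stack**: six 10 mm slices at 10 mm spacing centred on the heart,
  base → apex.  Apical cross-sections shrink fastest with displacement, so
  apical slices are the most motion-sensitive — the regional pattern the
  metrics report.

**Respiration.**  The diaphragm trace is
`d(t) = A·sin(2πt/T) + drift·t + Σ events`, defaults A = 7 mm, T = 4 s,
drift 0.05 mm/s.  Deep-breath events are compact smooth bumps
`extra·sin²(π(t−t₀)/τ)` (default one event: 15 mm extra over 8 s).  The
heart follows with `heart_scale` (default 0.42) in foot-head direction plus
an optional uncorrected in-plane translation (`inplane_scale`, default
0.15 × d(t), along y only).  The liver follows d(t) fully.  Setting
`heart_scale` equal to the tracking factor makes an ideally tracked
acquisition exactly motion-free for the heart; mismatch (as in vivo, where
the ratio is subject-dependent) leaves proportional residual motion.

**Contrast.**  The arterial input is the peak-normalised gamma-variate
`C(t) = A·((t−t₀)/(αβ))^α · exp(α−(t−t₀)/β)` (t₀ = 5 s, α = 2.5,
β = 1.5 s, A = 4 mmol/L); the myocardial curve reuses the family with
+4 s delay, +2 s dispersion and 25 % amplitude.  T1 follows fast-exchange
relaxivity `1/T1 = 1/T1₀ + r₁·C` (r₁ = 4.5 L·mmol⁻¹s⁻¹), and signal
weights are `PD·(1 − exp(−TS/T1))` with ideal saturation.  The saturation
delay TS is not part of the published protocol; the default is 100 ms and
configurable.

**Coils.**  Eight Gaussian-lobe receive channels on a ring around the
chest, alternating between two foot-head levels, with per-coil complex
phase ramps plus a 0.05 floor so sum-of-squares sensitivity never
vanishes.  The in-plane and inter-slice variation is what lets the
extended-FOV parallel-imaging problem separate R_ext = 7 aliases; this
works at the native 1.9 mm matrix (128 phase-encode lines per half-FOV) but
not on the 64-pixel coarse grid used by the fast unit tests, which
therefore exercise R_ext ∈ {2, 4}.

## Acquisition model

Each heartbeat (RR = 1 s) has three saturation-recovery blocks 180 ms
apart; block b excites slice pair (b, b+3) — maximal separation, standard
SMS practice.  CAIPIRINHA phase cycling gives band 1 `+π/2` per excitation
and band 2 `−π/2`, so the inter-band phase difference alternates 0, π and
band 2 lands half an extended FOV away while both bands keep the
±π/2-per-pulse cycling that bSSFP needs.  The multiband-2 × N-fold problem
(N = 3.5) is encoded directly as R_ext = 2N = 7 on a doubled phase FOV and
undersampled time-interleaved: dynamic d acquires lines
`k ≡ d (mod R_ext)`.

The readout is an ideal single-shot snapshot: no bSSFP transients, banding,
off-resonance or eddy currents (hence no frequency-response correction is
needed), and no RF waveform synthesis — the navigator magnetisation is
simply assumed available in every block.  Band phases are indexed by
absolute phase-encode line rather than excitation order so the band-2 shift
is identical in every dynamic regardless of the TGRAPPA line offset (with
interleaved sampling a literal per-excitation increment would add a
dynamic-dependent sign on band 2 and break merged calibration).  k-space is
stored centred (DC at row n/2) with orthonormal FFTs; an even phase-encode
count is required (asserted) so the centred CAIPI phase ramp equals the
half-FOV roll exactly.

Complex Gaussian k-space noise (default σ = 5 × 10⁻⁴ per coil sample, in
orthonormal-FFT units) gives an LV image SNR around 40 after R_ext = 7
reconstruction — consistent with a high-SNR bSSFP readout.  Noise seeds
derive only from (run seed, dynamic, block), so paired arms see identical
realisations.

## Navigator and tracking

The navigator is a 1 mm-resolution, 80 mm foot-head profile through the
lung–liver boundary: a step (liver 1.0, lung 0.12) blurred by 3 mm, plus
seeded Gaussian noise (default σ = 0.02).  Displacement is the argmax of
the normalised cross-correlation against the reference profile (first shot
of the series), refined by a parabola through the peak and neighbours; the
refinement is skipped for an exact integer-lag match, where the asymmetric
neighbour scores would only bias the vertex.  Shots whose peak correlation
falls below 0.4 are flagged and the last accepted displacement is held, so
a noisy navigator never aborts the scan; a tracker that raises is likewise
logged and the previous offset reused.  The applied offset is
`tracking_factor × displacement` (0.42), applied to the immediately
following readout of the same block — the few-millisecond feedback latency
is neglected.

The tracking factor can be *recovered* from an untracked simulation: with
the LV tilt known, the mask COM-x trace divided by tilt_x regressed on the
diaphragm trace has slope −heart_scale.  The x component is used because
the uncorrected in-plane translation acts along y only.

## Reconstruction

TGRAPPA calibration merges the R_ext consecutive dynamics centred on the
target dynamic (clamped at the series ends) into fully sampled k-space;
each line comes from the unique dynamic that acquired it.  GRAPPA weights
(4 phase-encode source lines {b−R, b, b+R, b+2R} × 5 readout taps × all
coils per target, ridge λ = 10⁻⁴ of the mean normal-matrix diagonal) are
refit per window — this is what makes the reconstruction sensitive to
deep-breath outliers: a window straddling an outlier position yields
inconsistent calibration and ghosting in that dynamic.  One numerical
point found the hard way: the least-squares fit must use *every*
phase-encode base line; subsampling that lattice aliases the k-space
oscillations of off-centre structures into the normal equations and
visibly biases the weights (readout columns can be strided safely, default
stride 2).  Acquired lines are passed through bit-exactly; missing lines at
the extreme k-space edges (below the first acquired line of an offset
dynamic) remain zero — negligible energy.  Coil images are combined by
sum of squares and the doubled FOV split into the two bands.

Per-frame reconstruction quality is diagnosed as NRMSE against the matched
fully-sampled ground-truth frame of the *same* motion and enhancement
state, isolating undersampling/calibration artefacts from motion itself.
For the deep-breath diagnostic, "quiet" reference dynamics are those inside
the analysis window without an event: during the first-pass upslope the
calibration inconsistency is enhancement-driven (NRMSE up to ~0.5 at the
bolus arrival) and would swamp the motion effect being measured.

## Registration and temporal filter

Registration is per-slice 2D, every dynamic onto a reference frame, using
a multi-resolution (3 levels, 30 iterations/level) symmetric-forces demons
algorithm on percentile-normalised frames with 2 mm Gaussian field
smoothing (SimpleITK backend).  The commercial inline algorithm of the
scanner is closed; the contract checked here is behavioural — residual
in-plane motion decreases and SSD never increases (an identity-field guard
enforces the latter unconditionally).  The reference frame is the dynamic
of peak myocardial enhancement — the same dynamic that opens the metric
analysis window; registering to any other motion state would systematically
penalise the windowed metrics.  Deformation fields are retained and applied
to the ground-truth masks so post-registration residual motion is measured
on exactly the correction the images received.

The temporal filter is a per-voxel 1D Gaussian along dynamics, σ = 1.2
dynamics, truncated at 4σ, reflect-padded, unit DC gain
(`scipy.ndimage.gaussian_filter1d`).  σ is interpreted in units of
dynamics (frames), not seconds; the source protocol does not state the
unit.  On simulated enhancement curves the filtered peak stays within 5 %
in amplitude and 1 dynamic in time.

## Metrics

avDICE and avCOM are computed on the binary epicardial LV masks over the
analysis window (peak myocardial enhancement → end of series), against the
first window dynamic; a temporal-mean-COM variant of avCOM is available.
Ground-truth masks come from the phantom sampled at the *acquired*
(possibly tracked) slice positions, so through-plane motion deforms them
exactly as it deforms the anatomy.  Regions are base = slices 1–2,
mid = 3–4, apex = 5–6.

## Default experiment sizes

The default paired run uses a 128 × 128 matrix at 1.9 mm, 6 slices, 40
dynamics at RR = 1 s with one deep-breath event at 24–32 s; the packaged
`demo` config is 64 × 64 × 16 dynamics with compressed bolus timing.  The
full clinical matrix (FOV 360 × 326 mm², 80 dynamics) is available through
the protocol config.  On one CPU the default paired experiment completes in
about two minutes.

## What the simulations do and do not show

The twin reproduces the *mechanisms*: through-plane mask deformation and
COM displacement under free breathing, their suppression by prospective
tracking, residual in-plane motion removable by registration, and
calibration-staleness ghosting at deep breaths.  It does not model cardiac
contraction (acquisition is ECG-triggered to a fixed phase), bSSFP banding
or transients, saturation-pulse/navigator interference, pharmacokinetics
beyond a two-curve gamma-variate model, coil arrays at clinical channel
counts, or inter-subject anatomical variability — so absolute metric
values are not comparable to patient studies; only directions and orders of
magnitude are.  Low-correlation navigator rejection is exercised
synthetically; real navigator failure modes (mis-planning, poor SNR) are
outside the model.
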