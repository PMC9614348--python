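# Methods

This note documents the models and procedures implemented in `fusionscope`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices that matter.

## Single-vesicle TIRF fusion pipeline

**Signal model.** Fluorescently labeled proteoliposomes dock onto a supported
bilayer inside the evanescent field of a TIRF microscope. A docking event is
a step increase of the spot's central-pixel intensity to a plateau with no
decay. A fusion event is a transient spike — the labeled lipids dequench and
reorient as they enter the planar membrane, roughly doubling the intensity —
followed by exponential decay to background as the lipids diffuse away.

**Processing.** Movies (default 3000 frames at 20 ms) are smoothed with a
centered, edge-truncated temporal moving average (default window 3 frames;
centered so events are not shifted in time). The per-pixel maximum over the
stack is projected onto one image; every vesicle that ever visited a site
leaves its brightest state there. Particles are located on this projection by
a scale-normalised Laplacian-of-Gaussian response at the PSF scale with
local-maximum selection; the threshold is `threshold_sd` (default 5) times
the robust (MAD-based) SD of the response image, detections must be at least
`min_separation` pixels apart and ≥2 px from the border so the 5×5 analysis
area fits. Centers of mass are refined as intensity-weighted centroids in
the 5×5 neighbourhood and rounded to integer pixels. Per particle, the
central-pixel ("peak") and 5×5-mean intensity series are extracted.

**Classification.** Trace noise is estimated robustly from first differences
(MAD/√2), which is insensitive to steps and spikes. Docking is the first
frame where the peak series exceeds the pre-dock baseline (median of the
first 15 frames) by 5 noise SDs for at least 5 consecutive frames. The
fusion candidate is the maximum within 1 s after docking (ceil(1 s / Δt) =
50 frames at 20 ms); it is accepted when the excursion reaches 1.5× the
docked plateau step and the trace decays below baseline + 0.5× the plateau
step within 0.5 s. A spike later than the 1 s cutoff leaves the vesicle
non-fused; a trace without a docking step is rejected and excluded from the
denominator. All thresholds are configurable (`ClassifierParams`); the
values encode "spike with subsequent rapid decay" while tolerating noise at
spot SNR ≈ 10.

**Statistics.** Fusion probability is fused/(fused+non-fused) with a Wilson
95% interval. Conditions are compared by one-way ANOVA on per-bilayer
replicate probabilities with Dunnett-style contrasts against the control
(scipy's Dunnett implementation); the replicate unit is one supported
bilayer.

## Binding assay and dequenching correction

The field-mean intensity time course (one image per 30 s, a few pre-injection
baseline images) is fit by bounded nonlinear least squares to
I(t) = baseline + I_obs(1 − e^{−kt}), t from injection, with analytic
initial guesses (amplitude from last−first intensity, k from the half-rise
time). Because a fused liposome is brighter by β, the observed saturation
intensity mixes populations, I_obs = N((1−α)i_lip + αβ i_lip), and
normalized binding is N̂ = K·I_obs/(1+α(β−1)). The general denominator
1+α(β−1) is used rather than the β=2 shorthand 1/(1+α); the two coincide at
β = 2. α is taken from the fusion assay of the same condition; if it is
unmeasured the correction is skipped with a warning. K defaults to 1
(arbitrary units); K = 1/i_lip makes the correction an exact inverse of the
intensity model and is used in simulation tests.

## FLIC optics

**Forward model.** The dye sits at height h above a membrane supported on a
silicon chip with 16 SiO₂ terraces. Both the excitation and the emission
field form standing waves in front of the reflecting silicon, so the probed
intensity is F(d_ox, h) = |1 + r_ex e^{2ik_ex h}|² |1 + r_em e^{2ik_em h}|²,
k = 2πn_water/λ. The complex reflection r of the sub-stack below the dye
plane (membrane 4 nm / water cleft 4 nm / oxide d_ox / bulk Si) is computed
by the characteristic-matrix recursion at normal incidence with the
e^{i(kz−ωt)} sign convention (Im n ≥ 0 absorbing), which is the convention
consistent with the +2ikh round-trip phase. The tests cross-check this
against an independently coded recursive-Airy + field-superposition oracle
to 1e-10 relative.

**Scope of the optical model.** Normal incidence, scalar fields, no angular
or polarization integration over the objective aperture and no
photobleaching or quantum-yield modeling. The forward model sits behind one
function so a full angular model could replace it without touching the
inversion. Refractive indices are configurable with defaults n_Si = 4.086 +
0.028i, n_SiO₂ = 1.46, n_water = 1.33, n_membrane = 1.45, λ_ex = 546 nm,
λ_em = 590 nm (Alexa546 under a 610/60 band-pass). The 16 default terrace
thicknesses span 10–300 nm; the real chip's terrace heights are not public,
so only relative/recovery properties are asserted, never absolute intensity
values.

**Inversion.** For one 16-intensity set, the residual is minimized over
(h, scale, background): scale and background are profiled out by linear
least squares at each point of an h grid (0–40 nm, 0.05 nm step — well
inside one unambiguous interference period, appropriate since the labeled
SNARE residue sits within a few nm of the membrane), followed by bounded
scalar refinement around the best grid point. All-equal intensity sets are
rejected as uninformative. Distance changes Δd are reported per paired
repeat (mean condition height − mean control height) with the mean over
repeats and an ANOVA flag.

## Planar-bilayer (protein-free) fusion assay

Fusion of nystatin/ergosterol liposomes into a voltage-clamped bilayer
transiently inserts channels: an abrupt current rise that decays as
ergosterol dilutes. Detection: a centered running-median baseline (window
1 s) is subtracted; events open at upward crossings of 5.5 robust SDs
(MAD-based) of the residual. 5.5σ keeps the expected number of noise
crossings per 210 s trace at kHz sampling well below one (at 5σ it is ~0.06
per trace). A crossing must additionally climb by 0.8× the threshold within
0.1 s (rejecting slow drifts and noise riding on a decaying tail), and
crossings within a 0.2 s refractory interval are merged, so multi-channel
insertions from one liposome count once. Rates are events per minute over
the analysis window; post-alcohol rates are normalized to the pre-alcohol
rate of the same experiment (error on a zero baseline rate).

## Synthetic generators

All generators draw from a single seeded NumPy generator per call and are
bit-reproducible for a fixed seed.

* **TIRF movies** — Gaussian PSF (σ = 1 px) spots at integer positions with
  ≥6 px separation (rejection sampling), Poisson-distributed docking counts
  (default expectation 200 per 3000-frame movie, so every movie carries
  comfortably more than 150 events) with docking frames placed ≥0.5 s from
  the start and ≥1.5 s from the end, so each event has a baseline and a full
  observation window. A fraction (default 0.34, the control condition) fuse
  after a truncated-exponential delay: mean 0.24 s, floor 2 frames, ceiling
  1 s, putting ≈65% of fusion delays below 250 ms and all of them inside the
  1 s cutoff. Fusion multiplies the plateau by the dequenching gain 2 and
  decays with τ = 0.1 s. Noise is additive Gaussian (EMCCD-like; no full
  gain-register model), default spot SNR 10. Not emulated: vesicle diffusion
  before docking, photobleaching, drift, undocking.
* **Binding series** — first-order saturation sampled every 30 s with three
  pre-injection baseline images and additive Gaussian noise; ground truth is
  the noiseless I_obs and k.
* **FLIC sets** — scale·F(d_ox, h) + background with multiplicative Gaussian
  noise (default 5%), 100 sets per image by default. At these defaults the
  scatter of recovered heights over noisy sets is ≈0.7 nm — "order of 1 nm".
* **Current traces** — 210 s (3.5 min) at 1 kHz; Poisson event times (or a
  fixed list, for embedding the 17- and 30-event reference segments), each
  adding an instantaneous step with amplitude N(20, 3) pA decaying with
  τ = 0.3 s, on a Gaussian 2.5 pA noise floor. The spike-amplitude
  statistics of real nystatin fusion events are uncharacterized; these are
  free parameters chosen so typical events have SNR ≈ 8.

Passing the recovery suites on these generators shows the pipelines invert
their own signal models at realistic noise; it does not certify performance
on real movies with drift, bleaching, uneven illumination or correlated
EMCCD noise.

## Dose and CD utilities

Conversions use exact algebra with densities at 25 °C (ethanol
0.785 g/mL, MW 46.07; methanol 0.792 g/mL, MW 32.04), which reproduce the
standard equivalences (0.4% v/v ethanol = 68 mM = 0.31% w/v; 86 mM = 0.50%
v/v = 0.40% w/v) at their printed rounding; full precision is kept
internally and densities are overridable. CD aggregation sums the eight
deconvolution categories into Helix (Helix1+Helix2), Beta
(Anti1+Anti2+Anti3+Para) and Other/Turn (Turn+Others), with deltas against
the 0% alcohol control; the deconvolution itself is external and only its
8-category output is consumed.

## Problem sizes and determinism

The test suite and the acceptance script use 20 full-size TIRF movies
(3000×140×140), 500 noisy FLIC sets, 20 planar-bilayer traces plus the two
reference segments, 100 noisy binding fits, and 1000 ANOVA null simulations
— sizes at which every stochastic check is stable across seeds. All
stochastic tests run with fixed seeds; the acceptance script derives all
seeds from its `--seed` argument.

## Known limitations

* Particle detection stands in for an unpublished single-particle algorithm;
  it is parameter-light (LoG + robust threshold) rather than matched to the
  original.
* The docking/fusion time-point criteria are declared, configurable
  thresholds; the original analysis software's exact criteria are not
  public.
* The FLIC model is scalar and normal-incidence; absolute fitted heights at
  high numerical aperture would shift, while relative distance changes are
  far less sensitive.
* The classifier slightly deflates fusion probability (≈1% of events) by
  missing spikes that fall at the cutoff boundary or on very short plateaus;
  at study conditions the Wilson interval still covers the generator value.
* Loose vs tight docking cannot be distinguished from these signals.
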