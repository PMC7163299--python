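# Methods

This note documents the models implemented in `globule`, the choices made
where the underlying methods leave the design open, what the synthetic-data
generators do and do not emulate, and the package's numerical conventions.

## Half-bleach FRAP with a partially permeable boundary

**Model.** Effective free diffusion of the bleached-particle concentration
c(r, φ, t) inside a disk of radius R, with a radiation (Robin) boundary
condition ∂c/∂r + h·c = 0 at r = R. The barrier height h (1/μm) is reported
through the dimensionless permeability p = R·h; its inverse l = 1/h is the
effective thickness of the boundary (crossing it costs as much as diffusing a
distance l inside). Effective diffusion absorbs transient binding inside the
body, so the diffusion time τ_D = R²/D_eff is apparent. The treatment is
two-dimensional: chromocenters and nucleoli are imaged in a single confocal
section and the bleach is a half-plane, so the axial dimension adds little
beyond a rescaling of τ_D.

**Solution.** Working in units of R and τ_D, the eigenmodes are
J_n(α r)·{cos, sin}(nφ) with α the positive roots of
α·J′_n(α) + p·J_n(α) = 0. This root condition is fixed by two internal
consistency requirements: the Sturm–Liouville normalization
∫₀¹ J_n(αr)² r dr = (α² + p² − n²)·J_n(α)²/(2α²) and the closed-form n = 0
(rim-exchange) weight 2p²/(α²(α² + p²)) both hold only for it, and only with
it does the series agree with an independent finite-difference solver with
the same Robin boundary. Expansion coefficients for the half-disk initial
condition are obtained by numerical projection (200-node Gauss–Legendre
radial quadrature): the angular integrals select n = 0 and odd n, and the
closed-form n = 0 weight is reproduced to 1e−15 and kept as a cross-check
rather than as the implementation. For p = 0 the conserved uniform mode
contributes ½ to each half; each remaining mode decays as exp(−α² t/τ_D).

**Truncation.** Modes are included up to a cutoff α_max chosen adaptively so
that the bleached-half content at the earliest requested time changes by
< 1e−6 when the cutoff grows by 30%. The truncation time floor is
2e−3·τ_D: the additional modes demanded by earlier times are numerically
negligible except in the first instants after the idealized instantaneous
bleach, where the series carries bounded Gibbs ringing anyway (the t = 0
values are set by the initial condition). Mode tables are memoized per
(p, floor-quantized t_min).

**Validation.** `globule.validation.fd_halfbleach_curves` implements
Crank–Nicolson time stepping on a staggered polar finite-volume grid
(48 radial × 96 angular cells; the pole is handled by a zero-area inner face,
the rim by ghost-cell elimination of the Robin condition; time steps ramp
geometrically from 1e−4 to 5e−3). Series and solver agree to < 0.1% max
absolute deviation on p ∈ {0, 1, 5, 20} over t/τ_D ∈ [0.01, 5] — an order
tighter than the 1% the tests assert.

**Normalization chain.** Raw ROI means are background-corrected against the
nucleoplasm, FRAP = (⟨I⟩ − ⟨I_BG⟩)/(⟨I_Nucleus⟩ − ⟨I_BG⟩) (this also
compensates acquisition photobleaching), weighted by relative ROI size so
curves are proportional to particle numbers, double-normalized with the
*bleached* ROI's constants (pre-bleach mean → 1, bleach frame → 0, both
curves scaled identically to preserve their relative magnitude), and the
non-bleached curve is shifted additively to unity before the bleach.

**Fitting.** The normalized curves are fitted jointly as
F_B = 1 − s·(f + (1−f)·c_B(t/τ_D)) and F_NB = 1 − s·(1−f)·c_NB(t/τ_D), with
scaling s, immobile fraction f, permeability p and τ_D shared. Bounded least
squares (p ∈ [0, 100], τ_D ∈ [1e−3, 1e4] s, f ∈ [0, 1], s ∈ [0.5, 1.5]) with
multi-start over p₀ ∈ {0.1, 1, 10}: the objective is weakly curved in p at
large p (an almost-open boundary looks the same at any larger permeability),
so a single start can stall in that valley. A start whose residuals are
already far below measurement noise short-circuits the rest. Standard errors
come from the Gauss–Newton covariance at the optimum; parameters pinned at
bounds are flagged.

## Image correlation spectroscopy

Nuclei are segmented at the 40% intensity quantile of the whole image,
chromocenters at the 90% quantile of the nuclear pixels (strictly-greater
comparison, so a constant region yields an empty mask rather than an
arbitrary tie split). The masked region is cropped to its bounding box and
off-mask pixels are filled with the on-mask mean, so they carry zero
fluctuation. The autocorrelation uses the non-periodic, overlap-only
convention — the rectangularized field is not periodic, so wraparound terms
would be artifacts — normalized by the squared mean of the rectangularized
image (equal to the masked mean by construction). A direct shift-loop
implementation defines the convention exactly; the radial average bins shifts
by the integer-rounded length with pair-count weights.

The radial curve is fitted with one or two stretched exponentials. In `auto`
mode the second component is accepted only if it improves the residual sum of
squares by more than 20% — a deliberately blunt rule that mirrors "needed a
second component" decisions without a full model-selection apparatus. λ₁ is
reported as the smaller correlation length, and the physical cluster size as
the full diameter 2·λ₁·pixel (15 nm/pixel by default). Whether the d = 0 bin
(which carries the uncorrelated shot-noise variance) enters the fit is
configurable; it is included by default.

## Optodroplet abundance and lifetime

The abundance statistic is the CV (population SD over mean — a fixed
convention so exact tests are possible) of nucleoplasmic pixel intensities,
optionally after Gaussian smoothing and exclusion masks (nucleoli,
pre-existing aggregates). Decay series are double-normalized: divide by the
first post-light-off frame's CV, then subtract the final normalized value; if
the pre-illumination CV lies *below* the final CV (long-lived droplets that
never fully dissolved), the normalized pre-illumination value is subtracted
instead. The subtraction-after-division order is a fixed convention here
(its inverse is applied consistently in the generator).

The normalized decay is fitted with A(t) = A₀(1 + kt)e^(−kt) (+ plateau for
long-lived-droplet constructs), the minimal two-step dissociation law with a
lag phase (dA/dt = 0 at t = 0). The reported lifetime is the half-decay time
τ = 1.68/k, with 1.68 the positive root of (1 + x)e^(−x) = ½ computed by
bisection. The saturation readout bins (concentration, abundance) cells into
log-spaced bins and reports the first bin center whose mean abundance exceeds
the lowest bin's mean + 2 SD — our construction, since the underlying
relationship is usually drawn only as a guide to the eye; a series that never
crosses reports a "not reached" sentinel rather than a number.

## Polarization-resolved FCS

Model: G_parallel = G_rot·G_trip·G_trans and G_crossed = G_trip·G_trans with
G_rot = 1 + f_R·e^(−τ/τ_R), G_trip = 1 + f_T·e^(−τ/τ_T) and a two-component
anomalous translational term with focal aspect ratio κ fixed by the user (it
is an instrument property). The global fit shares every parameter between
the two modes; since the rotational factor is the only difference, the
parallel−crossed contrast pins (f_R, τ_R) while the crossed curve pins
triplet and translation. Residuals are weighted by per-lag SDs floored at 1%
of the curve maximum. Bounds enforce the time-scale separation
τ_R ∈ [1 ns, 10 μs], τ_T ∈ [0.1, 100 μs]; a fitted f_R consistent with zero
flags τ_R as unidentifiable instead of reporting a meaningless number.

The correlator is a multi-tau cascade (16 linear lags, then 8 per octave with
doubling bin width), computed per 5-s window after removal of Fourier
components slower than 100 ms (stage drift, vibrations), and averaged with
per-lag SDs across windows. Normalization uses the full-window monitor
means: normalizing by the overlapping-segment means instead would bias deep
levels by O(1/segment length). Level-0 lags are bit-identical to a direct
correlator; coarsened octaves agree to the triangular binning tolerance. A
2-D Brownian-in-Gaussian-focus photon simulator exists solely to validate the
correlator amplitude (G(0) ≈ 1/N_eff with N_eff = C·π·w²); synthetic fitting
inputs are model curves plus amplitude-proportional Gaussian noise —
photon-level rotational-dipole simulation is out of scope.

## Ensemble fits and dose-response rules

*Turbidity.* t(c) = a/(1 + (c_sat/c)^n) on blank-subtracted data; with a
shared plateau the datasets are fitted jointly with a single `a`. c_sat
outside the sampled range is flagged. c_sat and n are invariant under
rescaling of the turbidity units.

*lacO FRAP.* F(t) = a₁(1 − e^(−t/τ₁)) + a₂(1 − e^(−t/τ₂)) with τ₂ fixed from
a freely diffusing control; diffusion is otherwise neglected. The transient
fraction is a₁ (free time constant, exchange at the array), the fast mobile
remainder a₂, and the stable fraction 1 − a₁ − a₂ — the pool that does not
recover on the observation window.

*Co-recruitment.* The candidate's array intensity is normalized to the
tether intensity and then to the same ratio for a GFP control (which is only
directly tethered); the excess over 1 counts indirectly bound molecules per
tethered one. That subtraction-of-one is an interpretation baked into the
readout and documented here rather than hidden.

*Dose-response segmentation.* HP1-overexpression mode: Otsu nuclei (256-bin
histogram) in the HP1 channel, chromocenters at 1.3× the per-nucleus median
DAPI. dCas9 mode: nuclei from DAPI, major-satellite repeats at
median + 0.1·(max − median) of the per-nucleus dCas9 intensities. Cells are
grouped low/medium/high at the 40th/60th marker percentiles
(linear-interpolation percentile definition; values at the cutoff go to the
lower group). Touching-nuclei separation is out of scope (sparse cells
assumed); background subtraction before grouping is off by default and
configurable.

## Synthetic data: what it emulates, and what it does not

Every generator serializes its ground truth; recovery tests read truth only
from that record, and identical spec + seed give bit-identical output (one
seed spawns independent child generators via `numpy.random.SeedSequence`).
Defaults are chosen once to represent realistic acquisition conditions:

- *Half-bleach*: curve-level pairs invert the normalization chain exactly;
  image stacks place the series profile in a disk (28 px radius) inside a
  nucleoplasm ring on camera background, optionally with Poisson noise.
  Replicate-averaged fits use 35 pairs at 2% Gaussian ROI noise.
- *STED cluster images*: 256² px at 15 nm/px; five chromocenter disks
  (~10% of the nuclear area, 2× base level so the 90% quantile segments them
  whole) containing sharp 120-nm disks convolved with a ~40 nm FWHM PSF at
  3× enrichment and ~10% area density; photon counts ~150–900 with Poisson
  noise. Sharp-plus-PSF objects are used because the correlation length of a
  sharp disk equals its radius — the identification behind reporting 2·λ₁ as
  a diameter — which does not hold for Gaussian blobs.
- *Optodroplet*: CV series at 10 s/frame from the decay law on a baseline CV
  of 0.15 with amplitude 0.35 and proportional Gaussian noise.
- *Pol-FCS*: model curves on a quasi-log grid of 25 points/decade
  (10 ns–1 s), matching the density of the multi-tau cascade, with
  amplitude-proportional noise.
- *Turbidity*: 8 log-spaced concentrations (2–200 μM), 3 replicates, 5%
  multiplicative noise, constant blank added back so analyses must remove it.
- *Nuclei panels*: 112² px frames in which the nucleus is a minority of the
  field (Otsu's bimodal split must land between background and nucleus, as in
  real confocal frames); size-buffering populations hold compartment area
  fixed with intensity ∝ expression (2.5× enrichment), concentration-
  buffering populations the converse (2× enrichment) over a 5-fold
  expression span.

Not emulated: optical aberrations, detector afterpulsing, axial sectioning,
cell-to-cell shape variability, chromatic misregistration, photobleaching
during acquisition, and photon-level polarization physics. Passing recovery
tests therefore demonstrates correctness and statistical efficiency of the
estimators under the stated noise models, not robustness to every real-world
artifact.

## Problem sizes and numerical conventions

Test and acceptance runs use deliberately compact problem sizes — e.g.
48×96-cell finite-difference grids, two to fourteen synthetic cells per ICS
check, 10⁴–10⁵-sample correlator traces, five replicate experiments per
reported recovery — chosen as the smallest sizes at which the checks are
statistically meaningful. Coordinates are 0-based pixel-centered (row, col);
physical units attach only at I/O boundaries; reports embed the full
configuration, seed and package version, and deterministic pipelines
reproduce reports bit-identically.

## Known limitations

- The half-bleach model assumes an instantaneous, perfectly half-plane
  bleach and a circular compartment; irregular bodies bias p and τ_D.
- p is weakly identified once the boundary is effectively open (p ≳ 20):
  fits report it pinned at the bound rather than inventing precision.
- The ICS `auto` rule (20% RSS improvement) is a heuristic; for principled
  selection compare fits with an information criterion externally.
- The saturation-concentration rule depends on the lowest-concentration bin
  being a genuine baseline; populations without low expressors mislead it.
- The multi-tau correlator assumes stationarity within each 5-s window;
  strong photobleaching violates it.
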