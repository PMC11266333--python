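# Methods

This note documents the model, its assumptions, the numerical choices,
and what the desk-scale studies do and do not establish.

## Scanner model

The scanner is a cylindrical ring of 34 sectors; each sector holds 4
axially stacked modules of 4 transaxially stacked blocks carrying a
4 × 9 crystal array (5.3 mm axial × 3.95 mm transaxial × 25 mm deep
LYSO).  The 9-crystal block axis is taken axial and the 4-crystal axis
transaxial: this is the only assignment that yields 544 crystals per
ring (hence 272 sinogram projections), 36 rings, and a ~19-cm axial
field of view simultaneously.  `ring_radius_mm` is the crystal
front-face radius; it is not a published quantity and defaults to
372 mm, chosen so that the minimum-sector-difference-4 coincidence
acceptance spans 2·372·cos(2π·2/34) ≈ 694 mm ≈ 70 cm transaxially.
Inter-crystal, inter-block and inter-module gaps default to 0; the
axial extent is always reported as computed from the pitches (190.8 mm
by default), never forced.  Crystals subtend equal arcs on the
front-face cylinder (a cylindrical approximation of the flat blocks);
the leftover arc between the crystal span and the sector pitch forms the
inter-sector gap, so rays can miss between sectors.  The indexing
convention is 0-based throughout:

    flat_id = ((sector·4 + module)·4 + block)·36 + crystal_a·4 + crystal_t
    ring    = module·9 + crystal_a
    transaxial_pos = sector·16 + block·4 + crystal_t

Detection efficiency is uniform by construction; lead shielding and the
plastic cover are config flags consumed only as optional transport
annotations and default to off.

## Phantoms and materials

Phantoms are ordered lists of geometric primitives (sphere, cylinder,
annulus, box; cylinders and annuli are scanner-axis aligned); in
overlaps the *later* primitive wins.  511-keV linear attenuation
coefficients and Compton fractions ship in `data/materials.yaml`,
computed from standard photon cross-section tabulations (mass
attenuation × density, coherent scattering excluded) and frozen.
Dimensions the performance standard fixes but that are easy to
mis-state are hard-coded with comments: the scatter-phantom line bore
45 mm below the cylinder axis, sleeve walls of 1.25 mm starting at a
3.9-mm inner diameter, IEC sphere diameters 10–37 mm on a
114.4-mm-diameter circle, a 50-mm lung insert.  The patient bed is a
generic carbon-fibre slab, included in the scatter scenario by default.

## Transport

Decays form an inhomogeneous Poisson process with intensity
A₀·2^(−t/T½), T½ = 6586.2 s; each decay annihilates with probability
0.969.  Photon pairs are exactly back-to-back unless the Gaussian
acollinearity option is enabled; positron range is an optional Gaussian
blur.  Both default to off — the simulated spatial resolution is already
finer than a physical scanner's, and these refinements only matter for
resolution studies at sub-millimetre scale.

Free paths are sampled exactly against the piecewise-constant μ along
each ray (analytic primitive intersections, priority evaluated at
segment midpoints).  An interaction is absorption with probability
1 − compton_fraction, otherwise a single Klein–Nishina-sampled Compton
scatter; after `max_scatters` (default 1) scatters a photon escapes
without further interaction.  The single-scatter approximation is the
principal simplification relative to a full physics engine: it produces
a realistic scatter fraction (~40 % on the 70-cm phantom) and a
scatter/random background for the TOF spectra, but underestimates
multiple-scatter tails.  Outside every primitive the background is
vacuum; ambient air would attenuate < 0.5 % over the bore and can be
added as an explicit air primitive if wanted.  Detection deposits the
full remaining photon energy in the entered crystal (no inter-crystal
scatter, no depth-of-interaction: the hit is positioned at the
front-face entry, and the chord to the outer crystal radius sets the
capture probability 1 − e^(−μ_LYSO·chord)).  Hit times are decay time
plus path length over c, carried as double-precision ns; TOF arithmetic
is done in ps.

## Digitiser

Stage order: adder → readout → pile-up → quantum efficiency → energy
blur → energy window → deadtime → timing blur → noise injection →
coincidence sorter.  Pile-up precedes energy discrimination because
summed pulses must be re-discriminated (a stacked true can leave the
window, a stacked scatter can enter it).  Deadtime defaults to 0 ns and
sits after the window, where an experimentally determined value could be
inserted directly; the placement and the paralyzable/non-paralyzable
model are switchable.  The readout's energy centroid keeps the earliest
constituent timestamp on purpose — repositioning without re-timestamping
is what degrades the coincidence timing resolution in Anger-logic
systems, and the model reproduces that mechanism.  Centroid ties round
to the lower crystal id.  Pile-up merges chained pulses whose
inter-arrival gaps are below the 20-ns window; the merged pulse keeps
the first pulse's time, crystal and event id and ORs the scatter flags.
Energy resolution scales as FWHM(E) = 0.094·√(511·E) keV (constant
fractional resolution at 511 keV, inverse-square-root elsewhere); only
the 511-keV value is empirically constrained.  Background noise is a
homogeneous Poisson stream at 1193 kHz, uniform over crystals, with
energies drawn uniformly inside the 425–650 keV window — the simplest
model that passes the window by construction; nothing downstream
depends on the noise energy spectrum.  The sorter gives every single its
own 2.45-ns window; take-all-goods emits each unordered pair with
|Δt| ≤ τ exactly once (ties in time are broken by crystal id).
Classification against truth: same event id and neither photon
scattered → true; same event id otherwise → scatter; different events or
noise → random — an exact partition of the prompts.

## Sinograms

The transaxial convention maps a crystal pair to (view, radial) through
the LOR normal angle θ ∈ [0, π) and signed offset s at the
crystal-centre radius R_c: view = ⌊θ/(π/272)⌋, radial = 207 + round(s/Δs)
with Δs = π·R_c/544 ≈ 2.22 mm (the interleaved half-crystal pitch).  A
diametral same-ring LOR lands in the central bin 207 of 415.  Axially
the full ring-pair Michelogram (36² = 1296 planes, ordered by segment)
is used; the vendor's proprietary 1261-plane layout is *not* replicated
— every analysis here operates after single-slice rebinning or on axial
sums and is invariant to the plane ordering, which the test suite
asserts by comparing Michelogram-then-SSRB against direct SSRB binning.
Binning can rebin axially on the fly (`planes="ssrb"`), which the
pipelines use to avoid materialising the ~0.5-GB full Michelogram, and
can cap the ring difference; counts are conserved exactly in integer
arithmetic.  TOF bins are 29 × 169.26 ps centred on Δt = 0, covering the
4.9-ns coincidence window; out-of-window differences are discarded and
counted.  Randoms-from-singles evaluates r_xy = 2τ·s_x·s_y over every
accepted crystal pair blockwise per ring pair; cross-ring contributions
are split evenly between the two Michelogram planes of a ring pair
(immaterial after SSRB).

## NEMA analyses and desk-scale adaptations

All studies run at a few 10⁵ decays per frame instead of ≥10⁷ prompts;
the frame *activities* are kept realistic and the durations shrunk, so
rate-dependent physics (randoms, pile-up, noise) is preserved while
counting noise is larger.  Adaptations this forces:

* **Count losses.** The standard's per-projection max-alignment is
  performed on slice-summed, lightly smoothed (5-bin boxcar) radial
  profiles, and the per-view shift is applied to all slices.  The line
  source is axis-parallel, so its radial position is slice-independent
  and this is exact; at full statistics the two procedures coincide,
  while at desk scale the per-(slice, view) argmax would lock onto
  noise.  The strip method itself is literal: 120-mm mask, ±20-mm
  strip, edge pedestal by linear interpolation at ±20 mm; trues are
  C_TOT − C_r+s, the scatter fraction is averaged over the 3
  lowest-activity frames (randoms negligible there, threshold
  configurable), S = T·SF/(1−SF), R = prompts − T − S,
  NEC = T²/(T+S+R).
* **TOF.**  The timing error is measured Δt minus the geometric Δt from
  the closest point of the known line to the LOR through the crystal
  centres.  Mashing quantises Δt on a CS-wide lattice whose phase
  relative to each event's error is uniformly distributed (the
  geometric offset varies continuously across LORs), so the estimator
  quantises with a per-event uniform phase and then applies the NEMA
  uniform up-sampling; each step contributes (CS)²/12 of variance, and
  the reported CTR_cor removes their quadrature sum
  2√(2 ln 2)·CS/√6 ≈ 162.7 ps.  The fine spectrum is boxcar-smoothed
  over 5 × 13.02 ps bins (≤0.3 % quadrature bias) and a linear pedestal
  interpolated between the tail means beyond ±1.5 ns absorbs scatters
  and randoms.
* **Spatial resolution.**  2D FBP (ramp filter, cut-off a fraction of
  Nyquist, parallel-beam approximation of the interleaved sinogram) of
  the SSRB slices around each axial position, with the ring difference
  capped (default 6) because SSRB smears a radially offset point
  axially in proportion to offset × ring difference.  Peak values come
  from a parabolic fit through the three samples around the maximum;
  FWHM/FWTM by linear interpolation between straddling samples —
  exact on triangles, <1 % biased on sampled Gaussians (asserted over a
  sweep of sub-bin offsets).  Sources are placed on the +x axis so
  image axes coincide with radial/tangential/axial.  The model has no
  depth-of-interaction or inter-crystal scatter, so its radial
  resolution does not degrade with offset the way a physical scanner's
  does.
* **Sensitivity.**  Decay-corrected per-sleeve rates are fitted
  log-linearly in accumulated wall thickness; the fitted slope is an
  *effective* attenuation (both photons cross the sleeve, obliquely),
  which is exactly why the standard extrapolates empirically rather
  than inserting a tabulated μ.  The absolute sensitivity of this
  idealised model (~2.4 %) exceeds a physical scanner's (~1.3 %)
  because packing losses, dead material and inter-crystal effects are
  absent.
* **Image quality.**  The proprietary iterative reconstruction is out
  of scope; a synthesiser (rasterised activity ⊗ isotropic Gaussian
  PSF + seeded Gaussian noise scaled to the background median) provides
  controlled ground truth for the metric code.  ROIs are voxel-centre
  circular masks; the 12-position background template (shipped as
  `data/iq_background_rois.yaml`) sits on a 100-mm radius at angles
  interleaved between the spheres, ≥15 mm from wall and spheres, on 5
  slices (0, ±10, ±20 mm).  CRC, BV, IR and the lung error follow the
  standard's ratio definitions and are invariant under global
  rescaling.

## Calibration

The noise/quantum-efficiency fit is ordinary least squares of
experimental-like singles rates on bare-digitiser rates,
S_exp = QE·(S_sim + Noise): slope = QE, intercept/slope = Noise; only
low-activity frames (below a configurable cut, i.e. unaffected by
deadtime) enter.  Pile-up optimisation scores each candidate window by
the maximum relative prompt-rate difference against a reference curve
over ≥3 activity points, seeded and deterministic, skipping and
recording failed candidates.  Normalisation assumes the model's uniform
efficiencies: geometric factors per (radial, plane) are the analytic
thin-annulus projection 2(√(R_o²−s²) − √(R_i²−s²)) scaled to the
measured plane totals over the measured profile (empty support bins
flagged and set to 1), and crystal efficiencies are fan-sums over a
flood-source trues list-mode, normalised to mean 1.  The flood input is
a coincidence table rather than a sinogram because the float binning
convention has no exact bin → crystal-pair inverse; fan-sums need the
pairs.  Annulus/flood statistics are scaled down (10⁶–10⁷ trues);
factor noise scales accordingly and the tests use tolerance bands.

## Numerical choices and degenerate inputs

Ties: centroid rounding to the lower crystal id; equal-time singles
ordered by crystal id; transaxially coincident (purely axial) LORs are
unbinnable and discarded.  The FBP output is scaled as
(π/N_views)·Σ q_θ with the ramp in cycles/mm, validated against the
analytic disc sinogram (interior mean within 5 %).  Empty inputs raise
`AnalysisError`s naming the violated precondition (all-zero images,
single-frame fits, unreachable tenth-max, imaginary mash correction —
reported with both values).  All randomness flows from
`numpy.random.Generator`; pipelines derive per-stage child seeds from
one global seed via a CRC32-labelled `SeedSequence`, so stages are
individually reproducible and seeds stay below 2³¹.

## Limitations

No multiple scatter beyond `max_scatters`, no Rayleigh scattering, no
inter-crystal Compton or its recovery, no depth of interaction, no
energy-dependent attenuation below 511 keV for scattered photons (they
escape after the scatter budget), uniform crystal efficiencies, no
iterative/TOF reconstruction.  Consequently the absolute sensitivity and
count rates exceed a physical scanner's, and passing tests establish the
correctness of the *analysis machinery* and the *relative* physics
(curve shapes, scatter-fraction band, NEC peak location, timing round
trips) — not quantitative agreement with any particular scanner's
published characterisation.
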