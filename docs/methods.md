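# Methods

`froidose` models the dosimetry of filtered region-of-interest (FROI)
cone-beam rotational angiography of the head: an attenuating sheet with a
circular aperture is placed in the beam so that only the diagnostic region
of interest receives full exposure, and the question is how much organ and
effective dose this saves over a plain rotational acquisition.  The package
covers the full chain — beam model, effective-parameter calibration, voxel
phantom, photon transport under the kerma approximation, and ICRP 103
dosimetry — at desk scale.

## Beam model

Tube spectra are generated by a semi-empirical thick-target tungsten model:
Kramers emission integrated over the electron slowing-down depth, with
target self-attenuation through the anode at the takeoff angle (default
12°) via a Thomson–Whiddington depth–energy relation
(C_TW = 7·10⁵ keV² cm²/g), plus the tungsten K lines above 69.5 keV with an
overvoltage-dependent yield.  Spectra are relative fluence in 1 keV bins
from 1 keV to the tube voltage; every downstream quantity is a ratio, so
normalization is arbitrary.  This is a deliberately simple model: its
low-energy tail is the least certain part, and all calibration procedures
below are designed so that spectrum-shape errors largely cancel.

Photon interaction coefficients (μ/ρ and μ_en/ρ) are bundled as compiled
tables on a fixed grid covering 1–150 keV, log-log interpolated, for the
elements H, C, N, O, S, Al, Cu, Gd, W and the compound entries air, water,
ICRU-44-style soft tissue and cortical bone.  The entries that control the
quantitative results (C, Al, Cu, air, water, soft tissue, bone in the
10–150 keV range) are accurate to ≈1–2%; Gd and W are coarser (Gd appears
only inside self-consistent round-trip fits, W only in anode
self-filtration), and the sub-10 keV extension is a photoelectric
extrapolation that carries no fluence behind clinical prefiltration.
Gd₂O₂S uses the handbook density 7.32 g/cm³.

Two instruments appear in the published transmission data and are modeled
with different inherent filtrations, neither of which is printed:

* the rotational C-arm: 1.5 mm Al window (typical angio tube) plus the
  manufacturer prefilter 0.3 mm Cu + 2.6 mm Al;
* the CT on which the patient table was measured: 6.0 mm Al equivalent
  (typical center-beam inherent plus shaped-filter contribution) plus the
  stated 2.5 mm added Al.

Both are estimated instrument parameters.  The CT value is additionally
supported by the cross-voltage consistency of the published transmissions:
with a much thinner assumed filtration the same measured data imply
effective densities that disagree across tube voltage by ~4%, with 6 mm
they agree within 2%.

## Calibration fits

Broad-spectrum transmission of a slab is computed as the ratio of
air-kerma-weighted spectrum integrals (weight E·(μ_en/ρ)_air(E), matching a
solid-state air-kerma dosimeter; plain fluence weighting is available as an
option).  Both calibration procedures are bracketed root searches on this
strictly monotone transmission curve, solved to machine tolerance:

* **Effective ROI-filter thickness** — thickness of a pure Gd₂O₂S slab
  matching a measured transmission of the composite screen filter.  The
  published per-voltage fits for 1–4 filter layers are pooled by dividing
  each by its layer count and averaging; the per-layer mean (0.102 mm),
  its 2σ spread, and the n-layer row averages reproduce the published
  table.  The underlying measured transmissions were never published, so
  the fitting operation itself is validated by round trips (recover a known
  thickness from its own transmission to 10⁻⁴ mm).
* **Effective table density** — density of a pure-carbon slab of assumed
  thickness matching the five measured table transmissions (70–102 kVp).
  Transmission identifies only the areal density ρ·t (≈1.73 g/cm² here);
  the reported density scales exactly inversely with the assumed thickness.
  The default thickness, 35.8168 mm, is the scale convention that puts the
  fitted densities on the published per-voltage density scale (mean
  0.484 g/cm³); it is also a physically plausible head-rest shell
  thickness.  Only the areal density is a physical claim.

The absolute-dose calibration factor is CF = (D_air/I·t)_meas /
(D_air/φ)_sim, one per tube voltage: measured free-in-air kerma per mAs at
the isocenter divided by the simulated free-in-air kerma per primary in the
identical rotational geometry.  Absolute voxel dose is then
D_abs = D_sim · CF · I·t with the per-frame mAs.  The measured D_air behind
the published analysis was never printed, so absolute doses in mSv are not
reproducible here; the comparative analysis (reductions, table influence,
position effects) is ratio-based and needs no CF.

## Cross-prediction of the table transmission (a known discrepancy)

Evaluating the fitted table slab under the 80 kVp C-arm beam gives a
narrow-beam kerma-weighted transmission of 0.71.  The published value for
this cross-check is 0.77, obtained there from a full Monte Carlo simulation
of the detector geometry.  The gap is robust: scanning the anode angle
(8–16°), window filtration (0–4 mm Al), detector weighting (kerma or
fluence) and emission-shape variants moves the narrow-beam prediction only
within 0.70–0.74, because the five fitted transmissions (0.68–0.71 at
70–102 kVp) pin the areal density and carbon's μ/ρ varies too little
between these beam qualities to reach 0.77.  A detector-geometry simulation
includes broad-beam scatter buildup into the detector, a few percent
effect that narrow-beam weighted attenuation excludes by construction (the
package's transport deliberately treats filters and table as pure
attenuators).  The package reports the narrow-beam value and flags the
difference rather than modeling detector scatter.

## Phantom

The synthetic head phantom stands in for a reference anthropomorphic
phantom that cannot be redistributed.  It is a deterministic, parametric
head-and-neck: ellipsoidal head with a 4 mm skin shell, 6 mm cranial bone
shell enclosing the brain ellipsoid, anterior eye-lens spheres,
infero-lateral salivary-gland ellipsoids, a posterior spinal cord cylinder,
and a neck cylinder, in a frame where +Y is anterior, Z caudo-cranial, and
the orbit plane sits at Z = 1580 mm so the published isocenter coordinates
(X 265, Y 90, Z 1580 / 1550 mm) land in the intended anatomy.  Densities:
soft tissue 1.05, skin 1.09, lens 1.07, salivary 1.03, cord 1.04, cortical
bone 1.92 g/cm³; all soft tissues share the soft-tissue coefficient table
(a simplification — compositional differences between brain, gland and
muscle are ≈1% in μ over 20–100 keV).  Voxel size defaults to 2.5 mm
isotropic; organ volumes agree with the analytic ellipsoid volumes to the
voxel-shell level.  A seed-driven relative size jitter (off by default)
provides anatomical variability when wanted.

What the phantom does not emulate: real anatomical heterogeneity (sinuses,
trabecular/cortical separation, red marrow distribution), body below the
shoulders, and the true ICRP organ masses.  Consequently absolute organ
doses on this phantom are *not* comparable to reference-phantom values;
directions, ratios and reductions are the meaningful outputs, and all
passing tests should be read at that level.

The patient table is attached by extending the grid posteriorly with a
rectangular carbon slab of the fitted effective density spanning the
phantom's X–Z footprint, separated by an air gap (default 10 mm).

## Geometry and transport

The source rotates in the axial plane on a 70 cm radius (the published
source–surface distance with the calibration chamber free-in-air at the
isocenter; an assumption, configurable), detector at 110 cm with a
20×20 cm field of view.  The published protocol is 106 projections at 2°
from 106°; the published end angle 318° contradicts this arithmetic and
316° wins.  Angles increase clockwise viewed from cranial with the source
anterior at 90°, which centers the 212° arc anterior to a supine patient —
the configuration in which the head-rest shadows only a minority of
projections, consistent with the published finding that the table matters
at the percent level.  "ROI size 20% of FOV" is read as aperture *area* =
20% of the FOV (projected radius ≈5.05 cm at the detector), with a
linear-fraction interpretation available.

Filters (prefilter and ROI filter) enter as per-ray attenuation weights
(weighted-attenuation rule); scatter generated in filter materials is
neglected.  Electrons are not transported anywhere: energy transferred to
electrons is deposited locally (kerma ≈ dose at these energies), using the
collision-kerma coefficient μ_en.

Two engines share one normalization (one primary per frame, summed over
frames):

* **Deterministic primary-kerma engine** (default): exact Siddon voxel
  traversal from the source to every non-air voxel center, per-energy-bin
  Beer–Lambert attenuation (phantom + filters), inverse-square fluence,
  collision-kerma deposition.  No scatter, exactly linear in mAs, exactly
  testable against closed forms.  Spectra are re-binned to 2 keV groups by
  default (0.2% effect on dose ratios; 1 keV available).
* **Monte Carlo photon engine** (fidelity reference, adds scatter): analog
  transport with Woodcock delta-tracking on a 1 keV cross-section grid;
  photoelectric absorption, free-electron Klein–Nishina Compton scattering
  (no Doppler broadening/binding), and a crude Rayleigh channel (Thomson
  angular shape, small empirical coherent fraction) — both documented
  fidelity limits.  Type-A uncertainties come from independent history
  batches (default 10–20); organ-level errors are recomputed from batch
  means because voxel errors are correlated within a history.

Known discretization behavior, relevant when comparing the engines: the
deterministic engine point-samples the voxel center while MC deposits over
the voxel volume.  The relative difference grows as (μ·Δx)²/24 and reaches
a few percent for cortical bone below 40 keV at 4 mm voxels; organs
straddling the cone edge additionally differ through partial-volume
penumbra.  The engine cross-validation test therefore uses an organ-labeled
cube fully inside the beam at 2.5 mm voxels and 60 keV, where both effects
are controlled; agreement is within statistical uncertainty there.

## Dosimetry

Organ equivalent dose is the mass-weighted mean voxel dose (w_r = 1 for
photons).  Effective dose uses the bundled ICRP 103 tissue weighting
factors over whatever tissues the phantom provides: skull maps to the
bone-surface term, the left/right salivary glands combine mass-weighted,
generic soft tissue enters the remainder (arithmetic-mean rule) as muscle,
and the eye lens is reported but never summed into E.  Organs absent from
the head phantom are listed with zero contribution and E is labeled a
partial-body effective dose.  Relative dose reduction is
1 − H_T(filtered)/H_T(baseline) per organ and for E; calibration cancels.
The theoretical benchmark is the dose-area-product reduction
R = (1 − aperture fraction)·(1 − transmission).

## Problem sizes

Desk-scale defaults: 2.5 mm voxels (≈0.7 M voxel head), 106 projections,
2 keV energy groups — about one minute per deterministic scan on one core.
The MC engine defaults to 10⁶ histories, which resolves organ means of
beam-covered organs to ≈0.2–1%; voxel-resolved MC maps need far more and
are not a desk-scale output.  Tests and the sweep examples use 4–5 mm
phantoms and reduced arcs where only directions or ratios are asserted.

## Known limitations

* No scatter in the deterministic engine; the MC engine's Rayleigh and
  Compton models are simplified (free electrons, form-factor-free coherent
  channel).
* Narrow-beam transmission cannot reproduce detector-geometry transmission
  measurements to better than a few percent (see the cross-prediction
  section).
* The synthetic anatomy places the eye lenses near the projected edge of
  the 20%-area aperture, making their filtered dose unusually sensitive to
  small geometry changes — an artifact of the stand-in anatomy.
* Tube current modulation is not modeled (deliberately, following the
  modeled protocol); absolute doses require a measured free-in-air
  calibration that is not available.
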