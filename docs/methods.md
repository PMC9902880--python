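# Methods

## Binding model

Probe-1 sites on the surface compete for two ligands in solution: the target
miRNA (dissociation constant `kd_target`) and the quencher strand probe 2
(`kd_probe2`). The solution volume (tens of µl) vastly exceeds what the
probe spot can deplete, so free concentrations equal totals and the
occupancies are closed-form:

    theta_target = (cT·e/KT) / (1 + cT·e/KT + c2/K2)

with `theta_probe2` analogous and `theta_free` the remainder. `e` is the
species' relative capture efficiency (perfect match 1), a phenomenological
stand-in for mismatch thermodynamics: the assay's published selectivity is a
set of fold differences, not ΔG values, so mismatches are modelled as
proportionally weaker capture. The fluorescent emitter density is

    probe1_surface_density·(theta_target + baseline·theta_free) + nonspecific_density

where `baseline` is the fraction of probe-1 sites never paired with probe 2
(incomplete quenching) and the last term is non-specific adsorption.

Kinetics are pseudo-first-order: `theta_target(t) = theta_eq·(1 − exp(−k_obs·t))`
with `k_obs = k_obs_per_conc·(cT + c2)`. Neither affinities nor rates are
published for these probes; the defaults — `kd_target` = 10 pM,
`kd_probe2` = 10 nM (probe 2 the weaker binder by design),
`k_obs_per_conc` = 1e7 /(M·min) — are plausible hybridization magnitudes
chosen so that the standard condition (10 pM target, 10 nM probe 2) reaches
99.7% of equilibrium at the protocol's 60-min reaction time, consistent with
the observed near-saturation there. All are overridable per species in the
run config.

## Movie simulator

Emitters are a homogeneous Poisson process: count ~ Poisson(density × field
area), positions uniform over the field minus a 10 px border (2 px inside
the detector's 8 px margin, so detections never clip). Each emitter carries
one fluorophore by default — one Cy5 per captured probe — or two with
probability `multi_emitter_fraction` (two probes inside one
diffraction-limited spot). Fluorophore lifetimes are exponential in frame
units at `bleach_rate`; a fluorophore emits for every full frame before its
bleach frame, so the surviving fraction in frame t is exactly exp(−rate·t).

Rendering integrates a symmetric 2-D Gaussian PSF over each pixel
(error-function differences), then applies the standard EMCCD chain per
pixel and frame: Poisson photoelectrons of signal + background, Gamma(shape
= photoelectrons, scale = EM gain) amplification (the usual excess-noise
model; skipped at gain 1), Gaussian read noise, a fixed offset, clipping at
zero and quantization to 16-bit counts. Movies are bit-reproducible from a
single seed; region sets use independently spawned child streams.

The optics and photon budget of the original instrument are unpublished;
the defaults — 256×256 px at 0.16 µm/px, PSF σ 1.3 px, 600 detected
photons/fluorophore/frame, 20 background photons/px/frame, gain 30, read
noise 10 counts, offset 100, bleach rate 0.01/frame (10 s mean, within the
"few to tens of seconds" bleaching regime) — give a peak-pixel SNR of ≈ 10
on the 5-frame detection average, matching the SNR ≥ 8 regime the validation
suite targets. Counting movies are 30 frames (the imaging protocol);
trace-validation scenes use longer configurable movies since most dyes
outlive a 3-s window.

What the generator does *not* emulate: dye blinking (a config extension;
the trace filter's no-upward-step rule would reject blinkers), drift,
uneven illumination, aggregation, and camera pixel-response nonuniformity.
Passing tests therefore demonstrate the correctness of the counting chain
under idealized single-molecule statistics, not robustness to those
real-data artifacts.

## Spot detection

Detection runs on the mean of the first 5 frames (SNR gain at negligible
early-bleach cost): difference-of-Gaussians band-pass (σ 1.3/3.25 px),
threshold = median + 5 robust SDs (MAD-scaled — spot pixels would bias plain
moments), 8-connected local maxima, suppression of maxima within 4 px of a
brighter one (ties broken toward smaller row, then column), an 8 px border
margin, and a 3×3 intensity-weighted centroid for the sub-pixel position.
Everything is deterministic; raising the threshold can only remove
detections, and whole-pixel translations of a noise-free scene translate
detections exactly.

## Trace analysis

Aperture photometry per frame: sum of pixels within 3 px of the spot minus
(aperture pixel count × median of a 4–6 px annulus). Step structure is
fitted by penalized binary segmentation under an L2 cost: a split is
accepted while it lowers the residual sum of squares by more than
β = penalty·σ²·log n (penalty default 5, minimum segment length 2), with σ
estimated robustly from median absolute successive differences (immune to
the steps themselves). A trace is single-molecule-consistent when it has no
upward level change and at most one downward change; "validation" mode
additionally requires the final level to sit within 2σ of zero (the dye was
seen to bleach out). Counting mode does not require the bleach to occur
inside the 30-frame movie, since typical bleach times exceed the 3-s window.

Binary segmentation is greedy, not globally optimal: on staircases whose
adjacent levels are only a few σ apart, or whose levels last a single frame,
it can pick different change points than an exhaustive search. In the
assay's operating regime (step sizes ≥ 8σ, levels ≥ 2 frames) it matches the
brute-force optimum exactly on the seeded test corpora; outside that regime
only the level *count* is reliable, which is all the accept/reject filter
uses.

## Quantification

Counts are summarized per region (accepted spots), per sample as mean ±
sample SD over 10 regions — the mean rather than the sum, so results are
stable under region-count changes. Calibration is ordinary least squares of
mean count against log10(concentration in pM) or log10(cell number);
R² = 1 − SSres/SStot. The LOD is the closed-form crossing of the fitted
line with blank mean + 3 SD — the conventional criterion, recorded in the
output since the original report states a detection limit without one. A
LOD below the fitted range is flagged as an extrapolation. Selectivity folds
are ratios of sample means, reference over variant.

## Experiment templates and the counting-efficiency model

The calibration and selectivity experiments are *configured* in expected
accepted counts: "place emitters such that the expected accepted count per
region is N". Accepted counts sit below emitter counts through three losses,
all fixed a priori by the imaging/detection configuration:

1. **close-pair merging** — emitters whose candidate maxima fall within the
   minimum separation (+0.5 px, since maxima are pixel-quantized) collapse
   into one detection; modelled by a position-only Monte Carlo of the
   Poisson process under the detector's greedy suppression rule, using a
   fixed internal random stream independent of run seeds;
2. **early bleaching** — an emitter dark for most of the detection
   averaging window is missed; survival of half the window,
   exp(−rate·m/2), is used;
3. **merged-spot rejection** — a merged cluster of k single-dye emitters is
   rejected by the trace filter when ≥ 2 of its dyes bleach within the
   movie (two distinct downward steps).

`CountingEfficiencyModel.invert` maps a target accepted count to an emitter
density through a monotone interpolation table of this forward model. It is
an approximation (PSF blending, localization jitter and threshold effects
are not modelled); end-to-end recovery tests bound its residual error at
1–2% across the working range.

Two experiment-specific choices:

* **Selectivity** runs through the binding model in the dilute capture
  regime (`kd_target` set two orders above the 10 pM working concentration,
  with the probe-1 surface density raised so the perfect-match count still
  sits on the concentration response line). Fold ratios of counts equal
  efficiency ratios only when occupancy is linear in `cT·e`; near
  saturation the ratio compresses (e.g. 1.73 instead of 2.1 at
  `cT = kd_target`), which is a property of any competitive isotherm, not
  of the pipeline.
* **Cell series** clamp negative expected counts to zero: the steep MB-231
  response line extrapolates below zero at 100 cells. The clamp biases the
  recovered slope by ≈ −2%, well inside the replicate scatter.

## Problem sizes and numerical choices

Quantitative experiments use 4 conditions × 10 regions × 30 frames at
256×256 px, averaged over 3 replicate master seeds; detector validation uses
10 independent fields at 0.05 spots/µm²; the step classifier is validated on
500 rendered 60-frame traces. Degenerate inputs are defined throughout:
zero target → zero occupancy; zero density → empty fields; constant traces →
one level, no change points; all-equal 3×3 neighborhoods → integer-pixel
centroid; empty detection sets → precision 1, recall per truth count.
Occupancy conservation holds to 1e−9, the kinetic asymptote matches
equilibrium to 1e−8, and OLS agrees with the normal equations to 1e−10
relative.
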