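# Methods

## Airway tree and pressure-drop model

The airway is a symmetric bifurcating tree of 25 conduits: the
endotracheal tube (ETT) at generation −1 (9 mm × 330 mm), the trachea at
generation 0 (18 mm × 120 mm) and bronchial generations 1–23. Generation
`n ≥ 1` holds `2^n` identical branches, each carrying `Q/2^n` of the inlet
flow `Q`; the ETT and trachea are single conduits carrying the full flow.
The reference morphometry tabulates generations −1, 0, 1–4 and 23
individually and gives only endpoints for generations 5–16 and 17–22;
those spans are filled by geometric (log-linear) interpolation, matching
the multiplicative taper of airway morphometry. The fill rule has little
numeric weight: the drop budget is dominated by the ETT and proximal
airways. Airway dimensions are held constant within a breath (no
compliance of the walls), and the tree is strictly symmetric — no
Horsfield-type asymmetry, no lobar heterogeneity.

Each generation contributes, at its per-branch flow:

* a Poiseuille drop `128 μ L Q / (π D⁴)` — identical, by substituting the
  laminar friction factor `f = 64/Re` into the Darcy–Weisbach major-loss
  form, to the major head loss (the test suite checks the two derivations
  agree to machine precision);
* a minor (bifurcation) loss `(8 K_L ρ / π²) Q|Q| / D⁴`, signed as `Q|Q|`
  so the loss always opposes the flow. The minor term is summed over all
  generations including the ETT and trachea.

Constants: μ = 1.9·10⁻⁵ Pa·s, ρ = 1.25 kg/m³, K_L = 2 (an average
coefficient across bifurcation geometries). All internal computation is in
SI; the API uses clinical units (mm, L/s, cmH₂O) with 1 cmH₂O = 98.0665 Pa.
The model stays laminar at all flows: Reynolds numbers are reported with a
laminar flag (Re < 2000) but no turbulent correction is applied.

The whole tree collapses to two lumped coefficients, `ΔP(Q) = aQ + bQ|Q|`,
with `a` the linear Poiseuille resistance (0.531 cmH₂O/(L/s) for the
reference tree) and `b` the quadratic minor-loss coefficient
(4.63 cmH₂O/(L/s)²).

## Patient-specific multiplier α

One dimensionless multiplier α ∈ [0.45, 1.50] rescales *every* diameter,
ETT included. Scaling the ETT — nominally a rigid tube of known size — is
deliberate: the model's defining identity `ΔP(α) = ΔP(α=1)/α⁴` holds only
under uniform scaling, and the packaged per-patient AUC pairs are
internally consistent with it (e.g. (0.36/3.33)^(1/4) ≈ 0.57). α is a
lumped surrogate for whatever narrows the effective airway — constriction,
secretions, regional collapse — not a literal anatomical measurement.

Identification matches the area under the model's inspiratory drop-vs-time
curve to the dynostatic AUC. Because the drop scales exactly as α⁻⁴, the
absolute-percentage-error criterion between the two AUCs is minimised in
closed form by `α = (AUC_model(α=1)/AUC_DSA)^(1/4)` — no 1-D search is
needed, and the reported APE is zero whenever the estimate is not clamped
at a bound (clamping is flagged). A per-sample diagnostic series — the
fourth root of the drop ratio at each inspiratory sample, masked where
ΔP_DSA < 0.05 cmH₂O because the fourth root amplifies noise near zero —
shows how uniformly one multiplier explains the breath; its scaled median
absolute deviation over √n is reported as a dispersion-based uncertainty
(`alpha_se`). It measures model adequacy, not sampling error.

## Dynostatic algorithm

The dynostatic pressure assumes equal inspiratory and expiratory airway
resistance at isovolume, giving
`P_dyn = (P_insp·Q_exp − P_exp·Q_insp)/(Q_exp − Q_insp)` — with
opposite-signed flows, a convex combination of the two airway-opening
pressures, so P_dyn always lies in their envelope. Implementation choices
(the source method leaves them open):

* signed flow (expiration negative) keeps the denominator away from zero
  except near phase boundaries; samples with |Q_exp − Q_insp| < 0.02 L/s
  are excluded and filled by linear interpolation in volume, and the
  excluded fraction is reported;
* the isovolume grid is uniform in volume over the range common to both
  limbs (default 100 points), padded 0.5% off the extremes where one
  limb's flow vanishes;
* each limb is made monotone in volume by a running extremum before
  interpolation;
* ΔP_DSA = P_insp − P_dyn is mapped back to the inspiration time base via
  the inspiratory volume–time relation, so it can be integrated over time.

For a single-compartment lung with linear resistance the DSA is exact, and
the test suite verifies ΔP_DSA equals the true model drop away from phase
boundaries. With the quadratic minor loss it is biased; see Limitations.

## Volume integration

Volume is the cumulative trapezoidal integral of flow, with one
refinement: across an interval where flow reverses sign, the pre-reversal
flow is held (left-endpoint rule). A ventilator's phase switch is an
abrupt valve event; interpolating linearly through it at 50 Hz fabricates
a spurious ~0.02 L increment at end-inspiration, enough to bias α by ~2%.
Optional drift correction (on by default) subtracts a linear ramp so the
loop closes; real and re-integrated loops rarely close on their own. When
a waveform file already carries a volume channel it is preserved, never
recomputed, and breath segmentation re-zeroes it per breath — ventilator-
exported volume is the better signal when available.

## Synthetic breath generator

The generator emulates the ventilation pattern of the source cohort:
volume-controlled SIMV with a decreasing inspiratory flow ramp and passive
expiration, over PEEP 5/10/15 cmH₂O and tidal volumes 0.4–0.6 L. The lung
is a single linear elastic compartment in series with the branching tree
at a known true α:

* inspiration: `Q(t)` ramps from `Q_peak` down to `flow_profile · Q_peak`
  (default ratio 0.25), integrating exactly to the tidal volume over the
  inspiratory time; airway pressure is `PEEP + E·V(t) + aQ + bQ²`;
* expiration: the airway opening is held at PEEP and the stored elastic
  pressure drives flow through the same tree — each step solves
  `E·V = a|Q| + b|Q|²` analytically for |Q| and advances V by explicit
  substepping (20 substeps per sample, keeping fast low-resistance trees
  stable without a generic ODE solver);
* optional Gaussian noise on the pressure channel, seeded; identical
  config and seed give bit-identical breaths.

Defaults, chosen once: sampling 50 Hz (typical of ventilator data
exports), inspiratory time 1 s, expiratory time 3 s, elastance 30 cmH₂O/L
(an ARDS-typical stiffness), PEEP 10 cmH₂O, tidal volume 0.5 L. The
generator shares the pressure-drop code with the fitter, so a noiseless
breath at known α is an exact identifiability oracle; a mismatched-K_L
mode exists to probe robustness to the average-loss-coefficient
assumption.

What the generator does **not** emulate: patient effort and asynchrony,
triggering artifacts, leaks, airway-wall compliance, gas compressibility,
heterogeneous (regional) mechanics, and ventilator valve dynamics (phase
transitions are instantaneous). Passing recovery tests therefore
demonstrates identifiability under the model's own assumptions, not
robustness to everything real waveforms contain.

The Monte-Carlo robustness scenario used in the tests is a cohort-typical
patient (true α = 0.58, PEEP 10, 1 cmH₂O pressure noise, 10 breaths,
fixed seeds), asking whether the median fitted α stays within 5% of truth.

## Cohort statistics

The packaged fixture carries the published 10-patient ARDS cohort: α and
AUC per PEEP level (5/10/15 cmH₂O), diagnoses and auto-PEEP. Summary
statistics use type-7 (linear-interpolation) quartiles, stated explicitly
because quartile conventions differ; on the 30 packaged α values this
yields mean 0.58, IQR [0.54, 0.63], range [0.45, 0.66]. Note the published
summary quotes 0.58 as the central value labelled once as a median and
once as a mean; the median of the 30 packaged values is 0.59 under any
standard convention while their mean is 0.58, so both are reported. The
COPD comparison is an unpaired two-sided Wilcoxon rank-sum (Mann–Whitney)
test, midranks with the continuity-corrected normal approximation (exact
enumeration for small untied samples), pooling the three per-PEEP values
of the 5 COPD and 5 non-COPD patients (15 vs 15). A two-sample
Kolmogorov–Smirnov p-value is reported alongside, with the caveat that
values tied at 2-decimal resolution make it convention-dependent.

## Known limitations

* **DSA bias under fast expiration.** With the quadratic minor loss,
  resistance is flow-dependent and the dynostatic equal-resistance
  assumption fails when expiratory flow far exceeds inspiratory flow at
  isovolume; the DSA then overestimates the inspiratory drop and α is
  biased low. For the synthetic generator with ARDS-typical elastance this
  is negligible in the clinically observed range (α ≲ 0.7, recovery
  within ~3%) but grows to ~25% by α = 1.4, where the low-resistance tree
  empties with peak expiratory flows several times the inspiratory flow.
  The bias is a property of the dynostatic method itself, not of sampling:
  it matches a closed-form analysis and is unchanged at 20× the sampling
  rate.
* Per-breath identification assumes a single α for the whole tree and the
  whole breath; heterogeneous or volume-dependent narrowing is absorbed
  into the lumped value.
* The laminar assumption is violated in the ETT/trachea above roughly
  0.2–0.5 L/s (flagged, not corrected), consistent with the source model.
* The clamp bounds [0.45, 1.50] are hard limits; a breath whose implied
  multiplier falls outside is reported at the bound with a flag rather
  than extrapolated.
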