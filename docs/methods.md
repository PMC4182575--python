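# Methods

This note records the models, defaults and design choices behind
`hcscreen`, and what the simulators do and do not emulate.

## Dose model

Viral dose is summarized by the multiplicity of infection,
MOI = (stock titer / dilution) × inoculum volume / cells per well. The
reference condition is a 3×10⁶ PFU/ml stock at 1:10 dilution on 3×10⁴
cells, giving MOI 0.5; the default inoculum volume of 0.05 ml is the value
consistent with those numbers and is configurable. Infection follows the
single-hit Poisson model: the number of infectious units reaching a cell is
Poisson(MOI), so the per-cell infection probability is 1 − e^(−MOI). This
is the standard virology assumption for a monotone, saturating
dose–response; the package makes no claim about multi-hit kinetics or
cell-to-cell spread, which would flatten or steepen the curve.

## Synthetic microscopy

`generate_field` places nuclei uniformly at random with a hard minimum
center separation (default 16 px for radii of 4–7 px, i.e. a sub-confluent
monolayer without touching nuclei) and keeps centers one radius + 2 px off
the border, matching the border-exclusion convention of the segmenter.
Nuclei are radially decaying Gaussian-profile disks (σ = 0.6 r). Infected
cells carry a strong GFP amplitude (mean 2000 over a background of 100);
uninfected cells carry a weak autofluorescence-level amplitude (60), so
that the positivity threshold has a realistic low-signal class on both
sides. Both channels get Gaussian read noise (sd 30) and optionally Poisson
shot noise. At these defaults the nuclear peak-to-noise ratio is ~100:1,
deliberately clean: the fixtures are meant to verify counting logic against
exact truth, not to span the difficulty of real plates. An optional
"touching pairs" mode places partner nuclei at 1.6 × radius to exercise
watershed declumping.

All truth draws (placement, radii, infection flags) happen before any
noise draw, so noise settings can never change the ground truth. Seeds are
counter-based: `SeedSequence([master, plate, well, field])`, so any field
is regenerable in isolation.

Not emulated: illumination gradients, cytoplasm, overlapping-nucleus
clumps beyond pairs, focus drift, real PSFs. Passing tests therefore show
the counting pipeline is correct and well-calibrated on clean, truth-known
inputs — not that it is robust to every artifact of real microscopy.

## Segmentation and classification

The nuclei recipe is the canonical one: Gaussian smooth (σ = 1 px), Otsu
threshold (or a fixed value), hole filling, optional distance-transform
watershed declumping (minimum seed separation 6 px), an area gate
(20–2500 px²) and border exclusion. Because Otsu always splits a histogram,
a contrast guard returns zero nuclei (qc flag `low_contrast`) when the Otsu
threshold clears the image median by fewer than 5 robust (MAD-based) sds —
otherwise a signal-free field would segment its noise. A flat image yields
zero nuclei with flag `flat_image` rather than an exception.

GFP positivity is per-field adaptive: a nucleus (mask expanded by 1 px) is
positive when its mean GFP exceeds background mean + k·sd with k = 5,
background being all pixels outside the expanded masks. With a confluent
mask there is no background and a fixed fallback threshold is used (flag
`no_background`). Per-field adaptivity makes the call robust to
field-to-field illumination shifts; k = 5 places the threshold far above
background noise yet far below the infected-cell signal at default SNR.

A well's efficiency is the unweighted mean of its per-field efficiencies
over fields with at least one cell (the pooled-count ratio is implemented
for comparison but not used); wells with no countable field are invalid,
and fewer than 3 contributing fields flags `few_fields`.

## Screen scoring

Range normalization, pooling and Z scoring are as in the README. Numerical
conventions: medians of even counts are the mean of the central order
statistics; the null sd uses the sample (n−1) estimator by default
(population sd is available); normalized values are never clipped, since
clipping would truncate the Z tails; the hit boundary z ≥ 3 is inclusive
and the cytotoxicity boundary (cell count < 50% of the plate
negative-control median) is strict. Exclusion precedence is invalid well >
cytotoxic > not expressed, and excluded hairpins can never be hits. Plates
need at least two valid controls of each type and a positive-control median
strictly above the negative one; otherwise the whole plate is flagged and
excluded. The pooled null requires ≥ 3 wells and a nonzero sd (a degenerate
null raises rather than silently producing infinite scores).

## Well-level screen simulator

Per well: efficiency = clamp₀₁(baseline × effect × plate offset + noise),
with lognormal plate offsets (σ = 0.1) and additive Gaussian well noise
(sd 0.01 on the efficiency scale). Defaults describe the modeled screen:
161 genes, 827 hairpins (five per gene, 22 genes carry a sixth), 96-well
plates with eight negative and eight positive control wells in the outer
columns, baseline efficiency 7.5% (the 5–10% band under IFN-γ priming),
positive-control effect 3.5-fold, 14 planted positive-regulator genes with
three effective hairpins each at 3.0-fold (the magnitude the screen's own
validated hits show). On the normalized scale the null sd is ≈ 0.053, so
the planted effect sits ≈ 15 null sds up — comfortably detectable, which
is what makes the recovery benchmark a check of pipeline correctness rather
than a marginal-power study. Cytotoxic wells are independent Bernoulli
events (rate 0.02) whose cell counts drop to 10% of normal (counts are
Normal(2000, 100) otherwise). Truth (effects, planted genes, cytotoxic
wells) is separated from measurement: changing noise levels changes
efficiencies, never the truth.

## Null calibration and its limits

A property worth stating precisely: the hit rule's false-positive rate
matches the standard-normal upper tail only when the per-plate control
medians are estimated precisely. With eight controls of each type per
plate, the medians' sampling error both shifts each plate's null by a
noticeable fraction of its sd and deflates the controls' own spread
relative to test wells (controls are centered by their own median); the
pooled null then has heavier-than-normal tails, and the realized hit
fraction at Z = 3 runs roughly 2.5–3× the nominal 0.00135. This is
intrinsic to plug-in range normalization with sparse controls, not an
implementation artifact. The calibration study therefore uses
`null_calibration_design()` — 384-well plates with 96 controls of each
type, no plate offsets, no planted effects — where the plug-in error is
negligible and the measured hit fraction agrees with the normal tail
within Monte-Carlo error. Users scoring real 8-control plates should
expect the nominal tail probability to understate the empirical
false-positive rate by a small constant factor.

Plate offsets add a second caveat: because well noise is additive after
the multiplicative offset, normalization rescales each plate's noise by
its offset, making the pooled null a mild scale mixture. At the default
offset σ = 0.1 the effect on the Z = 3 tail is small compared to the
sparse-control effect above.

## Follow-up assays

Relative expression uses 2^−ΔΔCt with amplification efficiency fixed at 2
(no efficiency correction, none being modeled); technical replicates are
averaged on the Ct scale before ΔΔCt; Ct values are validated to 5–40
cycles. The knockdown–phenotype dose–response uses Spearman rank
correlation (the claim is ordering, not linearity), with a monotonicity
flag at ρ ≥ 0.8. Reporter activity is luminescence / viability rescaled so
the untreated reference is exactly 1.

## Problem sizes and determinism

Tests and the acceptance checks run at desk scale, chosen as the smallest
sizes at which the statistical assertions have comfortable margins: the
distributional checks use 200–250 replicate fields or wells; the null
calibration uses one ~10,000-test-well screen; planted-gene recovery
averages 200 replicate screens of the full 161-gene design; segmentation
fidelity uses 50–200-cell fields and 12 fields per dose for the dilution
series. Everything that consumes randomness takes an explicit seed, and
all statistical tests run derandomized or with fixed seeds.

## Known limitations

- The segmentation defaults are tuned for the synthetic fixtures' SNR;
  real images need per-dataset parameter review (all knobs sit in
  `SegParams`).
- The simulator plants multiplicative effects with additive noise; real
  screens show spatial (edge/row) artifacts, which are deliberately out of
  scope, as are B-score/median-polish corrections and redundancy-weighted
  hit statistics (RSA/RIGER).
- Gene calls are threshold counts, not probabilistic; no FDR control is
  attempted beyond what the Z threshold implies.
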