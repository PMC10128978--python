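# Methods

This note documents the models behind `msipcr`: what the simulator emulates,
how sizing and calling are defined, the defaults that matter, and what the
package's passing tests do and do not establish about real instrument data.

## Mobility model and calibration

Fragment migration follows the classic log-linear mobility approximation:
canonical position `m(s) = M0 + K·ln(s/15)`, with the 15 bp and 1000 bp
alignment markers at fixed canonical positions (100 and 900 on an arbitrary
migration axis of 0–1024, sampled at 0.1). Each lane additionally applies an
affine distortion `m' = α·m + β` (defaults drawn per lane from
α ∈ [0.97, 1.03], β ∈ [−8, 8]) representing run-to-run migration
variability. The two-anchor calibration `size(m) = exp(a + b·m)` is the exact
inverse of this map, so calibrated sizes are invariant under any affine
distortion — both anchors co-distort. This choice makes the anchor-based
design testable: a noise-free lane must round-trip simulated allele sizes
exactly up to interpolation error.

Alignment markers are rendered as crisp bands of fixed migration-domain width
(σ = 2 migration units). This is deliberate: they are co-injected reference
fragments whose apex defines the calibration, and modelling them with the
gel's bp-resolution would make the 15 bp anchor hundreds of samples wide
under the log map, with an apex estimate that degrades the whole lane. PCR
product bands, by contrast, are Gaussian in *size* space with the gel's
σ (bp), composed with the mobility map.

## Electropherogram simulation

Per lane: anchor bands, one Gaussian band per allele (amplitude ∝ relative
template amount, germline amplitude 1000 signal units), a contraction-only
stutter ladder at −1…−3 bp with geometric decay 0.5 (poly-A PCR stutter is
predominantly contraction), additive white Gaussian baseline noise, and a
zero clip. Each lane draws from its own RNG stream keyed by
`(seed, crc32(lane_id))`, so adding lanes to a run never perturbs existing
ones and every output is bit-reproducible for a fixed seed.

Gel models:

| gel        | band σ (bp) | resolvability (2σ) | noise sd |
|------------|-------------|--------------------|----------|
| screening  | 6.0         | 12 bp              | 12       |
| high-res   | 0.75        | 1.5 bp             | 8        |

Resolvability here is the equal-amplitude bimodality threshold (two equal
Gaussians separate iff Δ > 2σ), placing the defaults inside the instrument
classes of ~10–15 bp and ~1–3 bp.

Germline product sizes are laboratory configuration, not assay biology —
every call is relative to the paired normal — so the defaults (NR-27 80,
NR-21 120, BAT-25 160, NR-24 200, BAT-26 245 bp, each in its own disjoint
window) were chosen for geometry: ≥ 38 bp between neighbouring germline
bands so screening-gel tails do not bias neighbouring windows, and ≥ 20 bp
of in-window headroom below each germline size for deleted alleles plus
stutter.

Tumour lanes mix `(1−f)` germline and `f` deleted allele per unstable
marker. Somatic deletion lengths default to discrete-uniform on 11–16 bp
(these loci shift predominantly by more than ten bases; the lower bound is
configurable down to 3 bp for boundary studies). Cohort tumour purity
defaults to uniform on [0.2, 1.0]. Simulated MMR-IHC labels follow the MSI
truth (MLH1+PMS2 or MSH2+MSH6 loss patterns for MSI-H) and can be perturbed
either by Bernoulli rates or by exact counts; the false-loss mode is an
isolated MSH6 loss, the discordance pattern actually seen between MSI-PCR
and IHC (MSH6 repairs base–base mismatches more than indel loops, so its
loss need not produce marker shifts).

## Peak detection and width convention

Peaks are local maxima of a lightly smoothed signal (Gaussian, σ = 2
samples) above a prominence of 5% of the lane maximum, with a minimum
separation of one gel σ (bp-equivalent). Apexes are refined to sub-sample
precision by a parabola through three log-signal points — exact for Gaussian
bands, which is what makes the ≤ 0.1 bp round-trip achievable on a 0.1-unit
grid.

`width_bp` is the *sigma-equivalent* width from the second central moment of
the band's support (the contiguous region above 8% of the apex, bounded
midway toward neighbouring peaks, bias-corrected for the truncation). A
clean band therefore measures ≈ σ. The moment estimator was chosen over a
half-maximum width because a low-fraction deleted allele merged into the
germline band sits below half height: FWHM is blind to it, while the second
moment grows with any unresolved satellite mass — exactly the signal the
smear trigger needs.

Shoulder detection (anchor QC) uses the derivative-inflection
operationalization: on a clean flank the first derivative is unimodal; a
shoulder is an interior derivative extremum that does not reach zero,
required to clear both 5% of the peak's own maximum slope and 9× the lane's
derivative-noise floor (estimated from the smoothing residual on band flanks
and propagated analytically through the smoothing and differencing kernels).
Two notes follow from the analytics. First, a mixture of two *equal*
Gaussians has exactly two inflection points at any sub-bimodal separation,
so equal mixtures never produce a derivative shoulder — shoulders require
amplitude asymmetry (roughly, satellites of 0.3–0.5 relative amplitude at
2–2.8 σ). Second, under heavy noise the detector is deliberately
conservative: for lane QC a false "shoulder" verdict (which voids the lane)
is worse than a missed one.

## Marker calling

- Major band: highest amplitude in the marker window, ties toward the
  smaller size. Sizes are rounded to integer bp before shift comparison,
  mirroring integer gel readouts; shift threshold is ≥ 3 bp, sign-agnostic
  by default (configurable to deletion-only).
- New minor bands: tumour peaks ≥ 10% of the tumour major whose rounded
  size matches no normal-lane band within ±1 bp (high-res) / ±3 bp
  (screening). The germline stutter ladder is identical in both lanes and
  therefore never counts as new.
- Smear (inconclusive): the tumour major is wider than 1.25× the gel's
  *nominal band width* — the analytic σ-equivalent of a clean
  stutter-broadened band, `sqrt(σ² + Var(stutter))` — or no dominant band
  stands out among peaks *overlapping* the major (second amplitude > 0.6×
  major within 2× width). Overlap-scoping matters: two well-separated
  near-equal bands are a resolved two-allele pattern, i.e. evidence of
  instability, not a smear. The width ratio of 1.25 sits between the ≈ 1.0
  (±4%) measured on clean simulated lanes and the ≥ 1.4 of unresolved
  tumour mixtures at fractions ≥ 0.2; a threshold of 2× nominal width would
  never fire for ≤ 16 bp deletions (maximum inflation
  `sqrt(1 + f(1−f)d²/σ²)` ≈ 1.6) and would disable escalation entirely.
- Classification needs ≥ 4 conclusive markers (PCR dropout excludes a
  marker without counting it unstable); otherwise the case is Indeterminate.
  Any marker still smeared after the high-resolution tier also leaves the
  case Indeterminate — no status is forced.

## LOD

The LOD is a series-membership value: the smallest titration fraction with
an unbroken run of unstable calls from 100% tumour downward; non-monotone
flag sequences are reported as such and read on the unstable prefix. An
inconclusive (smeared) marker at a fraction counts as not-detected on that
gel: the LOD measures unambiguous single-gel detection. Replicated series
are summarized by the modal flag per fraction. On the synthetic screening
gel, low-fraction mixtures with 11–16 bp deletions present as merged smears
rather than clean minor bands, so the simulated screening LOD is pessimistic
(often only the pure-tumour point); the high-resolution LOD lands near 10%
(limited by the 10% minor-band threshold, since a fraction f yields a minor
band of relative amplitude f/(1−f)). The tested property is the ordering —
high-resolution LOD ≤ screening LOD per marker — not the absolute values,
which on the real instrument depend on chemistry the simulator does not
model.

## Statistics

Concordance is the diagonal fraction of the (MSI-H vs MSS+MSI-L) ×
(IHC Loss vs Preserved) table, reported to one decimal. Fisher's exact test
(two-sided, significance p < 0.001) uses the standard conditional
hypergeometric definition — the sum of probabilities of tables no more
probable than the one observed — and is verified in the test suite against
an independent exhaustive enumeration on every 2×2 table with n ≤ 40. For
2×k covariates the Freeman–Halton extension enumerates tables with fixed
margins exactly up to a configurable limit and switches to a seeded
Monte-Carlo estimate of the same tail above it. Cohort tables report
percentages under both denominator conventions — the full MSI column
(printed-table style) and the known-status subset (in-text style) — because
published tables mix the two.

Percentages round half-up to one decimal, with one deliberate exception:
the screening-tier resolution rate in run summaries is rounded *down*
(truncated), so the stated share of cases resolved without escalation is
never an overstatement.

## Problem sizes and reproducibility

The simulation-based checks run at sizes chosen to estimate their quantities
stably: 200-case cohorts for status recovery (≥ 95% required at tumour
fraction ≥ 0.2 with default noise; 100% required at fraction 1.0 without
noise), 60-case noise-free cohorts for the exactness check, and 21
replicated titrations per gel for modal LODs. All randomness descends from a
single seed via per-lane hashed streams; re-running any entry point with the
same configuration reproduces every output byte-for-byte.

## Known limitations

- No PCR chemistry, fluorescence physics, or electro-osmotic drift beyond
  the per-lane affine distortion; anchors are ideal reference bands.
- Stutter is contraction-only with geometric decay; real poly-A stutter has
  a small addition-side component and length-dependent decay.
- The ≤ 0.1 bp sizing round-trip guarantee applies to isolated
  single-allele bands: an unresolved stutter ladder pulls a merged apex a
  few tenths of a bp toward smaller sizes. The pull is identical in tumour
  and normal lanes, so shift calls are unaffected.
- The smear criterion is this package's operationalization of a visual
  judgement; laboratories differ.
- Unpaired (tumour-only) calling is out of scope by design — the decision
  rule is defined against the matched normal.
- Passing the simulation-based tests shows the decision logic is correct
  under the stated noise model; it does not validate performance on FFPE
  artefacts, allele dropout, or instrument-specific baseline behaviour.
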