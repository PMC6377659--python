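# Methods

This package analyses A-to-I RNA-editing isoforms of the PDE8A intron-9
editing island as measured by capillary-electrophoresis single-strand
conformation polymorphism (CE-SSCP).  It covers the full chain: a
forward model of the measurement (synthetic data with known truth),
inversion of that measurement (trace quantification), differential
statistics over a paired two-group, two-region brain cohort, and an
AUC-maximising marker combination for group discrimination.

## Domain model

Nine island sites are catalogued: A–G (previously described in T cells)
plus the two novel brain sites M and N.  B (Chr15:85096687), M
(Chr15:85096753) and N (Chr15:85096771) carry published GRCh38
coordinates; the coordinates stored for A and C–G are representative
positions inside the 175-bp amplicon, chosen only to order the sites —
no analysis depends on them.  An isoform is the combination of edited
sites on one molecule, named by concatenating site labels in canonical
order (`NE` for the unedited molecule).  The per-sample observable is
the relative proportion of each isoform in the total analytical signal,
in percent, summing to 100.

Site-combination regularities (A observed only together with B; N only
together with A and B) are enforced in the default catalogue but treated
as *warnings* during validation of arbitrary profiles: they are
empirical observations about brain PDE8A editing, not logical
constraints, and synthetic or edge-case inputs may legitimately violate
them.

## Synthetic cohorts

`synth.simulate_cohort` draws profiles for a paired design: 2 groups
(control, suicide) × 2 regions (BA9, BA24) × `n_pairs` subjects
(default 8, the study size).  Because profiles are compositions, draws
are Dirichlet with concentration `dispersion × mean/100` around a
stratum mean vector.  Defaults:

| parameter | default | rationale |
|---|---|---|
| `n_pairs` | 8 | study design (8 matched case-control pairs) |
| `dispersion` | 500 | CV ≈ 9 % for the most abundant isoform (~29 %), 25–30 % for 1–3 % isoforms; consistent with the tight standard errors of a well-controlled CE assay |
| `subject_effect_sd` | 0.10 | log-scale SD of a per-subject multiplicative effect shared by both regions; induces the within-subject correlation a paired design assumes |

The default stratum-mean table has 30 isoforms (27 carrying site B; only
B, D and M occur as single-site isoforms; A only with B; N only inside
ABN), with B ≈ 29 % in control BA24 vs 21.5 % in BA9, NE stable at 6 %,
AB ≈ 2.6-fold enriched in BA24 over BA9, ABCEF doubled and B/ABDE
reduced in suicide BA24, ABEFG ≈ 3-fold increased in suicide BA9, and
ten rare isoforms below the 0.5 % reporting floor carrying < 2 %
cumulative mass.  Exact per-stratum values are code defaults
(`synth.DEFAULT_MEANS`), normalised to sum to 100; they are meant as a
realistic emulation of the measured profiles, not as assertions about
any particular cohort.

What the generator does *not* emulate: PCR amplification bias, dye
spectral overlap, co-migrating conformers, heavy-tailed outliers, or
missing samples.  Tests passing on this generator therefore demonstrate
correctness of the analysis chain under its stated error model, not
robustness to every artefact of real capillary data.

## Trace forward model and quantification

A trace set is three 11,000-point channels.  FAM and VIC observe
`Σᵢ pᵢ·gᵢ(warp(scan))`, where `gᵢ` is a unit-area Gaussian at isoform
*i*'s retention time (width 15 scan units; retention times 250 units
apart), so each isoform's peak area on the unified time axis equals its
proportion in percent.  Gaussian shape is a modelling choice — any
unimodal kernel would do; Gaussians keep areas analytic.  ROX carries
the 16-peak migration ladder through the same warp.  The warp is
monotone piecewise linear (3–5 anchors in practice), emulating
run-to-run migration drift; baseline drift is a slow sinusoid and noise
is additive white Gaussian.

Quantification inverts this model in five steps:

1. **Time basis** — ladder peaks are picked by prominence in ROX,
   matched in elution order to the expected ladder positions, and the
   monotone piecewise-linear interpolant through the matched anchors
   maps raw scan index to unified time (linear extension with the
   end-segment slopes outside the anchors).  Fewer than three usable
   peaks, or a non-monotone match, is an alignment error.
2. **Standards calibration** — each editing standard is aligned through
   its own ladder, baseline-subtracted, and scaled to unit area;
   standards closer than a configurable minimum retention separation
   are rejected as indistinguishable.
3. **Retention times** — apex positions of the calibrated references.
4. **Detection** — matched filter per isoform: `⟨y, r⟩/‖r‖` exceeds
   `detection_snr` (default 5) noise units, with noise estimated by the
   median absolute deviation of the aligned trace.  The matched filter
   integrates over the whole peak support, so components well below the
   apex-height noise floor but above the 0.5 % reporting floor are
   still detected.  Detection produces a candidate superset; final
   calls come from the fit plus the reporting floor.
5. **Best fitting** — non-negative least squares of the stacked
   FAM+VIC system against the candidate references (NE always kept as
   a candidate).  Weights are converted to percent of fitted signal;
   isoforms below the 0.5 % floor are removed (mass recorded) and the
   survivors renormalised to 100.  The floor is applied per sample; the
   analysis-level inclusion rule is separate (below).

Baseline removal is a smoothed rolling-minimum filter (pre-smooth 51
points, minimum over 501 points, re-smoothed), recentred on the median
of the residual so the noise floor sits at zero.  The 501-point window
exceeds the peak support, so minima fall between peaks; on noise-free
input the subtracted baseline is numerically negligible and NNLS then
inverts the forward model to ~1e-10 percentage points.

Numerical behaviour, measured by the test suite: noise-free
identity-warp recovery is exact to well below 1e-6 points; at noise of
2 % of the tallest peak with warp and baseline drift, six-component
mixtures are recovered with maximum error below 1 percentage point over
100 seeds; proportions are invariant to positive rescaling of the
signal channels, and warped samples agree with unwarped ones within
0.5 points.

## Differential statistics

For a contrast of two conditions (BA24 vs BA9 within a group, or
suicide vs control within a region), the per-isoform effect summary is
the set of deviations `Δ = %editing(cond 2) − %editing(cond 1)` over
all condition-2 × condition-1 sample pairs (64 for 8 vs 8), plus the
median variation `100 × (median₂ − median₁)/median₁`.

Isoform inclusion: an isoform enters a contrast family when its mean
proportion reaches 0.5 % in at least one group × region stratum.  This
reconciles the per-sample quantification floor with an analysis-wide
family of ~20 isoforms under the default generator.

**Choice of test.**  The hypothesis of interest is that the deviations
are centred at zero.  The package's default test is the exact
Wilcoxon–Mann–Whitney rank-sum test on the two condition samples: its
statistic is precisely the sign count of the cross-condition
deviations, and its null distribution is exact, so p-values are
calibrated.  A one-sample Wilcoxon signed-rank test on per-pair
deviations along the design pairing is exposed as an alternative
(`test="signed-rank"`), but note two caveats that make it unsuitable as
the default here: with 8 pairs its smallest attainable two-sided p is
2/2⁸ ≈ 0.0078, which after a Benjamini–Hochberg adjustment over ~20
isoforms cannot reach q ≤ 0.05; and applying a one-sample test to all
64 cross pairs instead would treat strongly dependent deviations as
independent and be badly anti-conservative.  The rank-sum default keeps
the deviation-centred-at-zero interpretation while remaining exact and
calibrated at the study's sample size.

Multiplicity: Benjamini–Hochberg across the included isoforms of one
contrast (one family per contrast panel).  Selection requires q ≤ 0.05
*and* |median variation| ≥ 20 %; both thresholds are configuration
constants.  Zeros are dropped before signed-rank ranking; ties are
mid-ranked; exact null distributions are used whenever tie-free sample
sizes permit (n ≤ 25 one-sample, combined n ≤ 20 two-sample).
Degenerate cases: all-zero deviations give p = 1; a zero baseline
median yields an undefined (infinite, sign-carrying) median variation
in contrast output and an explicit error from the standalone function.

Under the defaults, the null false-selection rate measured over 500
replicate null cohorts is ≈ 0.03 isoforms per ~20-isoform contrast, and
a programmed two-fold increase of a ~3 % isoform is selected in ≈ 92 %
of 200 replicates.

## mROC marker combination

The combined marker is `Z = a·Iso₁ + b·Iso₂ + c·Iso₃ (+ …)` with
coefficients maximising the empirical AUC (Mann–Whitney concordance;
ties count one half).  Because the empirical AUC is piecewise constant
in the coefficients, the optimiser is a deterministic multi-start
search on standardised markers — signed axis directions, standardised
class-mean difference, a regularised Fisher-discriminant direction, and
a coarse direction grid (72 angles for k = 2, a 200-point spherical
Fibonacci grid for k = 3, a fixed-seed direction set for k = 4–5) —
with Nelder–Mead refinement of the top candidates and ties broken
toward the earliest candidate.  Including the axis directions
guarantees the fitted panel never scores below its best single marker;
standardising before the search makes the achieved AUC invariant to
marker rescaling.  Coefficients are reported with unit Euclidean norm,
oriented so that higher Z indicates the case group (a sign-flip would
map AUC to 1 − AUC, so no further sign canonicalisation is applied).
Constant marker columns are dropped with a warning; panels are capped
at five markers (the study used three).

On default synthetic cohorts the BA24 panel (ABC + BCEG + ABDE)
typically reaches AUC = 1; the BA9 panel (BD + BCEG + ABF) reaches
0.73–1.0 depending on the realisation, reflecting the more moderate
BA9 effect sizes in the default means.

## Reproducibility

All randomness flows from explicit seeds; `pipeline.run_pipeline`
derives deterministic per-stage seeds from a single run seed via
SHA-256, writes every intermediate table, and records config, seed,
version and per-stage counts in `manifest.json`.  Rerunning a config
reproduces byte-identical CSVs.  Simulation sizes used by the test
suite and the acceptance script (100 quantification seeds, 500 null and
200 power replicates) were chosen so the full suite runs in well under
a minute while keeping Monte-Carlo error far from the asserted margins.

## Known limitations

* The generator's error model is additive Gaussian with a smooth
  baseline; real capillary artefacts (spikes, saturation, dye pull-up)
  are out of scope.
* "Deconvolution" of co-migrating single-standard conformers reduces to
  area normalisation for single-peak synthetic standards; separating
  true co-migrating conformers is not implemented.
* The exact published mROC algorithm (stepwise marker entry) is not
  reproduced; equivalence is at the level of achieved AUC, not
  coefficient values.
* Demographic/confounder testing on subject covariates is out of scope;
  the cohort generator produces no covariates.
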