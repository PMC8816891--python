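# Methods

## The analysis chain

The package analyzes antagonist screens built on a membrane-potential dye
readout: cells expressing one nAChR subtype are depolarized by an EC₉₀
agonist concentration, and an antagonist reduces the evoked fluorescence
increase. Each well is read twice — a baseline read before compound
addition and a final read after — and the analyzed quantity is the net
signal, net = final − baseline.

Per plate, net signals are rescaled to the normalized fluorescent signal

    NFS_w = (net_w − μ₀) / (μ₊ − μ₀),

where μ₀ and μ₊ are the means of the DMSO-only (zero-signal) and
EC₉₀-agonist (positive-signal) in-plate controls after robust outlier
removal. This anchoring is exact by construction: the retained-control NFS
means are 0 and 1 to floating-point tolerance, and NFS is invariant under
any affine transform of the raw fluorescence (gain and offset changes of
the reader cancel). Percent inhibition is 100·(1 − NFS).

Hit selection uses the empirical NFS distribution of all test wells in a
run, pooled across that run's QC-passing plates: the threshold is
mean − 3·SD (sample SD, n−1), and a well is a hit when its NFS is strictly
below it. A compound is a *confirmed* hit when it is a hit in every run of
a duplicate screen. Three rates summarize a campaign: the primary hit rate
(unique hits in either run / evaluable compounds), the adjusted hit rate
(both-run hits / evaluable), and % data passed QC (evaluable / library
size). Compounds sitting on any QC-failing or non-normalizable plate in
either run are excluded from the evaluable denominator — the exclusion
mechanism is a package convention, since campaign reports list evaluable
counts without stating one.

A consequence of the mean − 3·SD rule worth knowing: the threshold adapts
to the screen's own active content. Planted actives inflate the pooled SD
and pull the threshold down, so compounds at ~50% inhibition are borderline
in small or active-rich screens and confirm stochastically. This is a
property of the rule, not of the implementation.

## Quality control

Three gate statistics are computed per plate from the outlier-filtered,
background-subtracted controls:

- CV = sample SD / mean (per control class),
- S:B = μ₊ / μ₀,
- Z′ = 1 − 3(σ₊ + σ₀)/|μ₊ − μ₀|.

Defaults gates — CV < 0.10, S:B > 4, Z′ > 0.5, all strict — follow standard
HTS assay-quality guidelines; all are configurable (`QCThresholds`). Z′ is
affine-invariant and strictly decreasing in each control SD; CV is
scale-invariant; the gate is monotone (improving any metric never flips a
pass into a fail).

Control outliers are removed by the median ± k·1.4826·MAD rule with k = 3,
capped at 25% of points. A MAD rule was chosen because control counts are
small (n = 12) and a single pipetting failure should not move the anchors;
the cap bounds worst-case removal. Positional bias is reported per row and
column as (group mean − grand mean)/grand SD of test-well NFS, flagging
|bias| > 3 — a striping diagnostic, not a correction: edge wells (within 2
rows/columns of the border) are excluded outright rather than modeled, and
no spatial smoothing (B-score/LOESS) is applied.

## Concentration–response model

Agonist and antagonist curves use the four-parameter logistic on log₁₀
concentration,

    y = bottom + (top − bottom) / (1 + 10^(±h·(log₁₀x₅₀ − log₁₀x))),

with the sign choosing rising (agonist; x₅₀ = EC₅₀) or declining
(antagonist; x₅₀ = IC₅₀) orientation, and h constrained positive so the
direction is carried by the orientation, never by a sign-ambiguous slope.
Fitting is unweighted nonlinear least squares (scipy `curve_fit`) with
deterministic initialization from the data: asymptotes from the response
extremes, x₅₀ from the concentration nearest half-maximum, h = 1. The same
data therefore always produce the same fit; no global optimizer or random
restarts. Degenerate inputs (constant response, failed convergence) return
a flagged fit rather than raising, so batch pipelines can log and skip.
`se_ec50` is a delta-method standard error propagated from the fitted
log₁₀x₅₀. EC₉₀ = EC₅₀·9^(1/h) (the concentration giving 90% of the fitted
span) anchors antagonist screens; EC₉₀/EC₅₀ = 9^(1/h) holds identically.

## Orthogonal efflux analytics

The ⁸⁶Rb⁺-efflux assay measures ion flux through the channel directly, so
it arbitrates whether a fluorescence hit is channel-mediated. Each plate
carries triplicate total-efflux controls (agonist only), triplicate
non-specific controls (fully blocked or buffer alone — the two definitions
are equivalent and collapse to one role), and triplicate test wells per
compound. Specific efflux = mean(total) − mean(nonspecific), required
positive; % inhibition = 100·(mean(total) − mean(test))/specific, not
clipped to [0, 100]. A compound validates when its mean inhibition across
the three independent experiments strictly exceeds 3× the spread of no-drug
control inhibition; the spread is the pooled SD over all total-control
wells, each treated as a test well (per-experiment SDs from triplicates
would be too noisy to set a cutoff). Efflux-assay Z′ uses the same formula
as plate QC on the two control sets; with triplicate controls the per-plate
Z′ estimate is noisy, so assay-level judgments should use its mean across
plates.

## Selectivity classification

Per-compound validated flags across the three subtypes map to groups via a
total truth table: the six named groups (α3β4-only, α4β2-only,
α6/3β2β3-only, both-β2, all-three, not-validated) plus explicit
α3β4+α4β2 and α3β4+α6/3β2β3 groups for the two patterns outside the named
six — the classifier must cover all 2³ combinations even though those
mixed patterns are rare in practice (β2-containing subtypes share
pharmacology; cross-activity with α3β4 alone is uncommon). Efficacy bins
use strict comparisons: > 75% is "highly efficacious", ≤ 50% the
low-efficacy class; a compound's efficacy is its largest mean inhibition
over the subtypes where it validated.

## Synthetic data generator

The generator is phenomenological at the well level — it emulates what a
plate reader records, not dye kinetics or channel gating. Expected net
signal is affine in true fractional inhibition I:

    net = floor + (ceiling − floor)·(1 − I),
    I   = efficacy_ceiling / (1 + (IC₅₀/c)^h)   (antagonists at conc c).

Defaults (the study conditions, fixed once):

- **Geometry**: 384-well plates, 2-well edge band excluded, 12 zero + 12
  positive controls (columns 3–4 of the interior), a 12-point 3-fold
  reference-antagonist titration from 100 μM (column 5; reference IC₅₀s
  1.91/0.54/1.67 μM for α3β4/α4β2/α6/3β2β3, Hill 1), 204 test wells; a
  2,298-compound library splits into 12 plates per run, 24 plates per
  duplicate campaign per subtype.
- **Assay contexts**: EC₉₀ agonist 20 μM (α3β4) or 500 nM (β2 subtypes);
  signal floor 50 AU with per-subtype ceilings chosen so expected net S:B
  matches each assay's characteristic value (~148/61/64).
- **Noise**: multiplicative Gaussian per well, CV-parameterized
  (`well_cv`, default 0.06 — mid-range of observed per-plate control CVs
  (0.024–0.10) and yielding expected plate Z′ ≈ 0.8, matching the
  per-assay averages). Noise scales with the well's own signal, matching
  how control CVs are reported. Log-normal plate-to-plate drift
  (`plate_scale_sd` = 0.08) multiplies whole plates and cancels under
  in-plate normalization. The baseline read is an independent draw at 10%
  of the floor with the same CV — the baseline distribution is a declared
  convention, since only its subtraction, not its shape, is documented for
  real campaigns. An optional multiplicative edge artifact (`edge_bias`,
  default off) distorts border wells only; the magnitude of real edge
  effects is unreported, which is why the layout excludes those wells.
- **Screening concentration**: 10 μM when converting IC₅₀ to planted
  inhibition.
- **Efflux**: 24-well plates, 6 compounds per plate, triplicate everything;
  non-specific 500 cpm, specific 3,000 cpm, same CV model. Expected efflux
  Z′ ≈ 0.76, inside the 0.75–0.88 band typical of the assay.

The planted library (`default_truth_library`) mirrors a realistic campaign
composition: selectivity groups of sizes 26/6/5/20/10/15 (α3β4-only /
α4β2-only / α6-only / both-β2 / all-three / not-validated) among 2,298
compounds, the rest inactive. Planted classes are specified by *measured
inhibition at 10 μM* — high > 75% (planted 80–93%), the two non-high
α3β4-selectives moderate (55–70%), β2-group compounds ≤ 50% (planted
46–50%) — with each compound's efficacy ceiling back-computed from its
IC₅₀ (log-uniform 0.2–1 μM) so the screen sees the planted value. For
multi-subtype antagonists the shared ceiling is scaled from the worst-case
IC₅₀, so inhibition at the other subtypes can exceed the target by up to
~8%. "Not validated" compounds are fluorescence artifacts: an
`artifact_inhibition` of 75–90% acts on the dye readout only, with zero
channel inhibition, so they confirm as primary hits and are rejected by the
efflux stage — the triage the orthogonal assay exists to perform.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: dye-loading kinetics and signal drift within
a read; spatially correlated noise beyond a uniform edge factor (real
striping has structure); compound-specific artifacts other than a flat
fluorescence offset (quenchers with partial channel activity,
autofluorescence that *raises* signal); plate-to-plate correlation between
duplicate runs (runs are independent here, making duplicate confirmation
slightly conservative); and resupply failures between screen and
validation. Pipeline performance on simulated campaigns (sensitivity ≈ 1,
false-call rate ≈ 0 at these noise levels) is an internal-consistency
check, not a claim about any particular wet-lab campaign.

## Numerical conventions

Sample (n−1) SDs throughout — control groups are small (n = 12). Strict
inequalities at every decision boundary: the QC gates, the hit threshold
("lower than"), the 3×SD validation rule, the >75% efficacy bin. Negative
net signals are kept and flagged, never clipped. Rates are reported at
campaign precision: adjusted hit rate to 3 decimals, other percentages to
2; cross-assay means at 1 decimal (hit rate) and integer (validation rate).
NFS is a fraction internally; percent only at reporting. CSV I/O uses
round-trip float parsing so write→read is bit-exact. All stochastic
components draw from a single seeded generator; identical inputs and seed
give bit-identical outputs.

## Known limitations

- The evaluable-compound exclusion model (whole-plate exclusion in either
  run) is one of several defensible conventions; real campaigns may exclude
  at the well level.
- The 3×SD validation cutoff pools the control spread across experiments;
  a per-experiment cutoff would be noisier but is equally defensible.
- The 4PL fitter reports delta-method SEs, not profile-likelihood or
  resampled intervals; for publication-grade confidence bands, bootstrap
  the replicates.
- Mixed α3β4+single-β2 selectivity patterns get explicit group labels but
  no special downstream treatment.
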