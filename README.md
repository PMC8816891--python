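# nachr-hts

Analytics for high-throughput, cell-based antagonist screens of nicotinic
acetylcholine receptor (nAChR) subtypes — the α3β4, α4β2 and α6/3β2β3
receptors implicated in nicotine dependence. The package implements the
complete analysis chain of a membrane-potential-dye screening campaign:

- **Plate QC** — coefficient of variation of in-plate controls, signal-to-
  background ratio S:B = μ₊/μ₀, and the Z′-factor
  Z′ = 1 − 3(σ₊ + σ₀)/|μ₊ − μ₀|, gated at CV < 10%, S:B > 4, Z′ > 0.5
  (strict), with median/MAD control-outlier removal and row/column
  striping diagnostics.
- **Control-anchored normalization** — per well,
  NFS = (net − μ₀)/(μ₊ − μ₀), where net = final − baseline fluorescence and
  the anchors are the outlier-filtered DMSO (zero) and EC₉₀-agonist
  (positive) control means; % inhibition = 100·(1 − NFS).
- **Hit calling** — per-run threshold mean − 3·SD over all test-well NFS of
  QC-passing plates; a hit has NFS strictly below it; a *confirmed* hit is
  a hit in both duplicate runs. Rates: primary = unique hits/evaluable,
  adjusted = both-run hits/evaluable.
- **Concentration–response fitting** — four-parameter logistic
  y = bottom + (top − bottom)/(1 + (x₅₀/x)^h) on log-concentration
  (declining orientation for antagonists), EC₉₀ = EC₅₀·9^(1/h), and IC₅₀
  averaging across repeated fits.
- **Orthogonal validation** — ⁸⁶Rb⁺-efflux analytics: specific efflux
  (total − non-specific control means), % inhibition on the control window,
  and the validation rule mean inhibition > 3×SD of the no-drug controls.
- **Selectivity profiling** — integration of per-subtype validated flags
  into named selectivity groups (α3β4-only, α4β2-only, α6/3β2β3-only, both
  β2 subtypes, all three, not validated) with Venn overlap counts and
  efficacy summaries (>75% / ≤50% inhibition bins).
- **Synthetic screen generator** — a seeded, phenomenological well-level
  simulator (4PL compound effects, CV-parameterized multiplicative noise,
  log-normal plate drift, optional edge artifact, fluorescence-artifact
  compounds) that produces complete campaigns with known ground truth for
  validating the pipeline end to end.

Intended users: screening scientists and computational chemists who need a
reproducible, scriptable alternative to spreadsheet/Spotfire-style HTS
analysis, and method developers who want a ground-truthed simulator to
stress-test hit-calling rules.

## Worked example

`examples/03_screen_pipeline.py` simulates a duplicate-run screen of 204
compounds with seven planted actives and runs the full pipeline:

```
plates passing QC: 2/2
  hit threshold R1 (mean - 3 SD of test-well NFS): 0.525
  hit threshold R2 (mean - 3 SD of test-well NFS): 0.545
evaluable compounds:    204/204
unique hits (either run): 7
confirmed hits (both runs): 5
run-to-run concordance R^2 (test compounds): 0.683
primary hit rate:  3.43%
adjusted hit rate: 2.451%
confirmed hits and their planted truth:
  CMP0018: planted as ALL_THREE
  CMP0037: planted as NOT_VALIDATED
  ...
```

Reading the numbers: both plates clear the QC gate; the per-run hit
thresholds sit ~3 pooled SDs below the inactive NFS cluster at 1.0; all
seven planted actives surface as unique hits and five confirm in both runs
(the borderline ones are ~50%-inhibition antagonists near the cutoff).
The two `NOT_VALIDATED` confirmed hits are planted fluorescence artifacts —
compounds that depress the dye signal without touching the channel — which
the orthogonal efflux stage (`examples/04_validation_selectivity.py`)
correctly rejects while recovering the planted selectivity groups
26/6/5/20/10/15 exactly.

The other examples cover plate QC in isolation (`01_plate_qc.py`) and
agonist/antagonist 4PL fitting with EC₉₀ derivation (`02_dose_response.py`).

A thin CLI mirrors the stages:
`nachr-hts simulate|qc|call-hits|fit-dr|validate|classify|report --help`.

## Layout

```
src/nachr_hts/
  plates.py        plate geometry, layouts, manifests, CSV I/O
  simulate.py      seeded synthetic screens, efflux experiments, dose-response data
  qc.py            CV / S:B / Z', outlier removal, positional bias, QC gate
  screen.py        background subtraction, NFS normalization, hit calling, rates
  doseresponse.py  4PL fitting, EC90, IC50 averaging
  efflux.py        specific efflux, % inhibition, 3xSD validation, efflux Z'
  selectivity.py   selectivity groups, Venn counts, efficacy summaries
  pipeline.py      end-to-end orchestration and summary tables
  cli.py           thin command-line layer
```

See `docs/methods.md` for the model, parameter choices and limitations.
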