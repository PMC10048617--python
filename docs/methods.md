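# Methods

`dscspg` implements a validation pipeline for probabilistic genotyping of
single- and few-cell STR subsamples: a synthetic electropherogram (EPG)
generator that reproduces the stochastic pathologies of 1–5-cell direct
amplification, estimators for the five calibration quantities a
probabilistic-genotyping workflow needs, two likelihood-ratio engines with
replicate support, and the validation experiment designs built on them.
This note records the models, the defaults and why they were chosen, and
what the synthetic studies do and do not demonstrate.

## The synthetic few-cell EPG generator

The generator emulates a 32-cycle direct amplification of 1–5 buccal cells
typed on a GlobalFiler-style 21-autosomal-locus panel and read on a
3500-class analyzer.

**Peak-height law.** Each allele copy of a donor contributing `c` cells
yields a height drawn from a gamma distribution with shape `c / cv_peak²`
and mean `c · mean_height_per_cell · m`, where `m` collects a per-locus
log-normal amplification-efficiency factor (LSAE, sd `lsae_sd`), a
size-dependent degradation decay `δ^((size − size_ref)/100)` and any
per-locus inhibition multiplier. Shared alleles sum their contributions.
A gamma law was chosen over a log-normal because at single-cell template it
places realistic mass near zero: alleles whose realized height falls below
the minimum dye analytical threshold are simply never called, so **drop-out
is emergent**, not an independent coin flip, and drop-out co-occurs with
extreme heterozygote imbalance exactly as low-template data show.
`cv_peak` is the coefficient of variation of a single-copy single-cell
peak; the CV shrinks as `1/√c`.

Defaults: `mean_height_per_cell = 3000` RFU and `cv_peak = 2.4`. These were
set so that one-cell subsamples recover roughly 55–60% of a donor's alleles
(about 25 of 42) with frequent extreme imbalance, two-cell subsamples about
88%, and five-cell subsamples are nearly complete — the allele-recovery
regime few-cell validation studies report. `lsae_sd = 0.25` makes per-locus
efficiency vary by roughly ±50% (2 sd), visible as the inter-locus height
trends such data show.

**Stutter.** Stutter peaks are generated for every modelled type (back,
forward, double-back, half-back, half-forward, −1.5-repeat) at the
model-predicted stutter ratio plus truncated-Gaussian noise
(`stutter_sr_sd`, default 0.02), applied to the realized parent height.
Fractional-repeat positions follow the genotyping convention that the
fractional designation counts basepairs (a −2 bp position below allele 16
is 15.2). Maximum allowable stutter ratios default to the elevated values
appropriate for few-cell work: 0.7 (back), 0.7 (forward), 0.3
(double-back), 0.5 (half-back), 0.15 (half-forward), 0.15 (−1.5 repeat).

**Drop-in.** Per locus and sample, a spurious allele appears with
probability `drop_in_rate` (default 0.0164, the calibrated few-cell rate).
Heights follow a shifted exponential (scale 400 RFU) or a uniform law,
capped at `drop_in_cap` (default 5000 RFU, the smallest round thousand
above the largest drop-in such workflows observe).

**Saturation.** All heights are clipped at `saturation` (default 30,000
RFU), the detector ceiling; stutter is computed from the *unclipped* parent
height, which is what makes saturation detectable downstream.

**Negative controls** summarize a per-dye baseline trace (Gaussian noise,
`baseline_sd` default 4 RFU over 200 trace points — chosen so the derived
analytical thresholds land in the tens of RFU) plus any drop-in peaks.

**Perturbations** reproduce the standard artificial insults: degradation
(heights ×0.20 above a 220 bp split, ×0.95 below), inhibition (×0.60 at
D22S1045, D21S11, D13S317 and D2S1338) and a 15,000-RFU drop-in allele
(default allele 8 at D5S818; the nearest absent allele is used when the
donor carries an 8).

**What the generator does not emulate:** per-cycle PCR branching
chemistry, pull-up and spectral artifacts, off-ladder peaks, inter-run
instrument drift, and real population substructure (reference profiles are
drawn under Hardy–Weinberg from the supplied frequency table). Passing
tests therefore demonstrate internal consistency of the pipeline under a
realistic stochastic model, not performance on any physical instrument.

## Calibration estimators

* **Analytical threshold**, per dye: `AT = 2 × (max highest peak − min
  lowest trough)` over a set of negative-control injections. Peaks exactly
  at the threshold are retained downstream (≥ comparison).
* **Stutter regressions.** For single-source subsamples with known
  genotypes, SR = stutter height / parent height is scored per locus and
  type wherever the stutter position is unambiguous: positions coinciding
  with a true allele, or shared by two candidate (parent, type) pairs, are
  excluded. A present parent with no called stutter peak scores SR = 0, so
  stutter-free data fit a zero model. A locus/type is fitted as a linear
  function of parent allele number when ≥3 distinct parent alleles are seen
  and the OLS slope is significant at p < 0.05; otherwise the mean SR is
  used. Predictions are truncated to [0, cap].
* **Drop-in rate** = events / (loci × samples) over truth-free controls,
  reported as an exact rational quotient — no rounding or adjustment is
  applied. At most two peaks per control are counted as drop-in; more
  raises a contamination warning. The suggested height cap is the smallest
  round thousand RFU above the largest counted peak (floor 1000).
* **Saturation.** At simple-repeat loci, each parent with a measurable
  back-stutter peak yields an expected height `Ea = stutter height /
  predicted SR`. Pairs (Oa, Ea) are binned by observed height in 2000-RFU
  bins; the estimate is the lower edge of the first bin from which the
  median Oa/Ea stays below 0.9 in all later non-empty bins (tolerance and
  bin width configurable). Fewer than 50 usable pairs is an error; no
  divergence returns "none detected".
* **Heterozygote balance.** With Hb the larger-size/smaller-size sister
  height ratio and APH their mean, the variance model is `var(log10 Hb) =
  C²/APH`. Each observation's `(log10 Hb)² · APH` estimates C²; C² is their
  median divided by 0.45494 (the χ²₁ median), which makes the median-based
  estimator consistent for the variance — without that factor the nominal
  95% band `±1.96·√(C²/APH)` would cover only ~81% of Gaussian data. The
  band multiplier k is configurable (1.96 default).

## Likelihood-ratio engines

Both engines are statsmodels-style fitted models: construct with the
replicate EPGs, a prosecution and a defence hypothesis, and frequency
data; `fit()` returns an `LRResult` with per-locus log10 LRs, nuisance
estimates, a `summary()` table and a status that is `"ok"` or `"FAIL"` —
model validation failure is a distinct outcome, never a silent number.

**Genotype priors.** Unknown contributors' genotypes are assigned
Balding–Nichols subpopulation-corrected probabilities by sequential allele
sampling, conditioned on every typed reference appearing in either
hypothesis. With a single known contributor versus one unknown this
reproduces the standard theta-corrected match-probability forms exactly,
so the engine and the hand calculation agree on clean single-source
profiles. Alleles outside the locus universe (observed ∪ typed references)
are aggregated into a residual symbol with the remaining frequency mass;
unseen alleles receive the floor 5/(2N) for a database of N = 1000.

**Semi-continuous engine.** Peak heights are ignored. Per locus, the
likelihood under a hypothesis sums over genotype assignments the product
over replicates of: each carried allele copy detected independently with
probability 1−d_k (homozygote drop-out is d_k², stated explicitly because
conventions differ); unexplained observed alleles are drop-in with
probability c·p_a each, at most two per locus per replicate; a replicate
with no drop-in contributes 1−c. The drop-out d_k is shared across loci,
per contributor, and maximised on a grid — step 0.01 for up to two
contributors, step 0.05 for three, where the exact-enumeration guard ends.
A fixed d can be supplied instead (used for the Turing-expectation and
enumeration oracles). Computation is vectorised over the drop-out grid via
per-allele count-pattern tables.

**Quantitative engine.** A gamma peak-height model in the style of
MLE-based quantitative tools, restricted to two contributors: each
position's height is gamma-distributed with CV ω around `μ · mix_k · dose ·
δ_k^((size−125)/100)`, redistributed by fitted back/forward stutter
proportions; expected-but-absent positions contribute the gamma mass below
the dye AT; unexpected peaks are drop-in (rate × a uniform height law over
[AT, 30,000] by default, or an exponential law with λ = 0.01). Unmodelled
stutter types must be filtered from the data first; back/forward stutter
peaks stay in and the model fits them. The likelihood is maximised by
Nelder–Mead over (log μ, bounded ω, mixture logit, per-contributor
degradation, stutter logits) with multiple starts — for two-contributor
fits two extra starts seed the mixture weight at its extremes so strongly
unbalanced optima are reachable — followed by a fresh-simplex restart
polish; identical hypotheses share identical starts so their LR is exactly
zero. ω is bounded in [0.05, 2.5]: the lower bound prevents the density
spike on exactly-expected data, the upper keeps drop-out probabilities
meaningful. Stutter-only positions carry a wider CV, `stutter_cv_factor ×
ω` (default 3): stutter ratios are far noisier than allele heights, and
letting them drive the allelic ω washes out genotype resolution — the
same reason dedicated tools calibrate stutter variance separately from
allele variance. Degradation is bounded below by 1 − degradation_max
(default 0.1); analyses of deliberately degraded material should widen
this (the perturbation experiment uses 0.9, an effectively free decay
slope, since a −80% step cannot be represented inside [0.9, 1]).

**Calibrated-imbalance validity rule.** Optionally the engine accepts the
heterozygote-balance calibration (`hb_bounds`). At the fitted optimum —
never during optimisation, so the search surface stays smooth — a genotype
set is declared impossible when a contributor's het pair has one sister
observed at a height whose implied imbalance `log10(h/AT)` exceeds
`hb_k ×` the calibrated band half-width (hb_k default 2) while the other
sister is absent *and* that contributor is effectively the sole source of
the observed peak (expected share ≥ 0.999). This is what makes an extreme
missing-sister profile return LR = 0 when analysed as single-source with
the true donor conditioned, while an added contributor can legitimately
absorb the peak: the same mechanism by which calibrated variance models
exclude true donors under an understated contributor number, and rescue
them at N + 1. If the prosecution hypothesis cannot explain the data at
any parameter values the LR is 0 (−infinity in log10); if the defence
hypothesis is invalid at its own optimum the result is status `"FAIL"`.

## Validation experiment designs

All experiments return an `ExperimentReport` whose per-sample records each
carry their generating seed and whose aggregate rates are recomputed from
the records at write time. Child seeds derive deterministically from the
experiment seed by indexed splitting. Problem sizes below are the
package's defaults, chosen to give stable rates on a workstation; all are
configurable.

* **Sensitivity/specificity**: simulated 1-cell and 2-cell single-source
  subsamples and 2-cell mini-mixtures; true-donor LRs at thresholds
  log10 LR > 0 and ≥ 6; same-donor subsamples (screened at log10 LR > 1)
  joined into replicate groups of 3–5; a known non-contributor database
  searched for false positives.
* **Contributor-number misspecification**: single-source subsamples paired
  at N = 1 and N = 2, mini-mixtures at N = 2 and N = 1, with sign changes
  and zero-LRs rescued by N + 1 tabulated.
* **Replicate misclassification**: a correct-donor replicate group
  re-evaluated after adding wrong-donor subsamples of varying quality;
  engine failures reported as the distinct outcome `FAIL`.
* **Mixture deconvolution**: per equimolar mixture of 2–6 donors, the
  reference ceiling log10(1/RMP), the replicate LR from that donor's
  single-cell subsamples, and — for up to three contributors, the
  semi-continuous enumeration guard — the bulk standard-analysis LR;
  larger mixtures record a "not supported" refusal for bulk analysis.
* **Perturbation robustness**: a high-quality three-cell subsample
  (cv_peak 0.5, lsae_sd 0.1 — the complete, well-amplified kind of profile
  such accuracy tests are run on) analysed intact and under the three
  perturbations with the quantitative engine (six starts, free degradation
  slope).

## Numerical choices and degenerate inputs

* Allele designations compare with a 0.05-repeat tolerance to absorb text
  round-trips; fractional designations are preserved.
* LR = 0 is stored as −infinity; rendering layers may substitute sentinel
  values for plotting, the stored value is never altered.
* Semi-continuous likelihoods are exact sums; the drop-out grid tie-break
  takes the smallest grid value.
* The quantitative per-locus log-likelihoods are computed in log space
  throughout (a 15,000-RFU drop-in underflows otherwise) and the reported
  total is the sum of the per-locus values at the fitted optima.
* Degenerate calibration inputs: a flat baseline yields AT = 0; zero
  drop-in events yield rate 0 and the floor cap; fewer than 30
  heterozygote observations warn; an all-zero stutter table fits a zero
  model.

## Known limitations

* The quantitative engine has no per-locus amplification-efficiency
  parameter; locus-specific effects (inhibition) are absorbed by ω, which
  slightly widens LR spread relative to tools that model LSAE.
* The semi-continuous engine's three-contributor grid is coarsened to
  0.05 steps for tractability of exact genotype enumeration.
* Bulk standard analysis in the deconvolution experiment stops at three
  contributors (the exact-enumeration guard), one short of the four that
  dedicated tools recommend as their own limit.
* E[LR | Hd] = 1 holds exactly only when the defence model matches the
  generator; allele-collision effects of order c·d make the empirical mean
  differ at the 10⁻³ level.
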