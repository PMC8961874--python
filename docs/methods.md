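# Methods

This note documents the models behind `gdmr`: what is simulated, what is
estimated, the defaults and why, and what the package's validation does and
does not demonstrate.

## 1. The assay model

### Genomes and digestion

A synthetic genome is a random A/C/G/T sequence constructed to contain an
exact number of CCGG (HpaII/MspI) and GAATTC (EcoRI) sites, verified by the
package's own scanner. Each CCGG site carries a binary methylation state,
drawn i.i.d. Bernoulli(m); the realised methylated fraction is the genome's
ground-truth GDMR. An `exact=True` mode places exactly `round(m·n)`
methylated sites for uses that need the target hit without binomial
scatter. Digestion is deterministic: EcoRI cuts every GAATTC, MspI every
CCGG, HpaII exactly the unmethylated CCGG; each cut yields two sticky ends.
Methylation states are binary per site — no allelic or cellular mosaicism
within one genome; population-level fractions arise from averaging over
sites. MspI is modelled as fully methylation-insensitive; outer-cytosine
(CmCGG) edge cases are ignored. Partial digestion, star activity and
fragment-length effects are out of scope.

### The incorporation kernel

Pyrosequencing fill-in is modelled per end class with an incorporation
*schedule*: ordered `(base, multiplicity)` steps, each consumed at the
first dispensation of its base at or after a running pointer, which then
advances past that dispensation. Defaults, derived from the fill-in
chemistry of the two overhangs under the dispensation order
`GTGTCACATGTGTG`:

| end class | schedule | dispensations hit (1-based) |
|---|---|---|
| CG overhang (HpaII/MspI) | C×1, G×1 | C at 5, G at 10 |
| AATT overhang (EcoRI) | A×1, A×1, T×2 | A at 6, A at 8, T at 9 (double) |

The two A extensions are modelled as separate single-base steps (the
dispensation order offers A twice, at 6 and 8, flanked by C dispensations,
and the quantification protocol reads the EcoRI signal from the T peak at
9); the two template T's extend within one dispensation and produce a
double-height peak. Instrument conventions for peak placement vary, so the
schedules and the quantifier's peak assignment are both configurable — and
consistent with each other by construction. The leading `GTGT`
dispensations produce no signal and carry only baseline noise, honouring
the printed order.

Noiseless peak height is κ × (incorporations at that dispensation), with κ
an arbitrary intensity scale. Noise is multiplicative lognormal jitter with
a configurable CV (mean exactly 1) plus an optional additive Gaussian
baseline, clipped at zero.

### Quantification and noise propagation

GDMR is computed from the G peak (dispensation 10) and T peak (9) of each
reaction as `(1 − (HpaII_G/EcoRI_Hpa_T)/(MspI_G/EcoRI_Msp_T)) × 100`. The
bracketing of the assay formula is read as (1 − ratio of ratios) × 100 —
the only reading that yields percentages in [0, 100]; the alternative
literal placement of the ×100 inside the bracket is a typographical
artifact and is rejected. The formula is invariant to κ, to the
2-ends-per-cut factor and to any per-sample or per-reaction rescaling, so
whether an instrument reports raw or pre-normalised heights does not
matter. With zero noise the quantifier inverts the simulator exactly:
GDMR = 100 × (1 − HpaII cuts / MspI cuts) = 100 × methylated fraction.

Noise pushes values slightly outside [0, 100]; policy is clamp + flag
(`clamped_low`/`clamped_high`) rather than error, mirroring how bounded
percentages are reported in practice. Any of the four peaks at or below a
low-signal floor (default 1% of the run's maximum peak — an artifact
default, configurable) makes the sample's GDMR missing with a
`low_signal` flag.

The default peak CV is 0.014, calibrated to the assay's published
control-sample precision (CV 1.4% over 86 runs). Because the ratio of
ratios multiplies four lognormal factors, the implied GDMR CV for a
control methylated at fraction m is, by the delta method,
`CV_GDMR ≈ (1−m)/m · sqrt(exp(4·ln(1+cv²)) − 1)` — about 0.7% at m = 0.8.
`predicted_control_cv` exposes this propagation, and the validation suite
checks the simulated 86-replicate control CV against it (an internal
consistency check: the printed 1.4% is the calibration source, not an
independent target).

## 2. The phenotype generators

### Design

Defaults reproduce the study structure: 59 lambs (24 Romane,
23 Blackbelly, 12 Charollais; 28 males / 31 females) sampled at 5 monthly
occasions from birth, and a slaughter subset of 30 lambs (15 + 15;
16 males / 14 females) with 13 shared tissues (blood + 12 somatic) plus 3
sex-specific reproductive tissues each — 295 blood records and 480 tissue
records. The unbalanced breed counts are preserved deliberately so
LSMeans differ from raw means and the marginal-means machinery is actually
exercised. `scaled_longitudinal(factor)` scales animal numbers while
preserving the breed/sex mix, for power and recovery studies.

### Effects

Records follow `y = μ + Σ fixed effects + a_animal + e` with sum-to-zero
fixed effects, one `a ~ N(0, σ_a²)` per animal shared across its records,
and i.i.d. `e ~ N(0, σ_e²)`. Presets wire in published level means:

- **blood_gdmr** — date means 80.50/81.05/79.76/81.01/81.40, breed means
  81.13/80.24/80.87, sex means 80.37/81.12 (%). The three factors' printed
  means disagree by < 0.01 (rounding), so μ is their average and recovered
  level means are exact to ~0.003.
- **somatic_tissue / reproductive_tissue** — tissue level means using
  published values where printed (lung 70.45, muscle 67.69, spleen 72.46,
  cortical kidney 55.44, ovary 71.39; blood 80) and plausible
  interpolations elsewhere; the −9% female–male cortical-kidney gap enters
  through the tissue×sex interaction (row-centred within tissue so tissue
  level means stay interpretable). Reproductive tissues are generated with
  a breed + tissue structure and no sex term (sex is confounded with
  tissue there).
- **wbc_composition / cbc_counts** — white-cell composition means
  60.4/31.2/4.4/2.0/0.8 with SDs 11.6/10.5/2.8/1.6/0.3 (%), and total
  white-cell breed means 8.13/9.81/8.00 Giga/L.

σ_a and σ_e are **not published** and are artifact choices: σ_a = 0.76,
σ_e = 1.52 (%), set so that (i) σ_a²/(σ_a²+σ_e²) = 0.20, echoing the
reported blood-GDMR heritability of 0.20 used as a repeatability proxy,
and (ii) LSMean standard errors at the design size come out ≈ 0.2, the
order of the printed SEs (0.15–0.26). Tissue-panel σ_a = 1.5, σ_e = 3.0
reflect the larger printed tissue SDs (1.6–7.8).

### CBC composition

The five cell-type percentages are logistic-normal: per-type log
perturbations with scale sd/mean around the composition centres, then
renormalised so each record sums to exactly 100. The printed means sum to
98.8 (rounding of the source data), so the centres are those means
rescaled to 100; with the skew of the lognormal and the renormalisation,
the simulated mean lymphocyte share lands within ~0.5 points of 60.4.
Absolute counts are percent × a lognormal total (CV 0.2, an artifact
default). CBC is generated marginally — no CBC→GDMR link — unless a
covariate slope (e.g. `neutrophils`) is set on the effect spec, which
feeds the centred count into the GDMR mean and activates the
covariate-model pathway.

What the generators deliberately do **not** emulate: pedigree/genetic
structure, date-by-season confounding beyond a fixed date factor,
within-animal serial correlation beyond the shared intercept,
heteroscedastic tissues, assay batch effects. Passing recovery tests
therefore demonstrates that the estimation machinery is correct under the
stated model, not that the model captures every feature of real data.

## 3. Estimation

Mixed models are fitted by REML (statsmodels `MixedLM`; random intercept
per animal). Inputs are deterministically re-sorted before fitting, so
estimates are exactly invariant to row order. Fixed effects use
reference-cell coding internally; all reported quantities (LSMeans,
contrasts) are coding-independent.

- **Term tests**: Wald F per term, denominator df
  `n_obs − rank(X) − (n_subjects − 1)` (a containment-style residual df;
  Satterthwaite/Kenward–Roger are out of scope and matter little at these
  sizes — the published real-data p-values were produced by an unstated df
  method and are not exact reproduction targets).
- **LSMeans**: contrast = design row averaged uniformly over the full
  cross of the other factors' levels, covariates at their sample mean;
  SE via the coefficient covariance. Verified against R's emmeans to
  1e-4 in the test suite.
- **Tukey–Kramer**: `q = √2·|diff|/se(diff)` on the studentized-range
  distribution with k groups and the residual df; unbalanced designs are
  handled through the contrast covariance. Compact letters by
  insert-and-absorb; letters are assigned in ascending-mean order. In
  zero-variance fits, differences and SEs are both at round-off level, so
  comparisons are decided on a relative 1e-10 scale instead of dividing
  noise by noise.
- **BIC**: `−2·llf_REML + k·ln(N)` with k = 2 covariance parameters and
  N = subjects (the convention of the mixed-model software that produced
  the published comparison table); `convention="all"` gives the textbook
  all-parameters count. Only orderings are meaningful; comparing REML
  likelihoods across different fixed-effect sets is flagged as a caveat
  but reported, since that is exactly how the published model comparison
  was done. Whether that table used ML or REML is unstated; only the
  ordering is treated as a target.
- **Backward elimination**: drop the least significant term with
  p ≥ 0.05, interactions before the main effects they contain; ties break
  toward the higher-order term, then lexicographically (deterministic).

Correlations are pairwise-complete Pearson with
`t = r√(n−2)/√(1−r²)` p-values on n−2 df; pairs with < 3 complete animals
(notably all female×male reproductive-tissue pairs) are reported missing,
not raised. No multiplicity correction by default (nominal reporting, as
in the source analyses); Benjamini–Hochberg is an opt-in column.

## 4. Validation design and problem sizes

- Scanner: exhaustive agreement with a character-by-character oracle on
  all sequences to length 8, plus 100 random 10 kb sequences; palindromy,
  N-spacer concatenation and chunk-size invariance as property tests.
- Assay: the kernel hand-trace above is frozen as a unit test; closed-form
  inversion is exact on a methylation grid; κ-invariance, monotonicity and
  seed determinism are property tests.
- Model recovery: 20 replicate panels at the design size (59×5) recover
  the breed/sex LSMeans within 3 Monte-Carlo SEs (~0.15).
- Tukey letter pattern: at the design size the published date effects put
  the birth-vs-2-months comparison almost exactly on the Tukey critical
  difference (critical ≈ 0.76 vs a true difference of 0.74), so the
  published grouping cannot be reproduced reliably at n = 59. The critical
  difference scales as 1/√n_animals and falls strictly inside the
  (0.55, 0.74) window — the gap between the largest truly-grouped and the
  smallest truly-separated date difference — for roughly 62–108 animals.
  The recovery test therefore uses 1.5× the design (88 animals) and takes
  the majority pairwise decision over 50 replicates, from which the letter
  display is rebuilt. This n was fixed from that power analysis.
- BIC ordering: 50 replicates with a true date effect and no
  neutrophil link; the date model must win the majority.
- All simulation sizes (20 seeds for recovery, 50 for the pattern/BIC
  studies, 86 control replicates, 10 kb scanner sequences) are the
  package's chosen desk-scale defaults: large enough for 3-SE assertions
  to be meaningful, small enough to keep the whole suite around a minute.

## 5. Known limitations

- The real study's raw data are not redistributable, so real-data LSMeans,
  F-test p-values and absolute BIC values are not reproduction targets;
  validation is parameter recovery on matched synthetic data plus the
  printed correlation p-values, which are exactly derivable from (r, n).
- The scanner makes no assumption about genome assemblies; the ~6 million
  sheep CCGG count depends on an unstated assembly version and is not
  asserted anywhere.
- `MixedLM` occasionally needs an optimizer fallback (Powell/CG) near
  variance boundaries; fits at σ_a → 0 are valid but sit on the boundary
  and their σ_a² estimate is then downward-noisy.
- The compact-letter algorithm yields a minimal letter set for the
  patterns arising here; pathological significance graphs can admit
  multiple valid displays, in which case ties are resolved by level order.
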