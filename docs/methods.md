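# Methods

## Model and procedure

`dispscan` maps loci affecting residual trait *variance* (phenotypic
dispersion, vQTL) in an F2 intercross of two inbred strains P1 and P2.
The dispersion phenotype for individual *j* at locus *i* is the
absolute externally Studentized residual of the trait from a linear
covariate model that contains the locus itself:

    y_j = mu + alpha_i(g_j) + beta_MLH * MLH_j + beta_UCrea * UCrea_j + eps_j
    t_j = eps_hat_j / (sigma_hat_(j) * sqrt(1 - h_jj)),    PD_j = |t_j|

with h_jj the leverage and sigma_hat_(j) the residual scale of the
model refit without observation j (computed in closed form from the
full fit; this is the standard externally Studentized residual, so each
individual's dispersion score is not deflated by its own aberrance).
PD is then regressed on the locus genotype (plus MLH when selected) by
maximum likelihood under a left-bounded Gaussian model, and genotype
effects are tested jointly with a 2-df Wald contrast against the
reference (P2) homozygote.

Assumptions worth stating plainly: the stage-1 model is ordinary least
squares (no robust or heteroskedasticity-consistent variant); the
bounded-Gaussian stage treats |t| as approximately truncated-normal,
which is a working approximation (under the null |t| is folded-t), so
the joint Wald test runs slightly conservative — about 4.3% empirical
rejection at the nominal 5% with n = 300 (measured by the acceptance
script's null study); dispersion at linked markers is recomputed per
marker, so neighboring tests are correlated through both linkage and
the shared phenotype.

## Tobit variants

The scan default is the *truncated* variant, matching the renormalized
density L = prod f(y) / (1 - Phi((tau - x b)/sigma)); the *censored*
variant (probability mass at the bound) is implemented behind the same
interface and selected by `RunConfig.tobit_variant`, since the term
"Tobit" conventionally denotes the censored form and archived data sets
may have been fit either way. With no observations at the bound the
censored likelihood reduces exactly to the Gaussian one (tested to
1e-10). sigma is parameterized as log sigma for unconstrained BFGS;
an analytic gradient is supplied, a damped Newton polish (numerical
Hessian) finishes the optimization, and convergence requires a gradient
2-norm below 1e-6. Standard errors come from the inverse of the
central-difference observed information at the optimum on the natural
(beta, sigma) scale, step 1e-5*(1+|theta|).

## Covariate selection

Creatinine enters only the albumin models (urine concentration proxy).
MLH = n_het/n_typed enters when associated with dispersion at P < 0.1;
the probe fits the locus-free covariate model, forms PD, and regresses
PD on MLH by OLS. Two ambiguities were resolved as package defaults,
both switchable: the probe targets PD from the covariate-only model
(not the trait itself, and not per-marker PD), and the albumin~MLH and
albumin~UCrea covariates are carried in one joint model. Because MLH is
computed from the full marker panel, per-marker statistics are
invariant to removing markers only when a precomputed MLH series is
passed (`scan_trait(..., mlh=...)`); recomputing MLH from a reduced
panel perturbs the covariate, which is a property of the definition,
not of the implementation.

## Architecture calls

Genotypic dispersion means (mu_CC, mu_CA, mu_AA) come from the fitted
coefficients (CC = P1 homozygote, AA = P2 homozygote = reference).
Contrasts, all single-row Wald tests at the nominal `alpha_label`
(default 0.05):

* additivity: (+1, 0, -1), the homozygote difference; the
  heterozygote-vs-midparent contrast (-0.5, +1, -0.5) is also emitted
  since the two are conflated in common usage — the (+1, 0, -1) result
  feeds the "A" label;
* dominance families: (+0.5, +0.5, -1), (-1, +0.5, +0.5) for positive
  dominance and (+1, -0.5, -0.5), (-0.5, -0.5, +1) for negative
  dominance. Any single high homozygote sends several of these vectors
  positive, so family labels are gated by the sign of the midparent
  (dominance-deviation) contrast: positive dominance requires the
  heterozygote above the midparent, negative below;
* OD/UD: the heterozygote significantly above (below) both homozygotes
  by the two pairwise contrasts. The OD configuration is exactly both
  positive-dominance vectors firing, so OD absorbs D+ (and UD absorbs
  D-).

Multiple labels are reported (partial negative dominance = {D-, A}, the
dominant pattern in the motivating application); contradictory families
are flagged ambiguous rather than suppressed. The high-dispersion
allele is named by strain from the largest *fitted* mean.

Griffing's potence ratio h_P = Q/L = (2mu_CA - mu_CC - mu_AA) /
(mu_CC - mu_AA) is reported undefined (not silently NaN) when the
homozygote means coincide within 1e-12. Two sign orientations are
provided because the raw strain-ordered ratio measures dominance toward
the *P1* side while the field convention reads +1 as dominance toward
the *high* parent: `orient="high"` (default) divides by |L|, so +1/-1
mean complete dominance toward the high/low homozygote; the Q/L
identity and the strain-swap antisymmetry hold exactly for
`orient="strain"`.

## Multiple testing

Step-up Benjamini-Hochberg per cohort x trait across all tested markers
(no linkage adjustment), rejection additionally requiring nominal
P <= 0.01. The floor can only remove rejections; the alternative
reading (floor as an override admitting markers that fail BH) is
anti-conservative and was rejected. Ties share the maximal qualifying
rank; NaN p-values are excluded from m with a warning.

## Scan rules and numerical choices

* Reference genotype: the P2 homozygote is the baseline dummy level
  throughout.
* min_class_n = 5: a marker with any present genotype class smaller
  than this is skipped (listed with reason, excluded from the FDR m).
  Classes entirely absent are not penalized: hemizygous X markers in
  all-male F2s carry two classes and keep the joint test at 1 df but
  get no three-class architecture call.
* r-squared: the bounded-likelihood model has no canonical r2; the
  squared Pearson correlation between genotype-class fitted PD and
  observed PD is used, which reduces to the OLS class-model R2 in the
  censoring-free limit (tested).
* Consensus window 10 MB, same high-dispersion allele required by
  default; same-window groups with opposite alleles are reported as
  contrast pairs, not loci. Locus names are PD<Trait><k> ordered by
  chromosome then position.
* Determinism: identical config + seed produce byte-identical scan
  tables; every output embeds the config hash.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
data set: ~100 markers over 19 autosomes + X at 17 cM spacing
(synthetic bp = cM x 2e6 + 3 Mb, an affine map — only relative
positions matter to consensus grouping); F2 genotypes as two
independent gametes per autosome, each a Markov chain with Haldane
recombination r = (1 - e^(-2d))/2 (no interference; the map function is
swappable); a single maternal gamete for X. Phenotype defaults, chosen
once from the cohort descriptions the design targets: creatinine
~ N(76, 20^2) mg/dl truncated at 0; albumin = 2.17 + 0.013*UCrea
- 4.87*MLH + sum(mean shifts) + eps, giving a cohort mean near
0.7 mg/dl; sd(eps) = 0.5 x the product of per-vQTL sigma factors x
exp(-2*(MLH - 0.5)) (so the PD~MLH regression lands near -1.7);
detection floor at 0 on albumin; missingness 5% (albumin), 1%
(creatinine), 2% (genotypes). vQTL effects act multiplicatively on the
residual SD with per-class factors from presets (D- with high P2 =
(1, 1, rho)).

What the generator does *not* model: the strong right skew of real
albumin distributions (residuals are Gaussian before flooring), litter
and sex structure, genotyping error, linkage disequilibrium beyond F2
meiosis, and trait-specific missingness mechanisms (missingness is
completely at random). Passing recovery tests therefore demonstrate
correctness of the pipeline under its own model, and calibration under
Gaussian-like noise; they do not certify behavior under gross
distributional violation — which is precisely what the Studentization
+ bounded-likelihood design is meant to blunt, not eliminate.

## Problem sizes

The calibration studies use: 200 replicates of 99-marker, n = 300 null
cohorts for type-I error; 200 replicates of n = 400 cohorts with one
negative-dominant locus (sigma ratio 2) for localization (top marker =
causal or immediate neighbor) and architecture recovery; n = 10000 for
sigma-ratio estimation (with the albumin intercept raised so the
detection floor never binds, isolating the generative contrast from
censoring attenuation — under the floor the same ratio attenuates to
~1.7); 200000 gametes for the Haldane check; 10000 individuals for
segregation ratios. A full 99-marker, n = 400 scan takes about one
second on one CPU.

## Known limitations

* The truncated-normal working model for |t| is misspecified under the
  null (folded-t); the practical effect is mild conservatism of the
  joint test (~4.3% at nominal 5%, n = 300).
* The Wald architecture contrasts use the same fit as the joint test;
  with small class counts (near min_class_n) the chi-square reference
  is optimistic, and contradictory families can both reach nominal
  significance — such calls are flagged ambiguous.
* No interval mapping: tests are at genotyped markers only, and
  localization is reported relative to the marker grid.
* No permutation-based genome-wide thresholds; the FDR family is
  markers within one cohort x trait.
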