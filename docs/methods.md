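# Methods

`osdtox` quantifies how an entire soil microbial community responds to a
toxicant gradient (here: silver as Ag⁺, Ag nanoparticles, or sulfidised Ag
nanoparticles, in mg Ag kg⁻¹ soil), by treating every OTU in a 16S amplicon
survey as its own toxicity assay and summarising the per-OTU thresholds as a
community sensitivity distribution.

## Dose-response models

Two nested models are fitted to every endpoint series:

- four-parameter log-logistic:  y = c + (d − c) / (1 + (x/e)^b)
- Brain–Cousens hormesis:       y = c + (d − c + f·x) / (1 + (x/e)^b)

with d the control (zero-dose) response, c the lower asymptote, e the
inflection dose (the EC50 of the span) and b the slope. The hormesis term
f·x allows stimulation at low doses; with f = 0 the models coincide exactly,
and under f ≠ 0 the parameters b and e lose their slope/inflection reading.

**Fitting.** Nonlinear least squares (Levenberg–Marquardt), with e optimised
as log e so positivity is structural; tolerances 1e-10, at most 10⁴
evaluations. Starting values are chosen for unattended batch fitting: d from
the mean response at the two lowest doses, c floored at 0, e at the
geometric mean of the positive doses, b = 1, f = 0; three deterministic
perturbed starts are tried only when the primary start fails outright. A fit
that exhausts the evaluation budget is kept (LM descends monotonically) and
left to the R² screen; constant-response series are declared degenerate
(`fit_failed`) rather than "perfectly fitted". The parameter covariance is
s²(JᵀJ)⁻¹ with the analytic Jacobian mapped back to the natural scale; a
singular Jacobian leaves the covariance unavailable (downstream consumers
then skip CIs and treat hormesis as non-significant, with a warning).

**Acceptance screen.** A fit is usable only if (1) b > 0 — the response
declines, i.e. the toxicant inhibits; (2) e is below the maximum spiking
concentration — the half-effect lies inside the tested range; and (3)
R² > 0.65 (strict), with R² = 1 − SSres/SStot about the response mean.
Criterion 2 is applied to hormesis fits as well, although e has no clean
interpretation there; the rule set is deliberately uniform across models.

**Model choice.** For per-OTU work the hormesis fit is preferred whenever it
passes the screen (it yields the more conservative, i.e. lower, EC20);
statistical significance of f is recorded as metadata but not required. The
nitrification branch inverts this: hormesis is used only when f is
significant, otherwise the plain sigmoid — the two branches genuinely differ
and the divergence is intentional.

**Hormesis significance.** Wald t-interval: f ± t(n−5, 0.975)·SE(f),
significant iff the interval excludes 0. Characterised on null (f = 0)
simulations this test runs mildly liberal (≈6% at nominal 5%, df = 9),
which is typical of Wald intervals in small-sample nonlinear regression.

**ECx.** EC_p is the dose producing a p% reduction. Two reference modes:
`upper_asymptote` (default) solves y(x) = (1 − p/100)·d — the reduction is
measured from the control response; `span` uses the drc convention
EC_p = e·(p/(100−p))^(1/b), measuring the reduction across the d..c span.
Both have closed forms for the log-logistic; hormesis ECx is root-found on
the descending limb (bracketed between the fitted curve's peak and 10× the
maximum dose, relative tolerance 1e-8). Estimates below the control soil's
background concentration (0.1 mg kg⁻¹) are retained but flagged
`below_background`; a pipeline switch can exclude them from the OSD.
Delta-method 95% CIs propagate the covariance through the ECx gradient
(analytic for the log-logistic span form, central differences otherwise),
with the lower bound floored at 0.

## Preprocessing to absolute abundance

The pipeline is strictly staged — raw → filtered → rarefied → absolute —
and each operation refuses tables in the wrong stage.

1. **Low-count filter**: OTUs with a table-wide total ≤ 2 reads (singletons
   and doubletons) are removed.
2. **Rarefaction** to 9,000 reads per sample (multivariate hypergeometric,
   i.e. subsampling without replacement); samples below the depth are
   dropped with a warning rather than scaled. Per-sample RNG streams derive
   from (seed, CRC32(sample id)) so results do not depend on sample order.
3. **Copy-number correction**: A(i,s) = T(s)·r(i,s)/CN(i), where r is the
   read relative abundance, T the sample's total 16S load from qPCR and CN
   the OTU's 16S copies per genome — the response becomes genome-equivalent
   ("single-copy 16S") abundance. The 16S pool is conserved exactly:
   Σᵢ A(i,s)·CN(i) = T(s).
4. **Eligibility**: an OTU enters fitting for a treatment arm only with
   nonzero abundance in ≥ 6 of that arm's samples (degrees of freedom for a
   5-parameter fit); control samples count toward every arm.

## OTU sensitivity distribution and hazardous concentrations

Accepted EC20s per treatment are fitted by maximum likelihood to a Burr
Type III distribution, F(x) = (1 + (b/x)^c)^(−k) — the Burrlioz convention;
Burr III parameterizations differ across the literature, so this form is
fixed and stated. Parameters are optimised as logs (L-BFGS-B with analytic
gradients, several quantile-matching starts, Nelder–Mead polish when the
gradient norm indicates an early stop). At least 8 EC20 values are required;
below that, SSD practice switches to other distributions, which is out of
scope here and raises an explicit error instead.

HCp — the concentration affecting p% of OTUs, protecting 100−p% — is the
p/100 quantile, computed in log space for numerical stability at extreme
shapes. 95% CIs come from a nonparametric bootstrap over the EC20 records
(default 1,000 resamples; percentile method); each resample refit is
warm-started from the full-data MLE to avoid likelihood-ridge local optima.
Failed resamples are dropped and counted (warning above 10%, error above
50%). Treatments are compared by CI overlap — two HCp values differ
"significantly" iff their 95% CIs are disjoint; compact letters are derived
from the maximal cliques of the interval-overlap graph. The overlap rule
reproduces the superscript-letter pattern of the study this design follows,
but it is an assumption: the original software's comparison rule is not
published.

## Nitrification branch

Net nitrate production per replicate is NO₃⁻(t=28 d) − NO₃⁻(t=0); the t0
subtraction is the only correction (it also removes NO₃⁻ co-added with
AgNO₃). Responses are expressed as percent of the control mean and fitted
with the shared engine; EC10/EC20/EC50 are reported with delta-method CIs,
R², and CI-overlap letters across treatments. Gene-copy endpoints (e.g.
bacterial amoA per g soil) use the same operation via a precomputed
`response` column.

## Synthetic data generator

The generator emulates the reference design: a 14-rate geometric dose
gradient from 0.1 (the control soil's background) to 5,590 mg Ag kg⁻¹, one
sequenced sample per rate. Each OTU is insensitive (flat), log-logistic
declining, or hormetic. Defaults, chosen once:

| quantity | default | rationale |
|---|---|---|
| class mix (ins/ll/horm) | 0.4 / 0.4 / 0.2 | stimulation is the rare class in real soils |
| EC50 e | lognormal, median 20 mg kg⁻¹, σ_log 1.2 | bulk inside the gradient, realistic tails outside |
| slope b | Uniform(0.8, 4) | range seen in per-OTU fits |
| hormetic peak | Uniform(+10%, +50%) over d, f calibrated by bisection within the dose range | stated stimulation sizes |
| base abundances | lognormal σ = 1.5, renormalised | heavy-tailed community |
| 16S copy number | integer Uniform(1, 10) | span of bacterial rrn copy numbers |
| sequencing depth | 20,000 reads | above the 9,000 rarefaction target, as in real data |
| qPCR total | 10⁸ copies, lognormal CV 2% | order of magnitude of soil 16S loads |

Reads are multinomial over 16S-copy pool shares (abundance × copy number);
a Dirichlet-multinomial overdispersion knob exists but is off by default.
The qPCR total is an unbiased lognormal perturbation of the true pool.
What the generator does **not** emulate: taxonomic structure, compositional
correlations between OTUs, PCR/primer bias, chimeras, or spatial soil
heterogeneity — a green recovery test therefore establishes correctness of
the estimator chain under the stated noise model, not robustness to every
artefact of real amplicon data.

Known consequence of the stated noise model: with 9,000 reads over 500
heavy-tailed OTUs, the rarer accepted OTUs carry single-digit counts per
sample, and the median per-OTU EC20 recovery error sits near 30% (it falls
to ~3% for abundant OTUs or at 100× depth). The estimator is unbiased; the
limit is counting noise, and community-level quantities (OSD, HCx) are much
more stable than individual EC20s.

## Numerical choices and degenerate inputs

- e (and Burr parameters) strictly positive via log-parameterisation;
  internal log values clamped to avoid overflow during optimizer excursions.
- Hormesis peak location found by coarse log-grid + bounded refinement;
  for b ≤ 1 the Brain–Cousens curve is unbounded as x → ∞, so peaks and
  stimulation sizes are always taken within the assayed dose range.
- ECx root-finding reports a explicit "not attained" error when the target
  reduction is never reached in (0, 10·max dose]; callers treat that OTU or
  endpoint as having no ECx rather than extrapolating.
- Flat series, identical EC20s, < 8 EC20s, missing qPCR totals, samples
  below rarefaction depth: all rejected or dropped with explicit reasons,
  never silently imputed.

## Limitations

- Burrlioz's small-sample fallback distributions (log-logistic,
  inverse Weibull) are not implemented; n < 8 is an error.
- No weighting or variance modelling in the least-squares fits; responses
  enter unweighted, as in the reference analysis.
- The CI-overlap significance rule is conservative relative to a formal
  difference test.
- HDF5/JSON BIOM input is not supported; use the classic TSV flattening.
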