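# Methods

## The model

qsrrkit fits quantitative structure–retention relationship (QSRR) models:
linear regressions that map numeric molecular descriptors (MDs) to the
chromatographic retention time of an analyte, in minutes. Two model forms
are supported, both written without a constant term in their canonical
form:

* **classic**

  t_R(A) = a₁·MD₁ + a₂·MD₂ + … + aₙ·MDₙ

* **reference-augmented**

  t_R(A) = a₁·MD₁ + … + aₙ·MDₙ + b·t_R(R)

where t_R(R) is the analyte's retention time measured under the *same*
elution conditions on a second, reference, chromatographic column. The
augmented form treats a measurement on another column as one more
descriptor: two columns run under identical gradients see correlated
physicochemical driving forces, so t_R(R) carries signal that no
computed descriptor reproduces, and its coefficient b quantifies the
between-column retention transfer. All parameters are estimated by
ordinary least squares.

### Intercept policy

The canonical model forms carry no constant term, and the library default
is therefore `include_intercept=False`. Statistics packages typically add
a constant by default, however, and published coefficient tables produced
with such software may implicitly contain one. `include_intercept` is an
explicit flag on every fitting entry point, and the CLI prints a one-line
note whenever it fits without one. The synthetic-data recovery studies
fit *with* an intercept, because the generator shifts retention positive
by a constant offset (below) which the no-constant form would otherwise
alias into the slopes.

## Estimation and inference

OLS is solved through a QR decomposition of the design matrix — never by
inverting the Gram matrix. Rank is judged against a tolerance of
`max(n, p) · eps` times the largest singular value; a deficient design
raises an error naming the columns that are linearly dependent on their
predecessors (found by a greedy rank scan). Coefficient standard errors
use the unbiased residual variance SSE/(n−p) and the diagonal of
(XᵀX)⁻¹ computed from the R factor; p-values are two-sided from the t
distribution with n−p degrees of freedom. A numerically perfect fit
(SSE ≈ 0 relative to ‖y‖²) is flagged `degenerate`: SEs are reported as
0 and p-values as 0 rather than from a zero-variance t distribution.

Model quality is reported as the field's triple, all in minutes:

* average absolute error, mean |observed − predicted|;
* maximum absolute error;
* SEE, the standard error of the estimate, sqrt(SSE/(n−p)).

SEE is the model-selection criterion: among models of the same data, the
one with the smallest SEE is preferred. The "±" attached to each
coefficient is one standard error.

## Forward selection

`forward_select` implements the Forward entry procedure: at each step
every not-yet-entered candidate is refitted in the enlarged model, and
the candidate with the smallest two-sided coefficient p-value enters iff
that p is *strictly* below the entry threshold alpha (default 0.05).
Selection stops when no candidate qualifies, when the pool is exhausted,
or at an optional `max_terms` cap. For one added variable this p is
numerically identical to the probability-of-F-to-enter criterion
(t² = F). Design choices:

* ties on the smallest p break by larger |t|, then earlier column order
  — determinism; exact ties are measure-zero on continuous data;
* no removal step (Forward, not Stepwise);
* candidates that would make the design rank deficient at a step are
  ineligible at that step only and logged, not dropped for good;
* once the current model fits perfectly (SSE ≈ 0) selection stops:
  no candidate can reduce SSE and entry inference is undefined;
* forced variables (the reference term in augmented forward fits) enter
  first, unconditionally, flagged `forced` in the trace; the p<alpha
  invariant applies only to competitive entries.

The strict-less-than reading of the entry rule is deliberate; the
boundary case p = alpha does not enter.

### The fixed-descriptor augmentation recipe

The default way to build an augmented model mirrors standard QSRR
practice: forward-select descriptors for the classic model first, then
refit those same descriptors in enter mode with the forced reference
term, rather than re-selecting from scratch. Free forward re-selection
after the forced reference is available (`mode="forward"`). Near-zero,
insignificant descriptor coefficients that survive into the augmented
refit are retained, not pruned — the recipe reproduces the fixed model
form, not a re-optimised one.

## Descriptors

`compute_descriptors` is strictly 2D: descriptors are computed from the
molecular graph with RDKit, with no geometry optimisation or conformer
generation, so results are bit-reproducible. All ~210 registered RDKit
2D descriptors are available, plus an explicit name map for the
CDK-style names common in QSRR work:

| name | implementation |
| --- | --- |
| tpsaEfficiency | TPSA / molecular weight (fractional-PSA definition) |
| XLogP | Crippen MolLogP — nearest available computed logP, an approximation |
| nA / nAcid, nB / nBase | SMARTS counts of acidic / basic groups |
| nR | ring count |
| nHBAcc, nHBDon | H-bond acceptor / donor counts |
| C2SP3 | sp³ carbons bonded to exactly two carbons |
| khs.sNH2 | E-state –NH₂ fragment count |
| MDEC.33 | molecular distance-edge index over tertiary-carbon pairs |

Unmapped names raise an error naming the offender; nothing is silently
approximated. Because descriptor pools differ across toolkit versions,
competitive forward selection over "all" on real data can select
different (collinear) descriptors than another backend would — enter
mode with a printed descriptor list is the robust reproduction path.

`clean_matrix` removes zero-variance columns always, and columns with
any missing value by default (keeping the solute count fixed);
mean/median imputation is available but off by default. A-priori
descriptor tables (e.g. pKa₁, pKa₂, logP from an external prediction
service) load from delimited text with provenance `user-supplied`; the
package never predicts pKa or logP itself.

## Synthetic data generator

`simulate_dataset` draws a descriptor matrix of `n_descriptors` columns
(two thirds continuous, N(0, 1.5²); the last third small-integer Poisson
counts with mean 2, mimicking count-valued MDs), picks a small active
subset, and generates

    t_R(R) = Σ cᵢ·MDᵢ + ε_R        (shared-signal mode)
    t_R(A) = Σ aᵢ·MDᵢ + b·t_R(R) + ε_A

with independent Gaussian noise. Both columns are then shifted positive
by constants — never truncated — so every generative slope remains
exactly recoverable; the intercept of a constant-included fit absorbs
the offsets. The default configuration, used as the study conditions by
the test bench and the acceptance script, is n = 200 solutes, 30
descriptors, 3 active (coefficients 1.2, −0.8, 0.5), b = 0.8, noise SD
0.3 min on both columns. These sizes keep a 200-replicate recovery study
in seconds while giving per-replicate SEs small enough that recovery is
a sharp test.

Two deliberate corner cases:

* with `reference_model="independent"` the reference carries no
  descriptor signal — the null configuration for "does b stay at 0";
* at zero reference noise the shared-signal reference is an *exact*
  linear combination of the active descriptors, the augmented design is
  rank deficient, and the fit correctly refuses; exact zero-noise
  coefficient recovery is therefore exercised with an independent
  reference.

What the generator does **not** emulate: chromatographic physics
(gradient shape, pH transitions), heteroscedastic or non-Gaussian
retention noise, missing retention values, and realistic inter-descriptor
correlation structure. Passing recovery tests therefore demonstrate the
statistical machinery, not chromatographic validity on real data.

`paperlike_fixture` packages two deterministic synthetic datasets shaped
like the field's benchmark designs — 94 HILIC solutes in seven chemical
groups (13 sugars, 33 amino acids, 21 acids, 14 nucleonic
bases-nucleosides, plus small vitamin/alkaloid/amide groups) with
Amide/Bare-Silica columns, and 8 tryptophan-pathway solutes with three
a-priori descriptors across eight column×gradient conditions. Values are
synthetic; only shapes and vocabulary follow the benchmarks, so these
fixtures validate code paths, not published numbers.

## Numerical choices and limitations

* Units are minutes throughout; no unit conversion layer.
* Fit metrics are training-set metrics; a holdout split is not applied
  by default because the canonical workflow reports calibration quality.
* Group models require a minimum group size (default 4) and skip
  undersized groups with a warning.
* Model JSON serialises coefficients at full float precision; reloaded
  models predict bitwise identically.
* Forward selection at alpha = 0.05 over ~27 inactive candidates admits
  false entries at the usual multiple-testing rate: exact active-set
  recovery under the default study conditions is ~0.2 (frozen as a
  regression value), while recovery of b and the active coefficients
  within 3 SEs exceeds 99%. This is a property of the Forward procedure,
  not a defect of the implementation — the exhaustive-oracle equivalence
  tests pin the implementation itself.
* Robust/weighted regression, regularised or information-criterion
  selection, and prediction intervals are out of scope.
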