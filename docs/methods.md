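# Methods

## The buffering model

`genebuffer` treats the phenotypic effect of an allele as a partitioning
process: a measured trait (colony area, cell count, fluid volume in the
vessel analogy) splits between an observable **transfer** compartment and a
hidden **buffer** compartment. Five equivalent parameters describe the
split — the transfer fraction ŧ (mutant trait relative to the reference),
the buffer fraction b = 1 − ŧ, the ratios T = ŧ/b and B = b/ŧ, and the
buffering angle α, the polar angle of the point (ŧ, b) on the line
ŧ + b = 1. Any one determines the other four (`params` module). T and B
live on a ratio scale but are undefined at perfect buffering (ŧ = 0) and
perfect transfer (b = 0) respectively; we represent those as an explicit
`UNDEFINED` sentinel whose arithmetic raises, because silently propagating
NaN would erase a biologically meaningful state (e.g. a lethal double
mutant has B undefined, not missing).

The angle covers the whole spectrum without discontinuities:
amplification (−45°, 0°), moderation (0°, 90°), inversion (90°, 116.57°],
inverted amplification (116.57°, 135°). α = −45° requires |ŧ| → ∞ and is
enforced as an open bound; α = 135° is the cos α + sin α = 0 singularity —
reachable as an angle input's limit but mapped to a `DivergenceError` when
converting back to ŧ (equivalently, B = −1 has no finite ŧ). Both branch
formulas for α collapse to `atan2(b, ŧ)` on the constraint line; the test
suite checks this equivalence on a 1,000-point grid and the round trip
ŧ → α → ŧ to 1e-9.

## Growth families and time

Three trajectory families are implemented (`growth`): linear x₀rt,
quadratic x₀rt², exponential x₀e^{rt}. For the polynomial families the
transfer fraction of a mutant is the rate ratio, constant in time, so a
fitness measured at any time is a valid ŧ. For exponential growth
ŧ(t) = e^{(r_mut − r_ref)t} decays, and scalar summaries require an
explicit evaluation time. The cumulative (integrated) phenotype uses
closed forms checked against adaptive quadrature at 1e-6 relative error;
the r = 0 exponential degenerates to x₀·Δt. Time dilation
t_mut = (t_wt^n / ŧ)^{1/n} applies to polynomial degree n ≥ 1 and requires
ŧ > 0 (an inverted phenotype never reaches the wild-type value). Negative
rates are allowed throughout; the parameter algebra accepts the resulting
ŧ < 0.

## Neutrality models

Two mutually exclusive rules predict a multi-mutant's state when alleles
act independently (`neutrality`): **serial** (one process feeds the next;
ŧ values multiply) and **parallel** (simultaneous action on a shared
input; B values add, so ŧ_exp = 1/(Σ 1/ŧᵢ − (k−1))). Both are
permutation-invariant and fold pairwise. On (0,1]² the parallel
expectation strictly dominates the serial one, with equality only when a
cofactor is neutral — the origin of the opposite residual biases the
pipeline detects. For exponential growth the serial rule gives a constant
rate r₁ + r₂ − r_ref, while the parallel rule gives a genuinely
time-varying trajectory N(t) = x₀e^{r_ref t}/(e^{(r_ref−r₁)t} +
e^{(r_ref−r₂)t} − 1), returned as a callable rather than a scalar. In the
SGA context, colony area scales linearly with both time and per-mutation
fitness, so the serial rule and the classical multiplicative "product"
model coincide and single-mutant fitnesses are used directly as ŧ values.

## Interaction scales and classification

Deviation from a neutrality expectation is expressed as a relative error
(`scales`): ε_parallel = (B_cd − (B_c + B_d))/(B_c + B_d) and
ε_serial = −(ŧ_cd − ŧ_cŧ_d)/(ŧ_cŧ_d), oriented so aggravating
interactions are positive on both scales. Landmarks mark where the double
mutant matches the weaker/stronger single. Classification delegates
significance to caller-supplied q-values (default threshold 0.05, a
conventional FDR level; the scale itself prescribes none): non-significant
→ neutral (additive or multiplicative by model); significant positive →
aggravating, with sub-label synthetic-lethal when ŧ_cd ≤ a configurable
lethality floor (default 0.01 of wild-type fitness — "not observably
greater than zero" needs an operational cut-off and 1% of wild type is
below typical colony-size measurement resolution) and synthetic-sick
otherwise; significant negative → ameliorating, flagged as suppression
when the double mutant outgrows the fitter single. Buffering capacity is
quantified as the angular range max(0, α_observed − α_expected): variation
invisible in the intact background that the partner's loss exposes.

## The SGA residual pipeline

`sga` operates on plain pandas DataFrames with canonical columns
(`query_id, array_id, f_query, f_array, f_double, sd_double`); a column
map adapts foreign headers and incomplete rows are dropped and counted.
Stages: expectations under both models (non-positive fitness ⇒ parallel
expectation NaN, flagged not failed); per-cross two-tailed tests of
(f_double − f_expected)/sd_double with Benjamini–Hochberg correction
within each model family (statsmodels); filtering; standardized residuals
with scale s = √(Σ(obs − exp)²/(n − 2)) estimated once per model over the
filtered set; a per-cross hybrid that keeps whichever prediction has the
larger q (ties to serial, the incumbent model; configurable); summaries
(median, mean, P(x ≤ 0)) and two-sample Cramér–von Mises comparisons
(scipy).

**Null reference.** The per-cross test uses a standard normal on the
scaled deviation by default. A Student-t reference of caller-chosen
degrees of freedom is exposed (`df_t`), but replicate counts are not part
of the input schema, so no defensible default df exists.

**Filter design.** Crosses are kept when both single fitnesses lie in the
closed band [0.1, 0.9] — outside it the two models' predictions converge
and carry no signal — and when the q-value strictly exceeds 0.5, removing
crosses any model already rejects (plausible true interactions) from a
bias estimate that assumes neutrality. Each model's residuals are
computed on the set retained by *its own* q: conditioning the serial
residuals on the parallel model's q (or vice versa) selects measurement
noise pointing in the rival model's direction and manufactures a bias
even in pure-null data — a selection artifact we verified directly on
simulations with a single generating model, where joint-q filtering
shifts the true model's residual mean off zero. The hybrid set uses the
per-cross larger q. A conservative shared set (all q's above threshold)
is also counted and reported for comparability with single-number
retained-cross bookkeeping. The q filter is skippable (`q_min=None`),
which is the right choice for noise-free synthetic data: with zero
measurement dispersion every per-cross sd is 0 and no q family exists.

## Synthetic data

`simulate` draws cross tables with known ground truth: single fitnesses
uniform on [0.1, 0.9] (the informative band, so the default filter keeps
everything and test resolution is maximal); each cross is serial or
parallel with probability `frac_parallel` (default 0.5); a fraction
`frac_epistatic` (default 0) is perturbed on the serial ε scale by a
sign-symmetric half-normal of scale 0.5 — an acknowledged placeholder, as
real interaction-effect distributions are not characterized here; additive
Gaussian noise (default sd 0.05 fitness units, the order of SGA colony
fitness measurement error) truncated at zero; reported per-cross sd
scattered lognormally (σ = 0.2) around the true noise sd. One
`numpy.random.default_rng(seed)` stream makes tables byte-reproducible.
What the generator does **not** emulate: plate spatial effects, batch
structure, linkage, shared single-mutant fitnesses across crosses of the
same gene, and non-Gaussian error tails — passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real SGA artifacts.

The bias-recovery experiment (default n = 20,000 crosses, a size where
the directional effects exceed sampling noise by a wide margin while the
full pipeline runs in about a second) reproduces the qualitative
signature: serial-model residual mean positive, parallel negative, hybrid
nearest zero, with pure-single-model controls centered at zero within
3/√n.

## Diagrams

`diagrams` builds genotype trees of serial layers (single allele or
parallel pair, combined via B-summation). Transfer fractions multiply
down the vertical path; at every horizontal level the accumulated buffer
compartments plus the running transfer sum to exactly 1 (checked to
1e-9). Observed (epistatic) values attach in brackets beside the neutral
expectations — kept separate so the expectation stays auditable — and
`validate` reports them as informational discrepancies, distinct from
conservation violations. Exports: a bespoke DOT emitter (circles for
genes, filled = functional; boxes for compartments; red/green edge color
marks observed-vs-neutral paths) and JSON with an exact re-import
round-trip. Parallel pairs re-imported from JSON carry placeholder equal
splits of the combined B; conservation and re-export are unaffected.

## Numerical conventions

- Printed-value comparisons in tests use absolute tolerance 5e-3 (sources
  of such worked values round inconsistently, e.g. 0.429 vs 0.428 for the
  same quantity); angles printed to one decimal are compared at 0.05°.
- Exact conservation identities (ŧ + b = 1, T·B = 1, level sums, vertical
  products, round trips) are held to 1e-9.
- `state_from_angle` snaps cos/sin below 1e-15 to zero so 90° yields
  exactly ŧ = 0 (and B exactly UNDEFINED) rather than ŧ ≈ 6e-17.
- Hybrid ties and NaN q: equal q's choose serial; a NaN q (undefined
  parallel expectation) never beats a finite one.
- Residual scale s = 0 (every cross exactly on the model) returns all-zero
  residuals instead of 0/0.

## Known limitations

- The full-scale supplement analysis (~6.6M crosses) is an optional job
  (`scripts/costanzo_job.py`) requiring the user-downloaded file; its
  default column map is a best-effort guess at that export's headers and
  should be overridden via config if they differ.
- No uncertainty propagation on buffering parameters (point values only).
- No "min"/"additive-in-fitness"/"log" neutrality models, no aggregation
  of ε into network statistics, no inference of pathway order from data.
- ε on time-varying exponential-parallel expectations requires the caller
  to fix an evaluation time; no canonical time is imposed.
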