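# Methods

## pH-stat degree of hydrolysis

The pH-stat estimate counts protons released by peptide-bond cleavage
via the base consumed to hold the system pH constant:

    DH% = 100 · (C · V) / (a · m · h_tot)

with C the titrant concentration (mol/L), V its volume (mL) — so C·V is
millimoles of base — m the protein mass (g) and h_tot the substrate's
peptide-bond content (mmol/g; 7.35 is the conventional value for corn
protein and the CLI default). The dissociation degree of the newly
exposed α-amino groups, a = 10^(pH−pKa)/(1+10^(pH−pKa)), corrects for
the fraction of released protons actually titrated. The α-amino pKa is
temperature-corrected as pKa(T) = 7.8 + 2400·(298−T)/(298·T), the
standard pH-stat form anchored at 7.8 at 298 K. A variant with the sum
denominator (298+T) is selectable (`formula_variant="paper-literal"`)
because it circulates in parts of the literature, but it yields
physically impossible pKa values away from ambient temperature (≈ −89
at 323 K) and is never the default.

## Initial rates from progress curves

ADH activity is read from an A340 progress curve (NADH formation,
typically sampled every 10 s for 10 min). The initial rate is defined as
the analytic first derivative at t = 0 of a least-squares-fitted curve;
the default family is the quadratic polynomial A(t) = a0 + a1·t + a2·t²
(captures early-time curvature of a saturating curve while keeping the
derivative exact and the fit linear), with linear and single-exponential
(A(t) = a0 + amp·(1−e^(−kt)), rate amp·k) alternatives. Rates are
reported in AU/min regardless of the trace's declared time unit. The
activation, inhibition and scavenging percentages are plain ratio
statistics; they are invariant to uniform rescaling of all absorbances
in a record and are deliberately *not* clamped at zero, since
sub-control samples are meaningful (inhibition instead of activation).

## Box–Behnken fitting and ANOVA

The 3-factor Box–Behnken design is the 12 edge midpoints of the coded
cube (one factor at 0, the other two at ±1) plus replicated centre runs
(5 by default, matching the bundled 17-run dataset). Factors are coded
so that regression coefficients are comparable; on this design the
linear and interaction columns are mutually orthogonal, which gives two
useful identities used as test oracles: each linear coefficient equals
(ΣY at +1 − ΣY at −1)/8, and each linear term's partial SS equals
8·coefficient².

The full ten-term model is fitted by OLS. The ANOVA reports *partial*
(drop-one-term refit) sums of squares per term — the convention of
response-surface software — so the quadratic-term SS, whose columns are
not mutually orthogonal, do not add up to the model SS; that
non-additivity is expected and asserted in the tests. Pure error is
pooled within replicated coded points, lack of fit is the remaining
residual, F statistics use the full-model residual mean square (the
pure-error mean square for the lack-of-fit F), and p-values come from
the F survival function, displayed as "<0.0001" below that threshold to
match common print conventions. Fit statistics: R² = model SS/total SS,
adjusted R², and CV% = 100·√(residual MS)/grand mean. When a design has
no replicates the report is produced without the lack-of-fit split,
with a warning. Run order never matters; designs are compared as
multisets and responses matched by name.

## Desirability optimization

Multi-response optimization uses Derringer–Suich desirabilities: each
response is mapped to d ∈ [0, 1] by a linear ramp between anchors
(default: the response's observed minimum and maximum in the design, so
the best observed value scores 1), direction maximize or minimize, and
the overall objective is the weighted geometric mean D = (Π dᵢ^wᵢ)^(1/Σwᵢ),
equal weights by default. D is maximised over the coded cube by a
deterministic multi-start: bounded L-BFGS-B from the 27-point {−1,0,1}³
grid, keeping the best converged point. The argmax is invariant to
rescaling all weights by a common factor (asserted).

A known limitation, documented rather than patched: on the bundled corn
dataset this default objective has its global optimum at coded
(0.01, 0.10, 0.22) with D = 0.808, whereas the study that produced the
data reported an optimum at coded (0.40, 0.07, −0.01) where D = 0.770 —
a point that is not even a local optimum of the equal-weight objective,
and no non-negative re-weighting makes it stationary. The commercial
software settings behind the reported point were not published; the
package keeps the principled default rather than reverse-engineering
them. Predictions *at* the reported point are unaffected and reproduce
the study's values.

## Peptide properties and screening

Residue average and monoisotopic masses come from pyteomics' standard
amino-acid compositions; a peptide's mass is the residue sum plus one
water (additivity asserted on random sequences). Net charge is the
Henderson–Hasselbalch sum over positive groups (N-terminus, K, R, H)
and negative groups (C-terminus, D, E, C, Y); the default pKa set uses
textbook side-chain values (D 3.65, E 4.25, C 8.18, Y 10.07, H 6.00,
K 10.53, R 12.48) with termini 9.0/3.55, all overridable. Because every
sequence has both termini, the charge is strictly decreasing with a
guaranteed sign change on [0, 14], and the isoelectric point is found
by bisection (tolerance 1e-4 pH). Different published pKa sets move a
peptide's pI by a few tenths of a unit, so cross-tool agreement is
tolerance-based by design.

The screening funnel applies strict-inequality stages in order:
computed or observed mass < 1000 Da, ALC > 80 %, peak area > 10⁵,
external bioactivity score > 0.5, non-toxic, soluble. The bioactivity
threshold default of 0.5 reflects common practice of taking 0.5 as the
"likely bioactive" boundary for ranker scores; all thresholds are
configurable. External predictors are third-party tools, so the funnel
takes their outputs as record fields or from a pluggable score provider
and never re-implements them. Since each stage is an independent
predicate, the survivor set is invariant to stage order and record
order; only the per-stage attrition counts depend on order. The
missing-data policy is strict by default (a record lacking a field
needed by a stage raises an error naming record and field); a lenient
mode passes such records through the stage with a warning. The observed
MS mass takes precedence over the computed mass because de-novo lists
can carry masses not derivable from the reported sequence (the bundled
dataset's LMFP, printed at 928 Da against a computed 506.7 Da, is such
a case).

## Synthetic data

The generators emulate the study conditions: progress curves sampled
every 10 s for 10 min (61 points) from a quadratic ground truth
(default rate 0.02 AU/min, curvature −0.0005 AU/min², baseline 0.1 AU)
with Gaussian noise (default σ 0.002 AU, a realistic plate-reader
noise floor); Box–Behnken response tables drawn from known ten-term
surfaces plus Gaussian noise; and peptide tables in which a planted
subset satisfies every funnel stage with margin while every decoy is
forced to fail at least one randomly chosen stage (other fields drawn
from the passing distributions, so decoys are not uniformly bad). All
randomness flows through NumPy's PCG64 `default_rng(seed)`, making
outputs bit-reproducible for a fixed seed. What the generators do not
emulate: correlated measurement drift within a trace, non-Gaussian
assay error, realistic amino-acid composition biases, or any coupling
between a sequence and its planted scores — so passing recovery tests
demonstrates correctness of the estimators under the stated noise
model, not robustness to real instrument pathologies.

## Numerical choices

OLS via `numpy.linalg.lstsq` with an explicit rank check; SS
decomposition identities hold to 1e-6 relative and are asserted.
Coefficients are displayed at 2 d.p. and R² at 4 d.p. (print-precision
parity with published tables) while full precision is kept internally.
The bisection bracket [0, 14] is validated before solving; degenerate
inputs (zero protein mass, equal XOD controls, non-positive control
rates, duplicate trace times, rank-deficient designs) raise typed
errors rather than returning NaN. Analysis problem sizes used
throughout the tests — 100 seeds for rate-recovery and
coefficient-sampling checks, 200 seeds for the null-p-value
calibration, 100-record screening tables — are chosen to make Monte
Carlo standard errors small relative to the asserted tolerances.
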