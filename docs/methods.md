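# Methods

This note documents the models and procedures implemented in `typeslip`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not establish.

## Error identification

Typed text is compared with its stimulus after keyboard normalization:
capitals, accented characters and shifted symbols fold to the primary
character of the key that produces them (`A → a`, `ç → c`), so a shifted or
accented rendering of the right key is never counted as an error.
Backspace handling is configurable: `resolve` (default) applies each
backspace so the final on-screen string is analysed — participants could
see and correct their output, so the resolved string is what they accepted
— while `literal` keeps every typed character. Interkey intervals are
timestamp differences within a sentence, computed after correction
handling; the first keypress of a sentence has none.

Alignment is global Needleman–Wunsch with match +1, substitution −1,
gap −2. The traceback tie-break prefers diagonal over deletion over
insertion; any fixed order gives a valid optimum, this one is conventional
and makes outputs byte-reproducible. Token pairing walks the alignment
backwards, cutting a boundary at every target-side space aligned to a real
typed character; a deleted space therefore merges its flanking words into
one token, whose single first mismatch is the scored error. The error of a
mismatching token is its first non-matching column: a substitution yields
typed and target characters; a deletion yields a record with no typed
character (and no keypress, hence no IKI); a pure-insertion first mismatch
yields no target character. Records missing either character cannot be
scored by the classification rules and are labelled `other`.

The habit context is the four characters *of the intended sentence*
preceding the error. The intended context is well defined even when the
preceding typing contained errors; the typed-side context is stored too and
can be selected (`context_source="typed"`) for sensitivity analyses.

## Keyboard model

Layouts are flat grids: integer rows, unit-spaced columns, no horizontal
stagger; the space bar is a single key at the centre of the bottom row.
"Adjacent" means Chebyshev distance 1, which realizes diagonal adjacency
exactly on an unstaggered grid; adjacent keys are at distance 1 by fiat,
all other pairs at Euclidean grid distance. Characters absent from a
layout are placed at the mean key position, so every distance query is
total; two unknown endpoints give distance 0. UK-QWERTY and Spanish-ISO
QWERTY layouts ship as editable TSV data files; the true physical
geometries (including row stagger) are deliberately approximated, and any
alternative can be supplied as data.

## Character language model

Habit strength is supplied by an order-5 character model with Witten–Bell
interpolated back-off:

    p(w | c) = (n(cw) + T(c) · p(w | c′)) / (N(c) + T(c))

bottoming out in a uniform distribution over the vocabulary. Witten–Bell
was chosen because it is robust for character models estimated from small
corpora and has no tuned discount constants; the classifier only *compares*
two probabilities under the same model, which is insensitive to the exact
discounting for well-observed contexts. The smoothing scheme is recorded on
the model object. Training normalizes per line: lowercase, whitespace
collapsed, digit-only lines dropped, diacritics preserved, and `order − 1`
start symbols per line, so short contexts are sentence-start contexts.
Out-of-vocabulary characters receive the residual-uniform floor
(≈ T/(N+T) · 1/|V| at the unigram level) rather than zero, so comparisons
against unknown typed characters remain defined. Models round-trip through
the ARPA format (start-symbol contexts are written with the conventional
dummy probability so their back-off weights survive), making externally
built models drop-in replacements.

The packaged training corpora are original English and Spanish prose
(~70 sentences per language) shipped as plain text. They are small; the
habit statistic only needs stable *relative* probabilities of common
continuations, which character 5-grams reach quickly, but rare-context
estimates are correspondingly coarse. Any larger corpus can be used via
`typeslip train-lm`.

## Classification rules

Both rules are strict inequalities, so ties fall through: motor requires
the typed key strictly closer to the previous key than the intended key is;
habit requires the typed character strictly more probable than the intended
one; otherwise `other`. The motor rule is applied first and masks the habit
rule. An error with no previous keypress skips the motor test. All four
intermediate quantities (two distances, two probabilities) are stored per
error, so every label is auditable row by row.

Rates: `motor_rate = n_motor / n_errors`;
`habit_rate = n_habit / (n_errors − n_motor)`, undefined when every error
was motor. Errors removed by the IKI filter are removed from everything,
rates included (a flag retains them for rates only).

## IKI filtering and summaries

The long-pause filter computes, per language, the 99.5th percentile
(linear-interpolation quantile) of correct-keypress IKIs and removes every
keypress — correct or errorful — with IKI **≥** the threshold. A
percentile of 100 disables filtering. The filter result carries its
thresholds, and re-filtering that object reuses them, so filtering composes
idempotently. Correct keypresses are alignment-matched columns; keypresses
after the error within a mismatching token belong to neither category.
Summaries report per-participant mean IKIs in seconds, both error rates,
and metadata; controls whose UPDRS falls in the patient range (at or above
the cohort's minimum patient score by default) can be excluded, mirroring
standard cohort hygiene.

## Statistical stage

*Mixed ANOVA.* The 2×2×2 design (keypress type within; group and language
between) is computed by the exact split-plot decomposition available when
the within factor has two levels: between-subject effects are the Type II
ANOVA of each subject's mean over the two types; within effects are the
Type II ANOVA of each subject's difference, with the keypress-type main
effect as the effects-coded intercept test. On balanced data this
reproduces `aov(y ~ A*B*W + Error(subject))` exactly (cross-checked against
R in the test suite); on unbalanced data Type II sums of squares are used
and reported as such.

*Nested regression.* Mean error IKI is regressed on group, habit rate,
motor rate and language; each term's significance is the F comparing the
full linear model against the model without that term (equal to the squared
t of a single dropped coefficient).

*Poisson GAM.* UPDRS (a non-negative integer score) is modelled with a log
link and penalized B-spline smooths (basis dimension 10 per smooth by
default, scaled down for small cohorts; ridge penalty weight selected per
smooth) of mean correct IKI, mean error IKI, motor rate and habit rate,
plus language as a factor. Fit is compared across predictor subsets by
AIC; percent deviance explained is reported against the intercept-only
Poisson model. The implementation is statsmodels `GLMGam`; on data
simulated from a log-linear Poisson truth the fitted smooth is near-linear
and the AIC matches the GLM within a few units (tested).

*ROC / DeLong.* The diagnostic score is the GAM-predicted UPDRS on the
response scale; positive class is patient. The reported AUC is the
Mann–Whitney rank statistic (midranks for ties), identical to the
threshold-sweep curve's area to 1e−10 (tested). CIs are percentile
bootstrap over participants (2000 resamples, seeded; resamples that lose a
class are redrawn). Paired model comparisons use DeLong's
structural-components test, cross-checked against `pROC::roc.test` to
1e−8. Identical score vectors return p = 1. No multiple-testing
correction is applied across the ANOVA/regression terms.

## Synthetic cohorts

Each simulated typist draws a personal IKI median (log-normal around the
profile median, log-sd `iki_between_sd`) and a personal mechanism mix
(log-normal jitter, sd `mix_jitter_sd`) — between-participant heterogeneity
matching the spread of published per-group summaries. Keypress IKIs are
log-normal (within-typist log-sd `iki_log_sd`); errorful keypresses are
slowed by `error_slowing`. Each keypress errs with probability `p_error`
(0.04 controls, 0.05 patients — a realistic copy-typing error rate that
yields ~50–60 errors per typist over 15 sentences) by one of three
mechanisms: **motor** (uniform adjacent key, excluding the target),
**habit** (the language model's argmax given the four-character target
context; if the argmax *is* the target the draw falls back to uniform and
is recorded as such), or **uniform**. With `speed_coupling > 0` the habit
mechanism's odds are multiplied by `1 + speed_coupling` on keypresses
faster than the profile's nominal median; because typists themselves vary
in speed, this produces both within-typist (fast keypresses slip more) and
between-typist (fast typists slip more) habit–speed gradients, the latter
detectable by regression at n = 60 (tested). UPDRS is Poisson with the
profile mean (0.85 controls, 13.15 patients), patient draws truncated below
20 to match early-stage inclusion.

The four packaged profiles were calibrated once (`scripts/
calibrate_profiles.py`): a response matrix P(label | mechanism branch) is
estimated from pure-mechanism cohorts, a linear solve maps target rates to
nominal weights, and bias-corrected re-solves against full-pipeline
measurements refine the mix, IKI median and slowing until the
pipeline-measured cohort means match the published per-group motor rates,
habit rates and mean IKIs (final residuals, measured over 60 independent
seeds, are recorded in `data/profiles.json`). Calibration targets
*measured* rates precisely because classifier confusion makes mechanism
weights and measured rates differ.

### What recovery can and cannot show

Label–mechanism agreement has a structural ceiling set by keyboard
statistics, not by any tunable parameter. About 20% of English stimulus
bigrams (16% Spanish) place the intended key within grid distance 1 of the
previous key; a motor-mechanism error at such a position ties the strict
motor inequality and must fall through to `other`. Conversely the habit
mechanism's argmax continuations (`e→r`, `e→s`, `e→d`, …) are frequently
adjacent to the previous key on QWERTY — QWERTY puts many frequent bigrams
on neighbouring keys — so the motor rule, applied first, captures a
substantial fraction of habit-mechanism errors. Measured per-mechanism
agreement on default cohorts is therefore ≈ 0.75–0.80 for motor and ≈ 0.6
for habit. What *is* exact is tested exactly: decidable motor errors
(target beyond distance 1) are always recovered, tied ones never are, and
the measured habit rate is strictly monotone in the generated habit weight.
The same masking necessarily operates in real data: measured habit rates
under this rule order are conservative under-counts of habit-driven
errors, which biases group comparisons toward zero rather than creating
spurious differences.

The generator produces substitution errors only (no insertions, deletions
or corrections), a single error mechanism per keypress, and no fatigue,
learning or medication dynamics. Pipeline results on synthetic cohorts
therefore validate the machinery — alignment bookkeeping, rule
implementation, rate definitions, statistical calibration — and the
direction and approximate size of group differences under the assumed
generative structure; they are not evidence about real typing beyond that
structure.

## Numerical and reproducibility choices

Timestamps are integer milliseconds; IKIs are reported in ms and converted
to seconds only in summary tables. The DP fill is numba-compiled (pure
NumPy fallback); alignment, simulation and analysis are deterministic given
seeds, and every report embeds its seed. Simulation scale in the
verification suite — 20-seed cohorts at published cohort sizes for the
calibration checks, 100 seeds for directional checks — was chosen to keep
Monte-Carlo error well inside the tolerances being asserted.

## Known limitations

- Grid layouts ignore physical row stagger and key sizes; distances are
  approximations everywhere except the adjacency relation itself.
- The habit statistic inherits the training corpus; the packaged corpora
  are small original-text stand-ins, adequate for frequent character
  contexts only.
- First-mismatch scoring records at most one error per token; dense
  multi-error tokens are under-counted.
- The ANOVA uses the two-sub-model decomposition, exact only because the
  within factor has two levels; designs with more within levels are out of
  scope.
- The ROC analysis is in-sample, as in the original design; no
  cross-validation is attempted.
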