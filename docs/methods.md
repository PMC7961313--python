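# Methods

## Problem setting

An integrated health system records every arthroplasty as a CPT-coded
procedure with free-text fields for the scheduled procedure, the post-op
diagnosis, and the prosthesis model (part numbers typed by OR staff).
`implantreg` turns those records into an implant registry: one *episode* per
implanted major component (acetabular shell, liner, femoral stem, prosthetic
femoral head) running from implantation to removal or censoring, and
per-model Kaplan-Meier survivorship on top of the episodes. Because no such
extract is public, the package pairs the pipeline with a synthetic EHR
generator whose ground truth makes every pipeline loss and bias measurable.

## The synthetic cohort model

**Demographics and volume.** Patients receive one primary THA each; surgery
year is drawn from a per-year volume curve (default: a ramp from ~360 to
~3750 procedures/year over 2000–2017, mirroring the adoption pattern of a
large male-dominated system), sex is male with probability 0.947, age is
N(63.7, 10.1²) clipped to [21, 99]. Defaults reproduce the published
characteristics of the motivating cohort; they are reporting-only and feed no
estimator.

**Components.** A primary places shell + liner + stem + head, except for
monoblock shells (shell and articulating head as a single part number),
which occupy both the shell and head classes. Femoral-head material follows
a logistic ceramic-adoption curve P(ceramic|year) = 1/(1+exp(−(y−2015.5)/2.49)),
calibrated so ceramic passes metal between 2015 (~45%) and 2016 (~54%).
Minor parts (screws, hole plugs) accompany 40% of primaries.

**Failure and revision.** Component failure times are Weibull with global
shape k = 1.5 (rising hazard, expressing mid-life wear-out; configurable
per model) and per-model relative scale `scale_rel` (0.25 = a 4× scale
disadvantage). The global base scale is not a free parameter: it is solved
(Brent's method) so that the expected fraction of primaries with at least one
component failure inside its true follow-up window equals
`revision_fraction/(1−revision_fraction)`, making the configured
`revision_fraction` (default 0.047) the expected revisions/(primaries+revisions)
burden. Revision-of-revision chains add a small second-order surplus to that
expectation. A failure triggers a revision on the failure date replacing the
failed component and, with probability 0.5, its articulating mate
(shell↔liner, stem↔head); with probability 0.02 the failure is instead
treated by a removal-coded surgery that explants everything. Replacement
components draw fresh failure times; chains are followed to the study end.

**Censoring.** Death is exponential from surgery at 0.03/year (a realistic
all-cause rate for a mid-60s surgical cohort); encounters recur at
exponential gaps (mean 180 d) from surgery until death or study end, and
every surgery date is also an encounter. With probability
`out_of_system_revision_rate` (default 0.15) a failure is revised elsewhere:
no revision record is written and the encounter stream stops the day before
the failure, so the pipeline censors the episode early — the generator's
mechanism for the known upward bias of EHR-only survivorship. Failure truth
is drawn on a random stream independent of the out-of-system decisions, so
toggling the rate compares estimates on identical underlying truth.

**Data-entry corruption.** Each part entry is independently subjected to,
in precedence order: missing field; entry written into a uniformly random
other surgery's field; and otherwise any combination of wrong-digit
substitution (the corrupted number is guaranteed absent from the catalog, so
it is detectably wrong), letter-case flip, and excess characters drawn from
{REF, LOT, #, *, parentheses, stray spaces}. Default rates are the observed
per-part frequencies in a published 100-case manual audit of such a pipeline
(missing 39/391, wrong record 14/391, excess characters 11/391, wrong number
5/391, legacy part 14/391, case 3/391); per-year overrides exist but default
to time-constant rates. Legacy substitution swaps the implanted model for one
absent from the catalog. One stem family's catalog category term deliberately
claims it is a femoral head, exercising the curated class-override path.

## Pipeline design choices

* **Cleaning preserves letter case.** Stripping noise tokens and illegal
  characters is the cleaner's job; case is the catalog's. An uppercase
  canonicalisation before lookup would make case errors unobservable and
  unfixable-by-audit, so `clean_part_number` returns the entered case and
  `lookup_part` tries exact match first, then a case-insensitive fallback
  recorded as `match_mode="case_insensitive"` (disable it to reproduce the
  historical case-letter loss at the mapping stage).
* **Unknown category terms classify as minor.** A silent false major part
  would corrupt survivorship; a missed one is a visible false negative.
* **Model aggregation** is first-6-characters with exact-number and prefix
  override maps; shorter numbers aggregate to themselves with a warning.
* **Side conflicts are unknown, never guessed**; unknown-side surgeries are
  excluded from linkage and counted.
* **Linkage** keeps the first of two same-class parts placed at one surgery
  (logging the duplicate), opens episodes at orphan revisions (primaries done
  elsewhere exist in real data), merges same-day same-side surgeries, and
  censors at death (reason `censored_dead`) or else at the last encounter
  bounded by the study end. Death never counts as implant failure.
* **Kaplan-Meier.** Ties between removal and censoring on one day follow the
  standard convention (removals first, censored components still at risk).
  Default CI is the exponential-Greenwood log(−log) transform, which respects
  [0, 1]; plain Greenwood is available via `ci_method="greenwood"`. Time is
  internal days, reported years at 365.25 d/y. Curves are fitted only for
  models with ≥ `min_uses` (default 100) episodes.
* **Stratification rule.** Verdict *worse* requires the model's upper CI
  bound to sit below the pooled comparator's lower bound at some evaluation
  time and at every later one (*better* symmetric); evaluation times are the
  union of both curves' event times where both arms keep ≥ `min_at_risk`
  (default 10) at risk. The rule is antisymmetric by construction. It is
  **not** monotone in `min_at_risk`: raising the floor truncates the noisy
  tail and can promote a non-persistent separation to a persistent one —
  that truncation is the floor's purpose.
* **Scoring.** A part is *fully identified* only if extracted from its own
  record ∧ mapped ∧ classified with the correct class. A mapped major-class
  entry in a surgery where that part was never implanted (a relocated
  number) is a false positive. Funnel stages compare the cleaned number
  case-insensitively (case repairs are audited at the mapping stage, where
  they belong); stage percentages carry Wilson score 95% intervals, computed
  from the closed form and cross-checked against statsmodels.

## Experiment sizing

The validation experiments are scaled for stable inference on one CPU:
end-to-end identity runs at 5000 patients; the designated-outlier experiment
uses ten uniformly used shell models at 7000 patients (~700 uses each, ~50
failure events in the outlier arm) so the persistence rule has support
through the follow-up horizon; the crossover-recovery experiment uses 15 000
patients so the two years adjacent to the crossing each contribute ~1200
identified heads (≈1.4% standard error against a 4–5 point year-on-year
gap). Twenty seeded replicates each.

## What the generator does and does not emulate

It reproduces the *error taxonomy* and *censoring structure* that determine
pipeline validity — not clinical realism. There are no bilateral or staged
surgeries, no comorbidity or site effects, no seasonal scheduling, no
free-text operative notes, and error rates are time-constant by default
although real capture improves as barcode scanning spreads. Passing tests
therefore demonstrate that the pipeline's logic is lossless where the record
is faithful and degrades accountably under the documented error modes; they
do not certify performance on any particular real EHR, whose error mix must
be audited separately (the validation module accepts a manual-review file in
the ground-truth schema for exactly that purpose).

## Numerical notes

Greenwood variance is set to 0 where S(t) = 0 (the formula is undefined
there); degenerate all-censored inputs yield a flat S ≡ 1 curve with
unit CI; the Wilson interval is clipped to [0, 1]; probabilities and counts
are validated at config parse time with the offending field named. All
randomness flows from one integer seed through independent named
SeedSequence streams (demographics / assignment / failure / out-of-system /
corruption / encounters), so a rerun with the same config is byte-identical
and single-mechanism toggles perturb only their own stream.
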