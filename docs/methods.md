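# Methods

`pbpcost` reproduces and generalizes a cost analysis of four robotic-surgery
training curricula with decreasing adherence to proficiency-based
progression (PBP): full PBP with a mandatory e-learning benchmark (G1),
e-learning without the benchmark (G2), traditional lectures (G3), and a
conventional apprenticeship (G4). This note records the model, the
calibration choices, and what the synthetic data do and do not show.

## Cost model

Each curriculum g has a per-trainee **variable cost**

    v_g = (lab day rate) × (billed lab days) + (hotel rate) × (nights),

with default rates of €2450 per person-day of laboratory time and €200 per
hotel night (the actual rates of the source training centre). The lab
invoices only full or half days, so billed days live on the half-day grid
{0.5, 1.0, …, 3.5}; training is capped at 3.5 days.

The metric-based curricula (G1–G3) additionally share a one-time **fixed
cost** F = €132 377 for metric development, validation and e-learning
content, amortized evenly: a per-trainee share F/N that falls as 1/N
(€11 031 at N = 12 down to €265 at N = 500). G4 carries no fixed cost.

Per-trainee cost at cohort size N is `v_g + F/N` for G1–G3 and the constant
`v_g` for G4; total cohort cost is affine, `N·v_g + F` (F charged once).
All arithmetic is exact — integer euro cents, `fractions.Fraction` after any
division — and display rounding is half-up to whole euros, applied only at
the output boundary. Half-up is the convention under which
132 377/12 → 11 031 and 132 377/500 → 265.

### Calibrating v_g

The source publication never states v_g directly; two calibration paths are
provided.

* `from_printed_per_trainee_at_12` (default): v_g is the published
  per-trainee cost at the 12-trainee anchor minus the *displayed*
  (whole-euro) amortized share at 12. This gives v₁ = 14 139 − 11 031 =
  €3 108, v₂ = €3 481, v₃ = €4 186 (the G2/G3 anchors being published group
  totals over 12: 174 144/12 and 182 604/12), and v₄ = €7 067 directly.
  Under this decomposition every published per-trainee figure reproduces
  exactly (G1: 14 139 → 5 756 at 50 → 3 373 at 500).
* `from_records`: v_g is the mean observed variable cost of a cohort of
  trainee records, rounded to the cent. Because published figures carry
  rounding, the two paths agree only approximately.

### Two "total cost" readings

The published figures are internally inconsistent at the euro level: the
12-trainee totals equal 12 × the rounded per-trainee cost (12 × 14 139 =
169 668), which differs by €5 from the exact affine total 12 × 3 108 +
132 377 = 169 673. The package therefore exposes both:

* `cost_model.total_cost` — the exact affine total (used for break-even
  sweeps and all algebraic invariants);
* the projection grid's `total_eur` — cohort size × display-rounded
  per-trainee cost, the reporting convention of the source analysis, under
  which the grid identity *total = size × per-trainee* holds exactly.

The two differ by at most half a euro per trainee (≤ 0.02 % at the sizes
reported). Published totals at 50–500 trainees carry a further ≤ 0.05 %
internal rounding drift and are only reproduced to within 0.1 %.

## Cost-equivalence point

On the linear model the curricula's totals cross at

    N* = F / (v₄ − v₁) = 132 377 / 3 959 ≈ 33.44 trainees,

so full PBP is strictly cheaper from integer cohorts of 34 up. The
closed-form solver is verified against a dense integer sweep of the exact
totals. The source publication reports an equivalence point of 24.98
trainees; that value is not derivable from any combination of its printed
costs (all decompositions we examined give ≈ 33.4), so the package reports
its own N* and records the discrepancy rather than matching the printed
number. Both the real-valued N* and the integer break-even cohort are
reported, since "N* trainees" and "cheaper beyond ⌈N*⌉" answer different
questions.

A related published inconsistency: the G4 total printed for 100 trainees
(€545 245) is excluded from comparisons because it contradicts its own
confidence interval, whose midpoint (≈ €706 667) matches 100 × v₄.

## Effective cost per proficient trainee

Only 7 of 12 apprenticeship trainees (58 %) reached the proficiency
benchmark. `cost_per_proficient_trainee` divides the per-trainee cost by
the proficiency rate, attributing all spending to the trainees who actually
reached the benchmark: G4's €7 067 becomes 7 067 × 12/7 ≈ €12 115, widening
the gap to full PBP (where 100 % reached it). The headline comparisons
conservatively assume 100 % success in every arm; this operation quantifies
how conservative that is.

## Progression model and synthetic cohorts

Trials-to-proficiency is modelled as an absorbing Markov chain: each
30-minute training trial meets the benchmark with a fixed probability p
independent of history, so the time to absorption is geometric, censored at
a cap (default 30 trials, an upper bound implied by the 3.5-day limit that
no observed group mean approaches). The censored mean has the closed form
E[min(T, c)] = (1 − (1−p)^c)/p, verified in tests against direct pmf
summation and against Monte-Carlo simulation (agreement within 3 standard
errors at 10⁵ replicates).

The generator draws, per trainee:

* **proficiency** — Bernoulli with the group's target rate (1.0 for G1–G3,
  7/12 for G4);
* **trials** — censored geometric for proficient trainees; non-proficient
  trainees take the full allocation (trials at the cap, 3.5 billed days),
  matching how apprenticeship trainees exhausted their laboratory time;
* **hours** — exactly 0.5 h per trial. The published G4 figures (15 trials,
  7.75 h) deviate ≈ 3 % from this link; the generator keeps the link rather
  than inventing a per-trial duration distribution, so its hours target for
  trial-anchored groups is 0.5 × mean trials;
* **days** — drawn from a calibrated distribution on the half-day grid.
  Days are not derived from hours because the observed hours→days relation
  differs across groups (2.96 h → 1.17 d for G1 but 6.00 h → 1.5 d for G3);
  no single throughput constant reproduces both;
* **nights** — the policy `max(1, round_half_up(billed_days))`, which
  reproduces the observed ≈ 1 night for G1 and 3 nights for G4.

Calibration inverts the *mixture* mean over proficient and non-proficient
trainees, r·E[min(Geom(p), c)] + (1−r)·c = target mean trials (and likewise
for days), which reduces to a plain censored-mean inversion when r = 1.
This keeps the core parameter-recovery contract — calibrate ∘ generate at
n = 10 000 returns the calibration target within 2 % (2 points for
proficiency) — valid for the partially-proficient group too. G2's trial
count was never published; it is anchored on its published hours (3.38 h →
6.76 trials).

The days distribution uses the minimal-support solution: all mass on the
two grid points bracketing the target mean (exact mean by construction).
Two consequences worth knowing: the within-group variance of days — and
hence of costs — is a modelling choice, not an observed quantity (the source
reports no within-group variances); and when a target mean sits exactly on
the grid (G3's 1.5 days) the distribution degenerates to a point mass, so
G3's synthetic cost interval has zero width. Passing tests therefore
demonstrate the arithmetic, calibration and resampling machinery on cohorts
with the right *means*; they do not validate any claim about real
within-group cost variability or the significance of small-sample contrasts
other than the widely separated G1 vs G4 comparison.

## Uncertainty

* **Intervals**: 95 % percentile bootstrap on the mean per-trainee variable
  cost (default 10 000 replicates, seeded). The amortized fixed share is a
  known constant, so per-trainee intervals shift by it and total-cost
  intervals scale by N — consistent with the source's constant half-widths
  across cohort sizes within a group (≈ €431 for G1, ≈ €687 for G4). The
  source does not state how its intervals were computed; a normal-theory
  interval is implemented as a cross-check and neither method is claimed to
  be "the" published one. Constant input returns a flagged zero-width
  interval rather than raising.
* **Coverage**: the bootstrap's calibration is checked by simulation —
  1 000 draws of size-100 normal samples, requiring 93–97 % coverage of the
  true mean. Sample size 100 is used for this check because the percentile
  bootstrap is known to undercover for very small samples (≈ 91 % at n = 12,
  from the t₁₁-vs-z comparison), which is a property of the method, not a
  defect of the implementation.
* **Significance**: two-sided permutation test on the difference in mean
  costs, Monte-Carlo with the add-one correction p = (b+1)/(n_perm+1)
  (default 9 999 permutations, seeded), plus an exact full-enumeration
  variant that the Monte-Carlo version is tested against for group sizes
  ≤ 6.

## Numerical and interface choices

* Currency is never represented in binary floating point inside the cost
  path; floats appear only in generator/statistics code where they are
  harmless.
* Records travel as UTF-8 CSV with a required header
  (`trainee_id, group, trials, hands_on_hours, billed_days, nights,
  proficient`); invalid rows are reported with their row numbers, missing
  columns by name.
* Group 3 finished with 11 participants after a withdrawal; observed-data
  summaries use n = 11, while all cost anchors and projections use nominal
  12-trainee cohorts, as the published cost figures do.
* The reproduction pipeline (`run_reproduction`) stages its outputs in a
  temporary directory and renames them into place, so a failure leaves no
  half-written tables; identical configs produce byte-identical outputs.
* Default problem sizes — 10 000-trainee cohorts for calibration checks,
  10⁵ replicates for Monte-Carlo cross-checks, 10 000 bootstrap / 9 999
  permutation resamples — were chosen as the package's standard precision
  tier: large enough that Monte-Carlo error is far below every tolerance
  asserted, small enough to run interactively.

## Known limitations

* The generator reproduces group means and rates, not joint distributions:
  trials, days and nights are drawn independently given proficiency, whereas
  in reality slower trainees presumably book more days and nights.
* Costs excluded by the source are excluded here too: trainee personal
  expenses, currency conversion, discounting of the fixed-cost recovery,
  multi-centre heterogeneity.
* The 24.98-trainee published equivalence point remains unexplained; users
  comparing against the publication should expect this package's ≈ 33.4.
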