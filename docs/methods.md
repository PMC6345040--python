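# Methods notes

## Viability model and normalization

The package targets resazurin-reduction viability readouts: fluorescence
(ex 544 / em 590 nm) minus the plate's mean medium-only blank is taken as
proportional to viable-cell number. Normalization is strictly per plate —
blanks and controls are never shared across plates, because plate-to-plate
gain differences (reader settings, incubation time, seeding) would
otherwise leak into compound effects. The mean of a plate's own control
wells is 100% by construction, and all percent viabilities are invariant
to rescaling every reading on a plate by a common positive factor; both
properties are asserted in the unit suite.

Blank-corrected signal below zero is possible for total-kill wells when
background fluctuates. Such values are reported as-is with a
`flag_negative` marker rather than clamped, so the record stays faithful
to the raw data; a floor is applied only where a logarithm is actually
taken (screen scoring, see below). For combination dose-response series
the normalizing control is the fixed-concentration single-agent wells on
the same plate, selected via `control_role="fixed_dose_control"`, so the
curve isolates the added drug's effect on top of the modulator.

## Differential screen scoring

The chain is: plate-DMSO percent viability → unweighted mean over all
wells of a compound within a condition (duplicate plates × independent
runs; 4 wells in the canonical design) → division by the screen-wide mean
viability of that condition → per-compound log ratio between conditions →
Z-standardization over the screen.

Choices that were genuinely open, and how they were settled:

* **Log base** — natural log. Z-scores are provably base-invariant (any
  base rescales numerator and denominator alike), asserted to 1e-12.
* **Centering** — the screen mean of L is subtracted before dividing by
  the screen SD (a conventional Z-score). The preceding screen-mean
  normalization already makes mean(L) ≈ 0; explicit centering makes
  mean(Z) = 0 exact and testable. Whether the log ratio is formed from
  plate-normalized or screen-mean-normalized viabilities changes L only
  by an additive constant, hence no Z after centering; the implementation
  uses the screen-mean-normalized values.
* **Spread** — sample SD (n−1) over all compounds of the screen pooled
  across plates, not per plate.
* **Log floor** — normalized viabilities below 1e-3 are floored before
  the log and flagged (`flag_floored`), keeping total-kill compounds in
  the ranking with a finite, extreme L instead of discarding them.
  1e-3 is far below any viability measurable over well-to-well noise, so
  the floor is inert except for non-positive values.
* **Hit threshold** — |Z| ≥ 2 with inclusive boundaries, overridable
  (`--threshold`). Positive Z means selectively cytotoxic in the *test*
  condition.

No positional (edge-effect/B-score) correction, robust-MAD Z variant, or
multiple-testing adjustment is applied; the scoring deliberately mirrors
the plain screen-wide Z convention. Under the null with i.i.d. noise the
|Z| ≥ 2 rule tags ≈ 2Φ(−2) ≈ 4.55% of compounds, which the validation
suite confirms on simulated screens (the observed mean fraction runs a
couple of tenths of a percent low because the screen SD is estimated per
screen and plate-level control noise is shared among plate-mates).

## Dose-response fitting

The 4PL sigmoid is fitted by bounded trust-region least squares
(`scipy.optimize.least_squares`) over (top, bottom, hill, log10 ec50).
Bounds: top ∈ [50, 150]%, bottom ∈ [−20, 50)%, hill ∈ (0, 10],
ec50 within 100× of the tested dose range — chosen to keep the 50%
crossing identifiable for viability data in percent of control.
Multi-start initialization: ec50 at the dose interval bracketing the 50%
crossing (log-linear interpolation) and at the geometric mid-range, hill
at {0.7, 1.5, 3}, top/bottom at the clipped observed extremes; the lowest
residual sum of squares wins. Tight tolerances (1e-15) let noiseless
in-model data recover the generating parameters to ≤ 1e-6 relative error,
and on noisy data the fit is checked against an iteratively refined
grid-search oracle (never worse, within 1%).

A series with no spread (e.g. all wells at 100%) leaves ec50 and hill
unidentifiable: the fit returns `converged=False` with the degenerate
parameters rather than raising, and pipeline output lists the group under
failures instead of silently dropping it.

The reported potency is the absolute IC50 (curve = 50% of control), not
the relative EC50; if the fitted span does not cross 50% a distinct
"no absolute IC50" error is raised. Replication is handled by fitting
each independent experiment separately and averaging the resulting IC50s
(mean ± SEM, SD with n−1) — not by a pooled fit — because experiments
carry independent seeding/gain offsets. The SEM therefore reflects
between-experiment IC50 spread, not fit standard errors. Arms are
compared as fold change of mean IC50s with a two-sided, unpaired,
equal-variance Student's t-test on the per-experiment IC50s (the
classical Student form, not Welch); with fewer than two experiments on a
side the fold is still reported but the p-value is flagged undefined.

## Synthetic data

`simulate_screen` emulates the canonical screen design: a 328-entry
library on 4 plates (blank and DMSO wells on every plate: 4 and 8 by
default), each plate in duplicate and the screen run twice, so each
compound gets 4 wells per condition; compounds at a single 1 µM dose. A
cell-bearing well reads `blank_level + baseline · viability · ε` with
ε ~ LogNormal(0, σ), σ = √ln(1+cv²) — multiplicative because fluorescence
scales with viable-cell count. Blank wells get additive Gaussian noise
(SD 2% of the blank level); cv = 0 switches all noise off, giving exactly
reproducible truth values. Defaults: cv = 0.10 (typical well-to-well
variability for this assay class; the true magnitude of any given screen
is unknown and configurable), baseline 5000 AU over a 200 AU blank.
Condition-selective compounds are planted as per-condition viability
multipliers and recorded in a ground-truth table. Every plate draws from
a seed substream keyed by (condition, run, duplicate, plate), so
enlarging the design never changes existing plates.

`simulate_dose_response` draws percent viability around a 4PL curve
(default truth: top 100, bottom 0, hill 1, absolute IC50 10 nM) at 8
threefold dilutions from 1000 nM, triplicate wells, 3 independent
experiments, cv = 0.05; an optional modulator arm divides the absolute
IC50 by a fold-shift factor (> 1 = sensitization). `true_ic50_nM` is
interpreted as the absolute IC50 and the curve's ec50 derived from it, so
non-symmetric truth curves remain anchored at the 50% crossing.

What the simulators do **not** model: plate edge effects, spatial drift,
carry-over, cell-growth kinetics, compound fluorescence interference, or
heavy-tailed outliers. Passing validation therefore demonstrates the
statistical machinery is correct and calibrated under the assay's nominal
noise model, not that real screens are free of the artifacts above —
on real data those would need the (deliberately omitted) positional
corrections or manual well exclusion via the plate map's `unused` role.

## Validation study sizes

The validation suite and `scripts/acceptance.py` use: 500 simulated null
screens (Z calibration), 100 screens with ten 3-fold planted hits
(sensitivity / false-discovery proportion), 200 dose-response studies
(IC50 recovery), and 100 combination studies (3.5-fold shift recovery) —
sizes at which the Monte-Carlo error of each summary is small against its
acceptance band while the whole suite stays desk-scale.

## Interfaces

The five CLI subcommands (`simulate-screen`, `simulate-dr`,
`score-screen`, `fit-dr`, `report`) are thin wrappers over the library
functions; configuration precedence is flags > YAML file > defaults.
Analysis commands are deterministic by contract — identical inputs give
byte-identical output bundles (asserted in tests); randomness exists only
in the simulation commands and flows entirely from their seed. Warnings
raised by upstream stages (floored logs, single-replicate compounds,
non-converged fits) are captured into the bundle's `run.log`.
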