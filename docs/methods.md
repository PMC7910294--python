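# Methods

## The screen and its readouts

The pipeline models a 96-well high-content screen in which cells are
pre-treated with library compounds (10 µM, duplicate wells), stimulated
with IL-1β, and imaged for two inflammation markers — CCL2 and ICAM-1 —
reported as integrated fluorescence per Hoechst-positive cell, together
with the cell count itself. Every plate carries internal controls:
IL-1β + vehicle (the stimulated reference), unstimulated vehicle
(0.01% BSA + DMSO), TGFβ1 at 1 and 10 ng/mL (a known suppressor of the
induced response, used as an inhibition sentinel) and media-only wells.
Media-only wells are retained in files but excluded from all statistics;
they contain no cells, and per-cell intensity is undefined at zero cells
(such wells are flagged, their intensities set to NaN, and their
cell_ratio to 0).

## Normalization

Activities are fractions of the same plate's IL-1β + vehicle mean per-cell
intensity, per channel; cell ratios are the same construction on counts.
This is exactly invariant to multiplying a plate's intensities by any
k > 0, which is the nuisance it exists to remove. Unstimulated
(independence-tier) runs have no stimulated reference and are normalized
to the vehicle-only wells instead. Wells with zero cells are excluded from
every plate statistic rather than imputed.

## Quality statistics

The screening-window coefficient Z′ = 1 − 3(σp + σn)/|μp − μn| uses sample
(n − 1) SDs because per-plate control groups are small (four wells each in
the default layout). It is exposed at two granularities: per plate, and
pooled across a tier's plates after normalization (the screen-level
figure). The TGFβ1 check passes when 1 − mean activity of the TGFβ wells
reaches a minimum inhibition (default 0.2) per dose and channel; plates
without TGFβ wells are reported as "not evaluated", not failed. Channel
concordance is the ordinary Pearson correlation over all compound wells'
paired activities.

## Hit-advancement rules

Per compound and tier, replicate statistics are: mean activity, percent
change = (mean − 1) × 100, percent CV = sample SD / mean × 100, mean cell
ratio, and the largest single-replicate |change|. Classification order:

1. **Cytotoxicity** — cell_ratio ≤ 0.5 excludes the compound outright.
2. **Variability** — a channel that reaches the 20% effect threshold
   (by mean, or by any single replicate when the mean is dragged
   sub-threshold by spread) but has CV ≥ 15% is rejected as variable;
   if no channel survives, the verdict is `excluded_variable`. The
   single-replicate clause matters at the confirmation tier, where a
   genuinely active but irreproducible compound should be recorded as
   variable rather than quietly sub-threshold.
3. **Effect** — ≥ 20% change (inclusive) on either channel is a hit, with
   direction taken from the larger-magnitude qualifying channel; both
   channels' values are always carried in the output.

The effect threshold is inclusive while CV and cell-loss thresholds are
strict, matching the asymmetric phrasing of the original criteria.
Comparisons use a 1e-9 absolute guard purely to neutralize binary
representation of decimal thresholds (the float nearest 0.80 has percent
change −19.999999999999996); 0.801/1.199 remain non-hits.

The secondary (triplicate) tier evaluates only primary hits — the funnel
never resurrects a compound — so confirmed hits are a subset of primary
hits by construction. Dose selection at the tertiary tier takes, among
doses without disqualifying cell loss, the dose maximizing the best
channel's |percent change|, ties broken by higher cell ratio then lower
dose. The independence check flags compounds whose *unstimulated* activity
changes by ≥ 20% on either channel. The shortlist ranks confirmed hits by
best-channel |percent change| (ties lexicographic by compound id) and
greedily takes compounds under a per-therapeutic-class cap — a declared
formalization of "efficacy plus diversity", since the original selection
was qualitative.

## Dose–response machinery

The 4PL is parameterized increasing with hill > 0:
f(x) = bottom + (top − bottom)/(1 + (EC50/x)^hill), so f(0) = bottom and
f(EC50) is exactly the midpoint. Inhibition never needs a descending
curve because it is represented downstream as activity ratios. Fitting is
nonlinear least squares (scipy `curve_fit`, trust-region with hill bounded
in [1e-3, 50] and EC50 estimated on the log scale) on log-dose;
zero-concentration standards are mapped to a log-dose of −700, where the
logistic term underflows and the point anchors the bottom asymptote
exactly. Initialization: bottom/top from the response extremes, EC50 from
the geometric mean of the doses bracketing the half-range crossing,
hill = 1. Responses flat to within 1e-12 of their scale raise a
degenerate-curve error. Tolerances are set tight (1e-14) so noiseless data
are recovered to ~1e-6 relative error or better.

Back-calculation through a fitted standard curve flags readings at/below
the bottom asymptote as below-LOD (no numeric value — never LOD/2
substitution) and censors readings at/above the top asymptote at the top
standard (10,000 pg/mL) rather than extrapolating, because the inverse map
diverges at the asymptote. For the same analytical reason, relative error
of back-calculated concentrations grows without bound toward the top of
the curve even at fixed signal noise; recovery bands are therefore
meaningful only in the informative region around the EC50.

The stimulus working concentration is the lowest candidate dose whose
fractional response (f − bottom)/(top − bottom) reaches `min_fraction`
(default 0.5, inclusive) on every channel — submaximal on purpose, so both
induction and attenuation remain detectable. The 0.5 default reproduces
the conventional half-maximal working-point choice; it is a parameter
because the goal, not the number, is the principle.

Vehicle fold changes are computed per case and then averaged across cases
(folding first); averaging concentrations before folding is available as
an option. When the vehicle itself is below detection, the analyte
switches to absolute reporting and no fold is defined.

qPCR quantification uses the ΔCt method: ΔCt = Ct_target − Ct_GAPDH, and
fold = 2^−(ΔCt_condition − ΔCt_reference) against a named reference
condition (no default is hard-coded; "time zero" and "untreated" are both
legitimate references depending on the experiment). "Logged" per-cell
secretion values use log10, the conventional scale for pg/mL panels.

## The synthetic screen generator

The generator defines the conditions under which the pipeline is tested.
Per well, per-cell intensity is

plate_factor × basal × induction(role, channel) × compound_effect × exp(ε)

with: plate_factor log-normal (σ = 0.1 by default), shared across channels
within a plate — precisely the nuisance internal normalization removes;
well noise ε log-normal with CV 0.05 by default (σ = √ln(1 + cv²));
basal intensity 100 AU; induction fold 5.0 per channel, so unstimulated
vehicle sits at ~0.2× the stimulated reference; TGFβ1 inhibits the induced
response by 0.5 (high dose) and 0.6 × 0.5 (low dose). Cell counts are
Poisson with mean 2000 × viability. Truth effects are multiplicative on
the stimulated response, shared between channels (the two markers are
co-regulated in this system, which is what makes their concordance a
meaningful QC statistic); modulator magnitudes |effect − 1| are uniform on
[0.3, 0.6], half inhibitors and half inducers; cytotoxic compounds
(disjoint from modulators) have viability uniform on [0.10, 0.45], kept
below the 0.5 exclusion boundary so Poisson sampling cannot flip a planted
truth label; basal effects default to 1 (no stimulus-independent
activity). At doses below the 10 µM screening concentration, effects and
viability shrink toward 1 through the saturating factor
s(d) = (d/(d + 1 µM))/(10/11), which equals 1 at 10 µM — a package choice,
since no per-dose effect model is specified by the screen's design.

At these defaults the pooled screening window is Z′ ≈ 0.8 (per-plate
0.55–0.95) — a cleaner assay than many published screens of this class
report, because the generator has no spatial plate artifacts, no reagent
drift, and channel-symmetric noise. What passing tests show is therefore
that the *rules* behave exactly as specified under calibrated noise; they
do not certify performance on real plates with edge effects, carry-over,
or channel-specific variance, none of which the generator emulates.
Bead-array simulation emits the 11 standards (two-fold serial dilutions
from 10,000 pg/mL plus a blank) and sample signals through the same curve,
both with the requested multiplicative noise; blot simulation plants
effects as reference-relative spot intensities with exactly six reference
spots.

## Problem sizes

Default test and acceptance runs use screens of 200–300 compounds
(recovery and oracle checks, 20 seeds for the noisy band), one
1280-compound library pass for the end-to-end funnel, 50 seeds for the
EC50-error and panel-recovery medians, and 8–12-point dose grids — sizes
at which every quantity the suite asserts is stable to well within its
tolerance while the whole suite runs in seconds.

## Known limitations

- No spatial (row/column/edge) bias modelling or correction (B-scoring);
  the normalization is purely plate-multiplicative.
- The 4PL is symmetric; strongly asymmetric calibration data would need a
  five-parameter logistic, which is out of scope.
- Statistical hypothesis testing of per-compound effects is deliberately
  absent: the advancement criteria are threshold rules, and significance
  testing of validation assays is delegated to standard ANOVA routines.
- The funnel's diversity shortlist is a formalization of a qualitative
  selection; different caps or class vocabularies give different (equally
  defensible) shortlists.
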