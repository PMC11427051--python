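# Methods

This note documents the models, parameter choices, and numerical conventions
behind `spikemodes`, and what the synthetic testbed does and does not show.

## Analysis conventions

All event times are in seconds; windows are half-open `[start, end)` so a
boundary spike is never counted twice. The analysis window defaults to 3 min
of recording following a 3-min equilibration period, and cells firing below
0.5 Hz are discarded — a cell at exactly 0.5 Hz is kept ("less than" read
strictly). The CV of the IEI uses the sample SD (`ddof=1`) by default; the
population convention is a parameter, and the difference is negligible at the
several hundred intervals a 3-min recording of these cells yields. The IEI
histogram bin width (50 ms default) is reporting-only and never feeds the
classifier.

## Burst detection

The counting criterion — a cell is bursting when a 3-min window holds at
least three burst events of at least three spikes — needs a burst
delimitation rule to be operational. We use a maximal-run interval threshold:
consecutive IEIs at or below `max_intraburst_iei_s` (default 100 ms) belong
to one episode, and an episode qualifies when it spans at least
`min_spikes_per_burst` spikes. The default suits cells firing 1–4 Hz, whose
tonic IEIs (250–1000 ms) sit far above the threshold while intra-burst
intervals (~50 ms) sit well below. An adaptive alternative (threshold =
0.5 × median IEI) is available behind `BurstParams(adaptive=True)`, off by
default, as a robustness check for unusually fast or slow cells. Whether the
original assignments were made by eye or by a numeric rule is unknowable from
summary statistics alone; the interval-threshold rule is this package's
explicit, auditable operationalisation.

A caveat that matters in practice: a genuine gamma-renewal pacemaker above
roughly 5.5 Hz with CV near 0.3 produces occasional runs of two sub-100-ms
IEIs and can cross the three-burst criterion. This is a property of any fixed
interval threshold, not of the implementation; the cohort generator bounds
per-cell rates (below) partly for this reason.

## Classification

The decision tree is: bursting cells are *mixed mode* when their tonic
fraction (share of spikes outside burst episodes) is at least 0.40, otherwise
*rhythmic bursting*; non-bursting cells are *regular* when CV < 0.30,
otherwise *irregular*. Two boundaries deserve comment.

* **Regular/irregular at CV 0.30.** The published class bands are
  non-contiguous (regular "0.25 or less", irregular 0.30–0.65) and the
  printed regular class mean (0.27) exceeds the first band. We place the
  boundary at 0.30 — the lower edge of the irregular band — making the rule
  contiguous and consistent with the printed class mean. Configurable.
* **Rhythmic vs mixed at tonic fraction 0.40.** Mixed mode is described
  qualitatively as tonic firing with bursts overlaid; requiring at least 40 %
  of spikes outside bursts operationalises that. Non-bursting cells with
  CV > 0.65 remain irregular (bursting is the only gate to the bursting
  labels) and are marked out-of-band in the rule trace.

Classification is total and deterministic; every label carries the ordered
list of decisions that produced it.

## Clustering validation

Features per cell are the bursting flag (categorical 0/1), firing rate, and
CV. Gower dissimilarity averages a 0/1 mismatch with range-normalised
absolute differences, equal weights, so entries live in [0, 1]; the flag
alone contributes 1/3. Gower need not satisfy the triangle inequality, and
because each variable is range-normalised the dissimilarity — and hence the
silhouette — is scale-free: "tight" clouds are tight only relative to their
own spread. Ranges should be frozen once on the full table
(`GowerTransformer.fit`) when sub-cohorts are compared.

Hierarchical clustering runs Lance–Williams updates directly on the
dissimilarity matrix. `ward` applies the Ward update to squared
dissimilarities (the Ward.D2 convention, matching scipy and R `hclust`
ward.D2 on identical input); `ward_d` applies the same coefficients
unsquared, since published analyses do not always say which variant their
toolchain used. Merge ties break toward the lowest cluster indices. The
agglomerative coefficient is `mean_i(1 − m_i/M)`; it is 0 for n = 2 by
construction, and defined as 0 with a warning when all points coincide.

PAM refines the greedy BUILD start and nine seeded random starts with the
SWAP local search (best improving single-medoid exchange), keeping the best
objective. Plain BUILD+SWAP can stall in swap-local optima (we construct such
cases at n = 8 in the tests); the extra starts make global recovery routine
at validation scales while remaining deterministic under the seed. k-means
(Lloyd, best of 10 restarts, empty clusters re-seeded to the farthest point)
clusters a numeric encoding that parallels Gower's scaling — flag kept 0/1,
continuous variables range-scaled — and is scored, like all methods, on the
Gower matrix, as mixed-data validation toolchains do. Dunn index and mean
silhouette are computed for every method × k in 2–6; singleton clusters
score silhouette 0 and are excluded from diameters, with an explicit error
when every cluster is a singleton.

## Synthetic cohort generator

No recordings are deposited with the source study, so the testbed is a
point-process cohort generator calibrated to the published group statistics.
Three generative families cover the phenomenology (they are modelling
choices — the study describes firing patterns, not a generator):

* **Tonic (regular, irregular):** stationary gamma renewal; `κ = CV^{−2}`,
  mean interval `1/rate`. Exact in distribution, so calibration is
  closed-form.
* **Rhythmic bursting:** cycles that are either a burst (3 spikes at
  gamma-jittered 50-ms intervals, CV 0.2) or, with probability `p_single`, a
  stray single spike; cycles separated by gamma inter-burst gaps (CV 0.15).
  Given a (rate, CV) target the intra-burst IEI fraction is solved from the
  two-component IEI mixture (a 1-D root find) and converted to
  (`interburst_mean_s`, `p_single`). `p_single` is capped at 0.6 so single
  spikes stay a minority (tonic fraction ≤ 1/3) — a cell dominated by lone
  spikes would not be rhythmic by definition — which means CV targets below
  ≈ 0.78 at 2.3 Hz are met only approximately. Three spikes per burst (the
  criterion minimum) is deliberate: at the published rhythmic operating point
  (2.3 Hz, CV 0.84), larger bursts force a stray-single fraction so high that
  the tonic-fraction rule would relabel the cell mixed mode.
* **Mixed mode:** a two-state switching process — tonic gamma renewal
  interrupted by bursting epochs that emit whole bursts of 6 spikes
  (longer bursts than the rhythmic class, as observed) separated by 0.3-s
  gaps; exponential dwell times. Because a bursting visit always emits whole
  bursts, the burst count per visit is geometric with mean
  `1/(1 − e^{−cycle/dwell})`; the calibration solves the tonic dwell from the
  rate target with that correction and the tonic-state shape from the IEI
  variance budget, clipping shapes to [0.25, 64]. The tonic spike fraction is
  held at 0.8, comfortably above the 0.40 mixed-mode gate.

`calibrate_bursting` refines the closed-form solutions by a bounded
Nelder–Mead search whose oracle is the generator itself at 50× the analysis
duration, averaged over two fixed seeds (the slowly switching mixed process
otherwise lets the search overfit single-seed noise); it raises an explicit
infeasibility error, reporting the achievable statistics, when a target
cannot be met within 2 %. Per-cell specs use the closed-form paths, so
cohort generation is fast and deterministic.

### Per-cell heterogeneity

Published "±" values are standard errors; per-cell spread needs SDs, so
SD = SE·√n per class (regular rate: 0.4·√40 ≈ 2.5 Hz, etc.). Per-cell
(rate, CV) targets are drawn from truncated normals with the location shifted
so the post-truncation mean equals the published class mean:

* CV bands follow the class definitions — regular (0.05, 0.30), irregular
  and mixed (0.30, 0.65), rhythmic (0.70, 1.05). The classes are *defined*
  by CV ranges, so untruncated normals would generate self-contradictory
  cells (a third of "regular" cells above the regular/irregular boundary).
* Rates are bounded to (0.55, 6.0) Hz for every class: the floor keeps cells
  above the 0.5-Hz exclusion, and the cap reflects the reported 1–4 Hz
  operating range of these cells — the SE-derived SD would otherwise invent
  6–10 Hz pacemakers, which both misrepresent the population and trip any
  fixed interval-threshold burst rule.

Within a class, rate and CV are drawn independently; the true within-class
joint distribution is unknown. The cohort-level negative rate–CV correlation
emerges from the between-class structure alone, so its magnitude on synthetic
cohorts is not comparable to the published within-cohort value — only its
sign is.

### Presets

Cohort presets carry class counts in (regular, irregular, rhythmic, mixed)
order with per-preset provenance strings. The pooled shell cohort is
40/68/13/24 of 145. The male/female split decomposes those counts exactly
(male 18/6/1/4 of 29, female 22/62/12/20 of 116), which reproduces the
published female grand mean rate (≈ 2.5 Hz) under the pooled class-mean
rates; the published male n of 30 and pooled n of 145 are mutually off by
one, and the decomposition resolves it in favour of the pooled counts.
Estrous-stage pies are published only graphically; the registered stage
counts are chosen to match the per-stage printed mean rates under the pooled
class rate means and the narrative ordering (estrus: more mixed/rhythmic;
diestrus: predominantly irregular). For diestrus those two constraints
conflict — a high irregular fraction pulls the mixture mean below the printed
stage rate — and the composition description was preferred. Core, stress
(FSS), sagittal-shell, drug (vehicle/CRF/apamin) presets are the integer
solutions of the printed percentages at the printed n; where plain rounding
breaks the total (the post-CRF table), largest-remainder apportionment is
used with ties broken in class order.

Cohorts use exact stratified class counts by default (`exact_counts`),
matching how printed cohort tables are stated; i.i.d. sampling is available.

## Neuromodulation operators

Drugs act phenomenologically: a row-stochastic 4×4 transition matrix over
firing modes plus per-class rate multipliers and CV deltas on the generator
parameters. Receptor-level mechanism (CRF-R1/cAMP/sK biophysics) is out of
scope.

* **CRF** (3/10/100 nM): the qualitative sensitivity pattern is encoded as
  which classes respond at each concentration (3 nM: regular and irregular;
  10 nM: all but rhythmic; 100 nM: all), with magnitudes as free
  configuration (defaults 1.25/1.4/1.6). The effective multiplier scales as
  `(2.5 Hz / rate)^{0.5}`, implementing the strong negative semi-log
  correlation of the CRF response with baseline rate; per-cell lognormal
  response noise (CV 0.15) makes cohort-level correlation analyses
  non-degenerate. The 100-nM mode-transition matrix is not hand-written: it
  is fitted to observed pre/post class distributions by
  `fit_transition_matrix` — projected-gradient least squares over
  row-simplexes, identity rows for classes absent pre-drug.
* A cell that switches class is re-drawn from the destination-class
  distributions, which describe the post-drug state directly; the
  within-class multiplier applies only to cells keeping their class
  (stacking both would double-count the effect).
* **Apamin** maps every mode to rhythmic bursting while preserving the
  cell's own rate (recalibrating the burst-pause family at the pre-drug
  rate), reproducing the elevated-CV / unchanged-rate signature.
* Post-drug calibration targets are clamped to each family's feasible range
  (tonic CV ≤ 0.64, rhythmic rate ≤ 12 Hz, mixed rate ≤ 8.5 Hz), with the CV
  floored at 0.05.

The drug response metric is the rate over the final 3 min of the drug window
as percent of the baseline-window rate; ΔCV is a plain difference
(regularisation negative). The semi-log concentration–response fit reports
the signed Pearson r (and slope/intercept/p) of percent-baseline against
log10 baseline rate; note that a squared correlation cannot be negative, so
published negative "r²" values for this fit are read as signed r and are not
used as calibration targets.

## Cohort statistics

The proportion χ² follows the operational convention of the source analyses:
inputs (possibly fractional, proportion × n) are rounded to the nearest whole
integer with half-up ties, classes empty in both cohorts are dropped with a
logged warning and reduced df, and the Pearson statistic is computed from the
table marginals without continuity correction (via
`scipy.stats.chi2_contingency`).

## Problem sizes and determinism

The acceptance script averages 20 independent seeds per experiment:
145-cell shell cohorts (pipeline recovery), 145-row feature tables
(clustering validation), the 116-cell female preset, and 52-cell pre-CRF
cohorts for the transition operator — matching the published cohort sizes
while keeping the full run under a minute on one CPU. All randomness flows
from `numpy` `SeedSequence`s spawned from the single `--seed`; identical
seeds reproduce cohorts bit-for-bit.

## Known limitations

* The generator reproduces first- and second-order IEI statistics (rate, CV)
  and burst phenomenology per class, not serial IEI correlations,
  slow drifts, or adaptation within recordings — real cell-attached data
  contain all three. Passing recovery tests shows the analysis pipeline is
  faithful to the stated class structure, not that the generator reproduces
  every property of the biological recordings.
* Within-class rate–CV independence is an assumption; see above.
* The interval-threshold burst rule is one defensible operationalisation;
  classifications of borderline cells (tonic fraction near 0.40, CV near
  0.30, fast pacemakers) are sensitive to its parameters, which is why every
  label carries a rule trace and all thresholds are configurable.
* The transition-matrix fit from a single pre/post distribution pair is
  underdetermined (any row-stochastic matrix mapping p to q is optimal);
  the projected-gradient solution from the identity start is the
  minimal-movement representative, adequate for proportion-level predictions
  but not interpretable as per-cell transition probabilities.
* Estrous-stage compositions are read from graphical summaries and should be
  treated as approximate.
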