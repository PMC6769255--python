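# Methods

## The occupancy model

`cratherm` models a gene's regulatory region as `n` enhancer binding sites
plus one promoter/RNAPII unit, each either bound or unbound. A system state's
relative energy sums per-unit protein:DNA terms (`q_site[i]` for an
activator bound at site *i*, `q_promoter` for RNAPII at the promoter) and
pairwise protein:protein terms (`omega_site_site[i,j]` between activators at
two sites, `omega_site_pol[i]` between a site-bound activator and RNAPII). A
pair term contributes only when both partners are bound — the product-of-
occupancies convention standard in equilibrium (Shea–Ackers-type) models of
transcription. There is no promoter self-pair term, no nucleosome or
competitor species, and exactly one promoter unit.

Boltzmann weights are `exp(−E/RT)`. Energies are expressed in kcal/mol with
R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 310.15 K (37 °C), so RT ≈ 0.616
kcal/mol; with energies drawn or fitted in [−5, 5] the weights span roughly
e^±8 per term, a workable dynamic range. The unit convention is a package
choice — only the dimensionless ratio E/RT enters any probability.

An experimental state (the set of targeted sites, plus a mode) selects
admissible system states: untargeted sites are pinned unbound in activation
mode; in inhibition mode the targeted sites are pinned instead (a targeted
repressor is assumed to silence its site completely, so the *untargeted*
sites are the active ones). The promoter is never constrained. The
probability of RNAPII occupancy is the weight sum over admissible states
with the promoter bound divided by the sum over all admissible states.

### Numerical choices

* All partition arithmetic runs in the log domain (log-sum-exp), so extreme
  energies cannot overflow; `p_rnapii` is exact to ~1e−15 against naive
  enumeration across 1–4 sites.
* Odds and odds-ratio computations (`log_odds_rnapii`) difference the bound
  and unbound log partition sums directly rather than transforming
  `p/(1−p)`, which loses ~7 orders of magnitude of precision when `p`
  saturates; the multiplicative independence law then holds to ~1e−14 over
  the full ±5 energy box.
* State enumeration is lexicographic over the occupancy vector with the
  promoter unit last, so every ensemble, table and test is reproducible.
* The empty targeted set is legal and represents the untreated control.

## Fitting

The objective is the Pearson correlation between modelled occupancy and
observed mean relative expression across conditions (replicate means; SEM is
carried for reporting only, matching an unweighted correlation objective). A
parameter vector whose modelled occupancies are constant has an undefined
correlation and scores −1 by convention, which repels optimizers from flat
regions without producing NaNs. The objective is affine-invariant in the
expression values, so only the *pattern* of activation is fitted — never an
absolute scale.

Multi-start fitting draws each start uniformly in the box (default
[−5, 5]¹⁰ for three sites) from per-start seeds spawned off one master seed
(order-independent and reproducible), then refines every start with two
bound-constrained minimizers of −r:

* **L-BFGS-B** (scipy.optimize), gradient-based with numerical gradients;
* **Hooke–Jeeves pattern search**, derivative-free, written in-package:
  exploratory ±step coordinate moves with pattern extrapolation, projection
  onto the box, step halving on failure, termination at step < 1e−4 or
  2,000 objective evaluations.

Running both guards against algorithm-specific bias; on smooth synthetic
problems their best objectives agree to ~1e−8. All `2 × n_starts` fits are
kept. The *selected ensemble* is every fit within 0.1 correlation of the
best; reported estimates are the per-parameter mean and 2.5/97.5 percentile
interval over that ensemble. Percentiles, not a normal approximation, because
selected ensembles are routinely multimodal — compensating parameter
combinations produce distinct local optima with equal correlations. The
ensemble therefore *characterises* the energies rather than pinpointing
them; the package treats this as a feature and tests it (couplings that the
design cannot expose — e.g. a site-pair term when no condition targets both
sites — provably never move the objective).

By default the control condition (nothing targeted, relative expression 1)
is included in the fitted vector, anchoring the baseline occupancy;
`include_control=False` drops it. Fitting an inhibition-mode table is
identical to fitting the complemented activation-mode table, exactly, and is
implemented through the same admissibility rule.

The statsmodels-style surface (`EnhancerActivationModel.fit()` →
`ActivationFitResults` with `params`, `conf_int()`, `summary()`,
`plot_param_distributions()`) wraps module-level functions
(`objective`, `fit_multistart`, `select_ensemble`, `summarize_ensemble`)
that remain public for scripting.

## Expression quantification

Fold changes use plain ΔΔCt with efficiency fixed at 2 (no efficiency
correction): within each replicate ΔCt = Ct(target) − Ct(reference); each
replicate's fold change is 2^−(ΔCt − mean control ΔCt); condition means are
then rescaled by the control condition's mean fold so the control reports
exactly 1 (with noisy replicates the unscaled arithmetic mean of control
folds exceeds 1 by Jensen's inequality; the rescale restores the
control-equals-one contract while leaving noiseless data untouched).
Replicates are averaged flat, SEM uses the n−1 standard deviation, and a
single replicate reports SEM as missing rather than 0.

Site z-scores put single-site effects for one gene on a common scale:
z = (x − mean)/SD over that gene's sites (n−1 SD, so three-site vectors are
handled sensibly). Interference z-scores are negated so that higher always
means a more important site, making activation (sufficiency) and
interference (necessity) directly comparable on one axis.

## ChIP-seq region normalization

Counts per region are depth-normalized to reads per million, then each
sample is divided by its mean RPM over a reference region set — the
antibody's own overlapping peaks (`peak_mean`) where untargeted peaks exist,
or designated background control regions (`control_mean`) where every peak
is targeted (the HA situation). The two methods are the same arithmetic on
different reference sets and agree exactly when handed the same set. Fold
change is the ratio of a region's normalized signal in a targeted sample to
the same region in the non-targeted control; the full pipeline is exactly
invariant to rescaling any sample's library size. Coordinates are 0-based
half-open (BED) throughout; browser-style 1-based spans must be converted on
entry. No pseudo-counts are added by default — zero control signal is an
explicit error with a `pseudocount` escape hatch.

## Predictor importance

Features and responses are z-scaled across sites (n−1 SD; constant columns
are an error naming the column). Relative importance in an OLS fit is the
Lindeman–Merenda–Gold decomposition: predictor *k*'s share is its average
sequential R² gain over all p! entry orders, computed by the equivalent
subset-weighted sum Σ_S |S|!(p−|S|−1)!/p! [R²(S∪{k}) − R²(S)] over the 2^p
predictor subsets (exact enumeration, hence the p ≤ 10 limit). Raw shares
sum to the full-model R²; reported shares are normalized to sum to 1. The
implementation is checked in tests against literal enumeration of all
orderings for p ≤ 5, against the closed form for orthogonal designs, and
for affine invariance and duplicate symmetry.

Feature builders: `count_tf_overlaps` counts the number of distinct TFs
(peak *sets*, not peaks) overlapping each region by ≥1 bp on half-open
intervals; `nearest_enhancer_distance` first discards peaks overlapping any
TSS interval (promoter-proximal signal is not an enhancer proxy), then
reports 0 for overlap or the half-open gap `c − b` between [a,b) and [c,d),
with a warning and a missing value when a chromosome retains no peak.

## The synthetic-data generator

`simulate_expression` embodies the model's central assumption as its
observation model: noiseless truth per condition is `a·p(RNAPII) + b`, with
Gaussian replicate noise of SD `noise_sd × a` on the linear fold-change
scale (log-normal noise available behind `noise="lognormal"`). Defaults are
the study design the package targets: 3 sites, the 8-condition design
(control, 3 singles, 3 pairs, triple), 4 replicates (at least two replicates
on each of at least two plates), `a = 30, b = 1` so fold changes span ~1–30
as strong synthetic activators produce, and `noise_sd = 0.05`. Ground-truth
energies default to uniform draws in [−5, 5] — the same distribution as the
fitting starts.

What the generator does **not** emulate: plate/batch structure,
amplification-efficiency drift, heteroskedastic qPCR error growing with Ct,
guide-RNA efficacy differences between sites, or any genomic sequence
context. Passing recovery tests therefore shows the estimator is correct
*under the model's own assumptions* — identifiable parameters are found,
cooperativity signs survive realistic replicate noise — not that real qPCR
data satisfy those assumptions.

For the cooperativity-recovery study the ground truth is fixed at
`q_site = +1`, `q_promoter = +1`, `omega_site_pol = −2` per site, with the
probed pair coupling at ∓3 kcal/mol and all other pair couplings 0: sites
bind weakly on their own but recruit RNAPII strongly once bound, a regime in
which the data pattern actually carries the pair coupling's sign. (An
all-zero background would decouple site occupancy from the promoter and
leave occupancy at 0.5 in every condition — no signal to fit.)

`gen_ct_table` inverts the ΔΔCt pipeline (target Ct sits log₂(fold) cycles
below the control baseline) so its zero-noise output round-trips exactly;
`gen_chip_fixture` draws Poisson counts with expected value
`base_rate_rpm × enrichment × library_size/10⁶` plus a block of background
control regions pinned at enrichment 1, so normalization recovers enrichment
ratios within Poisson error.

## Problem sizes

The test suite and the acceptance script run deliberately scaled-down
versions of the full procedure: 50 starts per algorithm for noiseless
recovery and 200 for the noisy sign-recovery studies (the full-scale
procedure is 1,000 starts × 2 algorithms = 2,000 fits and is exercised for
its counting semantics at small K), 1,000 parameter draws for the
enumeration oracle, 200 draws for the algebraic laws, and a 400-region /
5-TF interval fixture. These sizes were chosen so each property's
Monte-Carlo error is far below its assertion tolerance.

## Known limitations

* Equilibrium occupancy only: no kinetics, no non-equilibrium proofreading,
  no continuous occupancy.
* The correlation objective fits patterns, not absolute expression; an
  affine link is assumed, not estimated.
* Energies are identified only up to compensations the design cannot
  distinguish; report ensembles, not point estimates.
* Exact LMG enumeration stops at 10 predictors by design.
* Inhibition mode assumes complete silencing of targeted sites; partial
  repression is not modelled.
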