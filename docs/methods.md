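# Methods

This note records the models, estimators and numerical choices behind
each module, what the synthetic-data generators do and do not emulate,
and the design decisions made where the procedure was genuinely open.

## Screen scoring

**Model.** An arrayed overexpression screen measures, per gene, colony
pixel density on a selective (reporter-driven) medium and a permissive
control medium, with replicate colonies spread over plates. Plate
effects are multiplicative; colony noise is multiplicative; both are
treated as log-normal.

**Pipeline.**

1. *Dead-colony exclusion.* A gene whose mean permissive-medium colony
   size is strictly below 20 px is removed from both media (strict `<`;
   a gene at exactly 20 px is retained). The mean across permissive
   replicates is used because a single dead replicate should not discard
   a gene. Genes with no permissive measurement are excluded with reason
   "no control growth" rather than imputed.
2. *Plate normalization.* Within each treatment group (medium), every
   plate's sizes are scaled by (grand mean of plate means)/(own plate
   mean). After this, each plate's mean equals the group grand mean
   exactly (checked to 1e-9 relative); a single-plate group is left
   unchanged.
3. *Z-scores.* Each normalized measurement is standardized against the
   distribution of **all** normalized sizes in its medium group (sample
   SD, n−1). Pooling group-wide rather than per-plate is deliberate:
   plate effects are already removed, and group-wide pooling gives the
   most stable variance estimate. By construction the pooled replicate
   Z-scores have mean 0 and SD 1.
4. *Effect statistic and test.* Per gene, Δz = mean selective Z − mean
   permissive Z. The default one-sided p-value is the unit-variance
   normal test Δz/√(1/n_sel+1/n_perm) ~ N(0,1) under the null. This is
   exact rather than approximate in a useful sense: after group-wide
   standardization the replicate scores have variance 1 by
   construction, so no per-gene variance need be estimated. Welch's t
   on the replicate Z-scores is available (`test="welch"`), but at 4
   replicates it has ~6 degrees of freedom and cannot reach
   genome-wide FDR-adjusted significance even for +3 SD effects — it is
   a sensible choice only with many replicates. With a single replicate
   per medium both tests reduce to the normal tail of Δz/√2.
5. *FDR.* Storey q-values with the λ = 0.5 plug-in estimate of π₀
   (clamped to (0,1]), computed by the usual step-up running minimum.
   Below 100 genes the π₀ estimate is unstable and the scorer falls
   back to Benjamini–Hochberg; either procedure can be forced. Hits are
   genes with q < 0.05, ranked by Δz descending, ties broken by smaller
   q then gene id.

**Degenerate inputs.** A zero-variance medium group raises
`DegenerateScreenError`; a plate with non-positive mean size is an
error naming the plate; genes present in only one treatment group are
dropped with a logged reason.

## Screen simulator

Log colony size = log(baseline) + plate effect + noise, with
plate effects ~ N(0, σ_plate) drawn per (plate, medium, replicate) and
noise ~ N(0, σ) with σ = √ln(1+CV²). Defaults: baseline 300 px
(flatbed scans at 300 dpi give colonies of a few hundred pixels),
σ_plate = 0.15, CV = 0.15, 384 genes per plate, 4 replicates — ordinary
working conditions for an arrayed screen. Planted activators receive an
additive shift of `hit_effect_sd_units` × √(σ_plate²+σ²) (SD units of
the full within-group log-size distribution) on the selective medium
only. Dead strains (independent of hit status) get 1–15 px debris
colonies on both media. Seeds are split into independent child streams
via `numpy.random.SeedSequence`; no stream is shared between
sub-generators.

What the generator does **not** emulate: spatial row/column edge
effects within plates, batch effects between replicate pinnings beyond
the plate factor, and non-log-normal size outliers. Passing tests
therefore show the scorer is correct under multiplicative plate
structure, not that it is robust to spatial artefacts (which the
normalization here, like grand-mean plate normalization generally,
does not remove).

## Presequence enrichment

E(p,a) = log2[(f_obs(p,a)+ε)/(f_bg(a)+ε)] over positions 1..20, with
f_bg the residue usage over *all* positions of a user-supplied
proteome, and ε = 1/(2n) for n set sequences, added to both numerator
and denominator so unobserved residues give finite negative values
(a `floor=8` display clamp is optional). Position 1 (initiator Met) is
included as-is. Sequences shorter than the window are dropped, not
padded. 'X'/'*'/'-' symbols are skipped in all counts.

The uniqueness scan reports (position, residue) pairs where the query
residue appears in no reference sequence at that position — the
analysis that distinguishes one presequence's residues from a whole
localization class. It is purely presence/absence; with large reference
sets every residue tends to be observed somewhere, so the scan is
meaningful for curated sets of tens of sequences.

The simulator draws residues i.i.d. per position from a yeast-like
usage vector, with planted (position, residue, fold) biases
renormalized over the remaining residues (folds pushing a probability
past 1 are clamped with a warning; a force flag fixes a residue
outright). Real presequences have positional dependencies
(amphipathic-helix periodicity) that an i.i.d. model does not emulate;
recovery tests validate the counting and normalization arithmetic, not
a biological model of presequences.

## Conservation

Column score: fraction of unordered non-gap residue pairs that are
identical (sum-of-pairs identity). Pairs involving gaps are excluded
from numerator and denominator; columns with <2 non-gap residues score
0. A BLOSUM62 variant rescales each pair's score by its own residues'
diagonal maximum, (B(a,b)−B_min)/(max(B(a,a),B(b,b))−B_min), so
identical pairs score 1 and the worst mismatch 0; the column score is
the clipped mean. These are transparent, parameter-free scores;
physicochemical conservation scores of alignment viewers are related
but not numerically identical, so cross-tool comparisons should be of
profile shape, not values.

Windowed profile: arithmetic mean over each contiguous window (default
5 columns), reported by 1-based window start. The prefix/suffix
contrast at boundary b compares windows lying entirely within columns
1..b against windows starting after b; straddling windows belong to
neither side.

The alignment simulator draws a uniform-residue ancestor and
substitutes each column independently per descendant (star phylogeny,
no indels, substitutions uniform over the 19 other residues). It
emulates a conserved N-terminal block, not realistic phylogenetic
covariance.

## Assay estimators

* **2^−ΔΔCt.** Technical replicate Cts are averaged (arithmetic mean),
  ΔCt = Ct_target − Ct_reference per sample, ΔΔCt = ΔCt − ΔCt_control,
  fold = 2^−ΔΔCt. Amplification efficiency is fixed at 2; no
  efficiency-corrected variant. The control sample's fold change is
  exactly 1. Fold changes are invariant to any constant Ct shift.
* **ChIP enrichment.** (IP/input) at the target locus divided by
  (IP/input) at the silent *HMR* control locus; all signals must be
  positive. Invariant to rescaling all signals of one sample.
* **Half-life.** OLS of ln(intensity) on time; t½ = ln2/(−slope);
  slope ≥ 0 sets an infinite-decay flag. Replicate series are pooled
  into one fit after each is normalized to its own t=0 intensity —
  pooling uses all points while normalization removes per-replicate
  loading differences. Non-positive intensities are excluded with a
  warning (error if fewer than 3 points remain). At 10% multiplicative
  noise with 5 time points × 3 replicates the median absolute relative
  error is ~3%.
* **Growth constant.** ln(OD) is fitted over every contiguous window of
  9 points (2 h at 15-min sampling; clipped to the curve, never below
  5) and r is the slope of the *steepest* window passing an R² ≥ 0.99
  linearity guard — the maximum specific growth rate. Selecting the
  window by maximal R² instead is biased low on saturating curves:
  windows reaching into the deceleration phase have large between-point
  variance and therefore higher R² than clean exponential windows
  (~13% underestimation on logistic curves), which is why the steepest
  well-fitting window is used. Exact on pure exponentials; within ~4%
  on logistic curves at 0.5% OD noise. If no window passes the guard
  the steepest positive window is used (logged); with no positive
  window r = 0, flagged.
* **Membrane potential.** Each dye-quench trace is normalized to its
  own maximum; the index is the mean normalized fluorescence over the
  3-min window following mitochondria addition (window start and length
  configurable). Lower index = deeper quench = more potential.
* **Import kinetics.** Both series divided by the control series' final
  value ×100, so the control endpoint is exactly 100%; series must
  share their time grid.

The assay simulator provides exact closed-form (noiseless) modes for
every kind, used for exactness tests, plus multiplicative log-normal
noise for recovery statistics. The decay scenario with doubled t½
emulates proteasome inhibition doubling a precursor's half-life; the
recovery claim is about the *median* estimated ratio over replicated
simulations (a single noisy pair has ~8% ratio SD).

## Problem sizes

The shipped drivers and acceptance script use 2,000–5,000 gene screens
× 4 replicates, 500-sequence presequence sets, 10 × 80 alignments
(100 seeds), and 200-replicate assay simulations — sizes at which every
statistical check is stable from seed to seed while the whole suite
runs in seconds.

## Known limitations

* No spatial (edge/row/column) correction beyond plate-mean
  normalization.
* The uniqueness scan and enrichment matrix treat positions
  independently; no motif or helix-periodicity model.
* Conservation scores assume a gapless or lightly-gapped alignment;
  heavily gapped columns score near 0 by construction.
* Growth-rate estimation assumes at least one clean exponential stretch
  of ~2 h; diauxic or very slow curves need a custom window length.
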