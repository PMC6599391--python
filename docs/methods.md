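# Methods

This note documents the models and procedures implemented in `specs`, the
assumptions behind them, and the choices made where the design was open.

## The screen being modeled

The package targets sort-seq screens of synthetic promoter libraries: each
library member is a tandem repeat of one transcription-factor binding site
(TF-BS) upstream of a minimal promoter driving a fluorescent reporter. A cell
population carrying the library (ideally one integration per cell) is sorted
by FACS into five gates of increasing fluorescence — negative, low, high,
top 5–10%, top 5% — and each sorted bin is sequenced. A promoter's count
profile across bins approximates its single-cell fluorescence distribution,
and comparing profiles between two cell states (e.g. tumor vs. normal)
identifies cell-state-specific promoters.

## Library design (`library_design`)

Each PWM is collapsed to its consensus (per-position argmax; ties broken
alphabetically A<C<G<T so designs are deterministic) and used on both
strands. Consensi, including reverse complements, are deduplicated across the
whole collection before construct generation, so a palindromic site yields
one construct. A TF-BS of length L is repeated `k = floor(129 / (L + 3))`
times with a 3 bp spacer; the floor keeps the variable region within the
129 bp budget of a ~150 bp synthesized oligo, and motifs longer than 126 bp
(k = 0) are reported as un-designable. Every construct carries a unique
random 17 bp barcode, rejected on collision or on containing the AscI
recognition sequence GGCGCGCC, because that site delimits the variable region
in sequencing reads and must occur exactly once downstream of it.

Open choices fixed here: the spacer is the neutral 3-mer `CGT`; the fixed
flanks (a 16 bp 5' priming stub and a 3' flank of AscI site + minimal
promoter stub) are configurable module constants — real designs would
substitute vendor-specific sequences without affecting any algorithm.

## Screen simulator (`screen_simulator`)

The generator defines the study conditions under which the pipeline is
validated:

- **Per-cell fluorescence** is lognormal: log2 fluorescence ~
  Normal(median_{i,s}, σ), σ = 0.8 log2 units by default, the shape commonly
  seen in reporter cytometry.
- **Gating.** The negative gate is the 99.5th percentile of an uninfected
  control sample; among strictly fluorescence-positive cells, top 5% lies
  above the 95th percentile, top 5–10% between the 90th and 95th, and the
  remaining 90% of positives are halved at their median into low/high. Gate
  means ȳ_b are the mean fluorescence of the library population's cells in
  each gate (falling back to the control sample for gates the library
  population leaves empty).
- **Coverage and infection**: 100 cells per construct (the screen's
  >100-fold coverage) at 15% infection; uninfected cells carry
  autofluorescence only (median log2 = 7) and contribute no reads.
- **Sequencing** of each sorted bin is multinomial over the constructs
  occupying that bin, at 10^6 reads per sample by default, so per-sample
  counts conserve depth exactly.
- **Replicates.** Technical replicates redraw sequencing only; biological
  replicates additionally perturb every true median by Normal(0, 1.0 log2
  units) and redraw the cells. This reproduces the qualitative replicate
  hierarchy of such screens (technical log-count correlation well above
  biological).
- **Ground truth**: 60% of constructs are active with base activity uniform
  on 8–16 log2 a.u., jittered per state by Normal(0, 0.8) so activities
  correlate between states; the rest sit at autofluorescence. Planted
  state-specific constructs are active (uniform 12–15) in one state and at
  baseline elsewhere, i.e. >10-fold specific by construction.
- **Reads**: one read per count — variable region followed by the AscI-bearing
  3' flank, truncated to 150 bp — with i.i.d. per-base substitution errors;
  junk reads (no AscI site) replace real reads at a configurable fraction.

What the generator does **not** emulate: PCR jackpotting, integration-site
position effects, sorter impurity/spillover, cytotoxic sorting losses, and
count overdispersion beyond multinomial. Passing recovery tests therefore
shows the estimators are correct and well-behaved under idealized noise, not
that real screens of arbitrary quality will reach the same accuracy.

## Preprocessing (`ngs_preprocess`)

Reads lacking GGCGCGCC are discarded; retained reads are truncated at the
site's 5' edge. Identical sequences are collapsed first; each unique sequence
is assigned to the single best-matching library variable region within 2
mismatches (substitution-only Hamming by default, vectorized per reference
length; an edit-distance mode via edlib admits indels). Ties at the minimal
distance leave the sequence unassigned rather than guessed.

Size factors are native median-of-ratios: reference = per-construct
geometric mean across samples over constructs nonzero everywhere; factor_j =
median of count_ij / reference_i. Because inactive promoters never reach the
top bins, sorted-bin samples often share no all-nonzero construct; a small
pseudocount (0.5 in the default workflow) is applied inside the factor
computation only. The replicate filter keeps constructs with nonzero counts
in at least two replicates (technical or biological) of **every** state.

Sanger clones are matched by infix alignment (edlib, mode HW) of each
variable region against the clone sequence: edit distance 0 → intact, ≤ 10 →
mutated (CIGAR reported), else unidentifiable.

## Activity estimation (`activity_model`)

The activity score of promoter i is the weighted-average heuristic

    A_i = Σ_b ȳ_b n_{i,b} / Σ_b n_{i,b}

with n_{i,b} = log2(1 + normalized count), replicate-averaged. It is bounded
by the extreme gate means and monotone under mass shifts toward brighter
bins; it serves to pick calibration promoters spanning the activity range
(evenly spaced ranks of the mean score across states).

The predictor is an elastic net over engineered features: per-bin log2
counts (5), log2 total (1), bin proportions (5), adjacent-bin log2 ratios
(4), argmax bin (1) — 16 base features, reconstructed to span "counts per
bin (and total) and relationships between bins" — plus all 120 pairwise
products as first-degree interactions (136 total). A +1 pseudocount
precedes every log. Calibration targets are log2 medians of gated per-cell
fluorescence events. Training splits *promoters* (not rows) 60/40 so both
states of a promoter stay on one side; hyperparameters (mixing α ∈
{0, 0.25, 0.5, 0.75, 1}, penalty λ log-spaced 10^-4..10^1) are chosen by
minimum mean RMSE over five-times 5-fold repeated CV on the training split
(no one-standard-error rule), standardizing features inside each fold; the
final model is refit on the full training split and reported against the
untouched 40% test split alongside an unregularized linear baseline. Models
serialize to versioned JSON and reload to bit-identical predictions.

## Specificity ranking (`specificity`)

Specificity is the antisymmetric log2 fold-difference pred_A − pred_B, with
helpers at the 10-fold (log2 10) and 100-fold thresholds. Candidate
selection returns the four classes used for validation: top-n folds each
way, plus n promoters at evenly spaced quantiles of each state's predicted
activity ("range" classes). Enrichment of a candidate subset against the
library background (subset excluded) is a two-sided Wilcoxon rank-sum test:
exact enumeration of all C(n, m) assignments for combined n ≤ 12 (two-sided
p doubles the smaller tail, capped at 1; ties handled by midranks), the
tie-corrected normal approximation with continuity correction otherwise.

For low-coverage screens the model-free heuristic uses the three most
informative count features — total counts, negative-bin counts, argmax
bin — labeling a construct specific to A when its argmax in A is a positive
bin with negative-bin fraction < 0.25 (configurable; no printed value
exists) while its argmax in B is the negative bin. Candidates rank by the
negative-fraction contrast between states, then total counts, then id; a
construct whose argmax is the negative bin in every state is never promoted.

## Image statistic (`image_analysis`)

Reporter images are median-filtered (3×3, edge replication — delegated to
`scipy.ndimage.median_filter`) and reduced to 256-bin intensity histograms
of relative pixel frequencies; the stored value is log10(1 + frequency), so
absent bins are exactly 0 and no bin exceeds log10(2). Log base 10 is a
recorded convention — any base rescales all columns uniformly. Images of
higher bit depth are linearly min-max mapped to 8-bit before binning;
histograms are computed per provided image, not per stitched mosaic.
Missing days in a numeric time course render as gap columns.

## Problem sizes and numerical choices

Validation studies run at 200–500 constructs, 10^5–10^6 reads per sample,
and 40–81 calibration promoters — a deliberate scaled-down analog of the
full screen chosen so the complete simulation-recovery studies run in
minutes on one core while keeping >100× coverage and the default noise
model. Elastic-net fits use coordinate descent (max_iter 10^4, tol 10^-4);
α = 0 (pure ridge) stays in the grid for completeness although coordinate
descent is not the ideal solver there. Constant features standardize to
zero rather than dividing by zero. All randomness flows through explicit
seeds; every simulation, library build and training run is reproducible
byte-for-byte given the seed.

## Known limitations

- The engineered feature list is a documented reconstruction of its
  description; it sits behind a stable schema and can be swapped.
- The activity score is biased toward bin means when a promoter's
  distribution straddles gates; the regression model exists precisely to
  absorb that bias.
- The heuristic's negative-fraction threshold and the simulator's gate
  positions are configurable because the original instrument settings are
  not published.
- Hamming matching ignores indels by default (sequencing substitutions
  dominate on short amplicons); use the edit-distance mode where indels
  matter.
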